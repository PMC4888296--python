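"""Independent brute-force MSPA oracle.

A deliberately naive, pure-Python re-implementation of the morphological
classification rules (iterated erosion -> islets -> boundary zone with
edge/perforation split -> connector contacts), used only to cross-check the
production implementation.  No scipy, no vectorisation: explicit neighbour
loops and breadth-first searches.
"""

from collections import deque

CORE, ISLET, EDGE, PERFORATION, BRIDGE, LOOP, BRANCH, BACKGROUND = (
    "CORE",
    "ISLET",
    "EDGE",
    "PERFORATION",
    "BRIDGE",
    "LOOP",
    "BRANCH",
    "BACKGROUND",
)

OFFS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
OFFS4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]


def _neighbours(r, c, conn):
    for dr, dc in OFFS8 if conn == 8 else OFFS4:
        yield r + dr, c + dc


def _components(cells, conn):
    """Connected components (list of sets) of a set of cells."""
    cells = set(cells)
    seen = set()
    comps = []
    for start in sorted(cells):
        if start in seen:
            continue
        comp = {start}
        queue = deque([start])
        seen.add(start)
        while queue:
            r, c = queue.popleft()
            for nb in _neighbours(r, c, conn):
                if nb in cells and nb not in seen:
                    seen.add(nb)
                    comp.add(nb)
                    queue.append(nb)
        comps.append(comp)
    return comps


def classify_oracle(grid, conn=8, edge_width=1):
    """Return a dict (r, c) -> class name for every foreground cell."""
    nrow = len(grid)
    ncol = len(grid[0]) if nrow else 0
    fg = {(r, c) for r in range(nrow) for c in range(ncol) if grid[r][c]}
    out = {}
    if not fg:
        return out

    def inside(rc):
        return 0 <= rc[0] < nrow and 0 <= rc[1] < ncol

    # rule 1: iterated erosion; outside the raster counts as background
    core = set(fg)
    for _ in range(edge_width):
        core = {
            (r, c)
            for (r, c) in core
            if all(inside(nb) and nb in core for nb in _neighbours(r, c, conn))
        }

    # rule 2: components without core are wholly islet
    comps = _components(fg, conn)
    comp_id = {}
    for i, comp in enumerate(comps):
        for p in comp:
            comp_id[p] = i
    core_comp_ids = {comp_id[p] for p in core}
    for comp in comps:
        if comp_id[next(iter(comp))] not in core_comp_ids:
            for p in comp:
                out[p] = ISLET

    # rule 3: boundary zone = geodesic dilation of core within fg, depth <= w
    boundary = set()
    frontier = set(core)
    for _ in range(edge_width):
        new = set()
        for r, c in frontier:
            for nb in _neighbours(r, c, conn):
                if nb in fg and nb not in core and nb not in boundary:
                    new.add(nb)
        boundary |= new
        frontier = new

    # background components under complementary connectivity; unbounded = border
    bg = {(r, c) for r in range(nrow) for c in range(ncol) if (r, c) not in fg}
    bg_conn = 4 if conn == 8 else 8
    unbounded, holes = set(), []
    for comp in _components(bg, bg_conn):
        if any(r in (0, nrow - 1) or c in (0, ncol - 1) for r, c in comp):
            unbounded |= comp
        else:
            holes.append(comp)
    hole_cells = set().union(*holes) if holes else set()

    for r, c in boundary:
        nbs = list(_neighbours(r, c, conn))
        touches_open = any(not inside(nb) or nb in unbounded for nb in nbs)
        touches_hole = any(nb in hole_cells for nb in nbs)
        if touches_open:
            out[(r, c)] = EDGE
        elif touches_hole:
            out[(r, c)] = PERFORATION
        else:
            out[(r, c)] = EDGE

    for p in core:
        out[p] = CORE

    # rule 4: connectors, classified by their contacts with the zones of the
    # core components (a core component's zone = the component plus the
    # boundary pixels geodesically reachable from it within edge_width steps)
    zone = core | boundary
    core_zones = []
    for core_comp in _components(core, conn):
        zk = set(core_comp)
        frontier = set(core_comp)
        for _ in range(edge_width):
            new = set()
            for r, c in frontier:
                for nb in _neighbours(r, c, conn):
                    if nb in fg and nb not in core and nb not in zk:
                        new.add(nb)
            zk |= new
            frontier = new
        core_zones.append(zk)

    connector = {p for p in fg if p not in zone and p not in out}
    for conn_comp in _components(connector, conn):
        touch = {
            p
            for p in conn_comp
            if any(nb in zone for nb in _neighbours(p[0], p[1], conn))
        }
        contacts = _components(touch, conn)
        core_ids = set()
        for contact in contacts:
            for r, c in contact:
                for nb in _neighbours(r, c, conn):
                    for i, zk in enumerate(core_zones):
                        if nb in zk:
                            core_ids.add(i)
        if len(core_ids) >= 2:
            label = BRIDGE
        elif len(contacts) >= 2:
            label = LOOP
        elif len(contacts) == 1:
            label = BRANCH
        else:  # cannot occur: such a component would have been islet
            raise AssertionError("connector without contact")
        for p in conn_comp:
            out[p] = label
    return out
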