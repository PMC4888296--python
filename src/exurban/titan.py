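"""Threshold Indicator Taxa Analysis (TITAN) along an environmental gradient.

For each species, every candidate split of the gradient (midpoints between
consecutive distinct environment values leaving at least ``min_split`` sites
on each side) partitions the sites into a low and a high group.  The
Dufrene–Legendre indicator value of the species for each group,

    IndVal_g = 100 * specificity * fidelity
             = 100 * (mean abundance in g / sum of the two group means)
                   * (fraction of sites in g with the species present),

is standardised against a permutation null (environment values shuffled
across sites) to a z score.  The species' change point is the candidate/side
pair with the largest z; the direction is ``z-`` if the species is an
indicator of the low side (declines past the threshold) and ``z+`` if of the
high side.  The permutation p-value uses the maximum IndVal over all
candidates and sides as the test statistic (controlling for the scan's
selection), with the +1 correction.

Bootstrap resampling of sites yields the quality diagnostics: *purity* (the
fraction of bootstrap replicates agreeing with the observed direction),
*reliability* (the fraction with IndVal p <= 0.05), and the 5%/95% quantiles
of the bootstrap change-point distribution.

This is a self-contained implementation of the method; numeric parity with
the released TITAN2 R package is not attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TitanConfig:
    """Tuning knobs of the scan and its diagnostics.

    ``min_split`` is the minimum number of sites required on each side of a
    candidate split (the method's minimum is 3; the study default is 5);
    ``n_perm`` permutations standardise IndVals to z scores and feed the
    p-value; ``n_boot`` bootstrap replicates yield purity/reliability and
    change-point quantiles.
    """

    min_split: int = 5
    n_perm: int = 250
    n_boot: int = 250
    boot_quantiles: tuple[float, float] = (0.05, 0.95)
    purity_threshold: float = 0.95
    reliability_threshold: float = 0.95
    maximize: str = "z"  # or "indval": which statistic picks the change point
    max_redraws: int = 200

    def __post_init__(self) -> None:
        if self.min_split < 3:
            raise ValueError("min_split must be >= 3")
        if self.n_perm < 1 or self.n_boot < 1:
            raise ValueError("n_perm and n_boot must be >= 1")
        if self.maximize not in ("z", "indval"):
            raise ValueError("maximize must be 'z' or 'indval'")


def indval(abundances: np.ndarray, in_high: np.ndarray) -> dict[str, float]:
    """Dufrene–Legendre indicator value of one species for a 2-group partition.

    Parameters
    ----------
    abundances : array, shape (n,)
        Non-negative abundance per site.
    in_high : bool array, shape (n,)
        Partition; both groups must be non-empty.

    Returns
    -------
    dict with ``IndVal_low`` and ``IndVal_high``, each in [0, 100].
    """
    a = np.asarray(abundances, dtype=float)
    hi = np.asarray(in_high, dtype=bool)
    if not hi.any() or hi.all():
        raise ValueError("both groups must be non-empty")
    if a.sum() == 0:
        raise ValueError("species absent from every site")
    mean_low, mean_high = a[~hi].mean(), a[hi].mean()
    occ_low = (a[~hi] > 0).mean()
    occ_high = (a[hi] > 0).mean()
    denom = mean_low + mean_high
    return {
        "IndVal_low": 100.0 * (mean_low / denom) * occ_low,
        "IndVal_high": 100.0 * (mean_high / denom) * occ_high,
    }


def _candidate_cuts(env_sorted: np.ndarray, min_split: int) -> np.ndarray:
    """Cut positions k (size of the low group) for sorted env values.

    A cut at k is valid when env_sorted[k-1] < env_sorted[k] (ties collapse
    to a single candidate) and both sides keep >= min_split sites.
    """
    n = env_sorted.size
    ks = np.arange(min_split, n - min_split + 1)
    if ks.size == 0:
        return ks
    return ks[env_sorted[ks - 1] < env_sorted[ks]]


def _indval_profiles(a_rows: np.ndarray, ks: np.ndarray) -> np.ndarray:
    """IndVal at every cut for each row of site-sorted abundances.

    ``a_rows`` : (m, n) abundances already ordered along the gradient.
    Returns array (m, n_cuts, 2) with [:, :, 0] = IndVal_low, [:, :, 1] = high.
    """
    m, n = a_rows.shape
    csum = np.cumsum(a_rows, axis=1)
    cocc = np.cumsum(a_rows > 0, axis=1)
    tot = csum[:, -1][:, None]
    tocc = cocc[:, -1][:, None]
    low_sum = csum[:, ks - 1]
    low_occ = cocc[:, ks - 1]
    kk = ks[None, :].astype(float)
    mean_low = low_sum / kk
    mean_high = (tot - low_sum) / (n - kk)
    denom = mean_low + mean_high
    with np.errstate(invalid="ignore", divide="ignore"):
        a_low = np.where(denom > 0, mean_low / denom, 0.0)
        a_high = np.where(denom > 0, mean_high / denom, 0.0)
    b_low = low_occ / kk
    b_high = (tocc - low_occ) / (n - kk)
    out = np.empty((m, ks.size, 2))
    out[:, :, 0] = 100.0 * a_low * b_low
    out[:, :, 1] = 100.0 * a_high * b_high
    return out


def change_point_scan(
    abundances: np.ndarray,
    env: np.ndarray,
    config: TitanConfig | None = None,
    rng: np.random.Generator | None = None,
    perm_index: np.ndarray | None = None,
    warn_zero_sd: bool = True,
) -> dict:
    """Locate one species' change point along the gradient.

    Returns a dict with ``direction`` ('z-'/'z+'), ``z``, ``cp`` (the
    midpoint environment value of the winning split), ``indval`` at the
    change point, ``p`` (permutation, max-IndVal statistic, +1 corrected),
    and the per-candidate profiles used by the community-level summaries.

    ``perm_index`` (n_perm, n) may supply explicit permutations of site
    indices — used by the exhaustive test oracle; by default ``n_perm``
    random permutations are drawn from ``rng``.
    """
    config = config or TitanConfig()
    a = np.asarray(abundances, dtype=float)
    e = np.asarray(env, dtype=float)
    if a.shape != e.shape or a.ndim != 1:
        raise ValueError("abundances and env must be 1-D and aligned")
    n = a.size
    if n < 2 * config.min_split:
        raise ValueError(f"need at least {2 * config.min_split} sites, got {n}")
    if not np.isfinite(e).all():
        raise ValueError("environment values must be finite")
    if a.sum() == 0:
        raise ValueError("species absent from every site")

    order = np.argsort(e, kind="stable")
    es = e[order]
    ks = _candidate_cuts(es, config.min_split)
    if ks.size == 0:
        raise ValueError("no valid candidate split (too many ties or sites)")
    cps = 0.5 * (es[ks - 1] + es[ks])

    obs = _indval_profiles(a[order][None, :], ks)[0]  # (n_cuts, 2)

    if perm_index is None:
        rng = rng or np.random.default_rng()
        perm_index = rng.permuted(
            np.broadcast_to(np.arange(n), (config.n_perm, n)).copy(), axis=1
        )
    perm = _indval_profiles(a[order][perm_index], ks)  # (n_perm, n_cuts, 2)
    mu = perm.mean(axis=0)
    sd = perm.std(axis=0, ddof=1) if perm.shape[0] > 1 else np.zeros_like(mu)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (obs - mu) / sd, 0.0)
    if warn_zero_sd and (sd == 0).any():
        warnings.warn("zero permutation s.d. at some candidates; z set to 0 there")

    crit = z if config.maximize == "z" else obs
    flat = int(np.argmax(crit))
    ci, side = divmod(flat, 2)
    direction = "z+" if side == 1 else "z-"

    obs_max = obs.max()
    perm_max = perm.max(axis=(1, 2))
    p = (1 + int((perm_max >= obs_max).sum())) / (perm.shape[0] + 1)

    return {
        "direction": direction,
        "z": float(z[ci, side]),
        "cp": float(cps[ci]),
        "indval": float(obs[ci, side]),
        "p": float(p),
        "candidates": cps,
        "z_profile": z,
        "indval_profile": obs,
    }


def bootstrap_diagnostics(
    abundances: np.ndarray,
    env: np.ndarray,
    config: TitanConfig,
    observed: dict,
    rng: np.random.Generator | None = None,
) -> dict:
    """Purity, reliability and change-point quantiles from site bootstrap.

    Resamples sites with replacement ``n_boot`` times and reruns the scan on
    each replicate.  Replicates on which the scan is undefined (species
    absent, or no valid candidate split) are redrawn; the number of redraws
    is reported.
    """
    rng = rng or np.random.default_rng()
    a = np.asarray(abundances, dtype=float)
    e = np.asarray(env, dtype=float)
    n = a.size
    dirs, ps, cps = [], [], []
    redraws = 0
    for _ in range(config.n_boot):
        for _attempt in range(config.max_redraws):
            idx = rng.integers(0, n, size=n)
            ab, eb = a[idx], e[idx]
            if ab.sum() == 0 or _candidate_cuts(np.sort(eb), config.min_split).size == 0:
                redraws += 1
                continue
            res = change_point_scan(ab, eb, config, rng=rng, warn_zero_sd=False)
            break
        else:
            raise RuntimeError("bootstrap redraw cap exceeded")
        dirs.append(res["direction"])
        ps.append(res["p"])
        cps.append(res["cp"])
    dirs = np.array(dirs)
    q_lo, q_hi = np.quantile(cps, config.boot_quantiles)
    return {
        "purity": float((dirs == observed["direction"]).mean()),
        "reliability": float((np.array(ps) <= 0.05).mean()),
        "cp_q_low": float(q_lo),
        "cp_q_high": float(q_hi),
        "n_redraws": redraws,
    }


@dataclass
class TitanSpeciesResult:
    species: str
    direction: str
    z: float
    cp: float
    cp_q_low: float
    cp_q_high: float
    purity: float
    reliability: float
    p: float
    status: str = "ok"


class Titan:
    """Threshold Indicator Taxa Analysis of a site-by-species table.

    Parameters
    ----------
    env : array-like, shape (n_sites,)
        Environmental gradient value per site (here: compactness %).  Sites
        with non-finite values are dropped (with their abundance rows).
    abundance : DataFrame, shape (n_sites, n_species)
        Non-negative abundances (adjusted counts).  Species with zero total
        abundance are dropped.
    config : TitanConfig, optional

    Examples
    --------
    >>> model = Titan(env, abundance, TitanConfig(n_perm=250, n_boot=250))
    >>> results = model.fit(seed=7)
    >>> table = results.summary()
    """

    def __init__(
        self,
        env,
        abundance: pd.DataFrame,
        config: TitanConfig | None = None,
    ) -> None:
        env = np.asarray(env, dtype=float)
        abundance = pd.DataFrame(abundance)
        if env.shape[0] != abundance.shape[0]:
            raise ValueError("env and abundance row counts differ")
        keep = np.isfinite(env)
        self.n_dropped_sites = int((~keep).sum())
        env = env[keep]
        abundance = abundance.loc[keep]
        present = abundance.sum(axis=0) > 0
        self.dropped_species = list(abundance.columns[~present])
        self.env = env
        self.abundance = abundance.loc[:, present]
        self.config = config or TitanConfig()

    def fit(self, seed: int | None = None) -> "TitanResults":
        """Run the scan and bootstrap for every species (seeded, reproducible).

        Each species' stream is keyed by (seed, species name), so results do
        not depend on the column order of the abundance table.
        """
        import hashlib

        results, details = [], {}
        for sp in self.abundance.columns:
            key = int.from_bytes(
                hashlib.sha256(str(sp).encode()).digest()[:4], "big"
            )
            rng = np.random.default_rng(
                np.random.SeedSequence([0 if seed is None else seed, key])
            )
            a = self.abundance[sp].to_numpy(dtype=float)
            try:
                obs = change_point_scan(a, self.env, self.config, rng=rng)
                boot = bootstrap_diagnostics(a, self.env, self.config, obs, rng=rng)
                results.append(
                    TitanSpeciesResult(
                        species=str(sp),
                        direction=obs["direction"],
                        z=obs["z"],
                        cp=obs["cp"],
                        cp_q_low=boot["cp_q_low"],
                        cp_q_high=boot["cp_q_high"],
                        purity=boot["purity"],
                        reliability=boot["reliability"],
                        p=obs["p"],
                    )
                )
                details[str(sp)] = obs
            except (ValueError, RuntimeError) as err:  # row-level status, not abort
                results.append(
                    TitanSpeciesResult(
                        species=str(sp),
                        direction="",
                        z=np.nan,
                        cp=np.nan,
                        cp_q_low=np.nan,
                        cp_q_high=np.nan,
                        purity=np.nan,
                        reliability=np.nan,
                        p=np.nan,
                        status=f"error: {err}",
                    )
                )
        return TitanResults(self, results, details)


class TitanResults:
    """Fitted TITAN results: one row per species plus community-level sums."""

    def __init__(self, model: Titan, results: list[TitanSpeciesResult], details: dict):
        self.model = model
        self.species_results = results
        self._details = details

    def summary(self) -> pd.DataFrame:
        """Species table: direction, z, change point with bootstrap quantiles,
        purity, reliability, p, and significance flags at the 0.90 and 0.95
        purity/reliability thresholds (both require p < 0.05)."""
        rows = []
        for r in self.species_results:
            ok = r.status == "ok"
            rows.append(
                {
                    "species": r.species,
                    "direction": r.direction,
                    "z": r.z,
                    "cp": r.cp,
                    "cp_5pct": r.cp_q_low,
                    "cp_95pct": r.cp_q_high,
                    "purity": r.purity,
                    "reliability": r.reliability,
                    "p": r.p,
                    "sig_090": bool(
                        ok and r.p < 0.05 and r.purity >= 0.90 and r.reliability >= 0.90
                    ),
                    "sig_095": bool(
                        ok and r.p < 0.05 and r.purity >= 0.95 and r.reliability >= 0.95
                    ),
                    "status": r.status,
                }
            )
        return pd.DataFrame(rows)

    def community_sums(self) -> pd.DataFrame:
        """Secondary community-level sum(z) profiles: summed low-side (z-)
        and high-side (z+) scores across species at each candidate."""
        frames = []
        for sp, det in self._details.items():
            frames.append(
                pd.DataFrame(
                    {
                        "species": sp,
                        "cp": det["candidates"],
                        "z_low": det["z_profile"][:, 0],
                        "z_high": det["z_profile"][:, 1],
                    }
                )
            )
        if not frames:
            return pd.DataFrame(columns=["cp", "sum_z_minus", "sum_z_plus"])
        prof = pd.concat(frames)
        out = prof.groupby("cp").agg(
            sum_z_minus=("z_low", "sum"), sum_z_plus=("z_high", "sum")
        )
        return out.reset_index()

    def plot_change_points(self, ax=None):
        """Change points with 5–95% bootstrap intervals, markers sized by z."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.4 * max(len(self.species_results), 4)))
        ok = [r for r in self.species_results if r.status == "ok"]
        for i, r in enumerate(ok):
            colour = "k" if r.direction == "z-" else "w"
            ax.plot([r.cp_q_low, r.cp_q_high], [i, i], "-", color="grey", lw=1)
            ax.scatter(
                [r.cp], [i], s=20 + 10 * abs(r.z), facecolor=colour,
                edgecolor="k", zorder=3,
            )
        ax.set_yticks(range(len(ok)))
        ax.set_yticklabels([r.species for r in ok])
        ax.set_xlabel("compactness change point (%)")
        return ax


def run_titan(
    env,
    abundance: pd.DataFrame,
    config: TitanConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Functional wrapper: fit TITAN and return the species summary table."""
    return Titan(env, abundance, config).fit(seed=seed).summary()
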