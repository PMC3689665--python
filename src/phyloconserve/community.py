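"""Regional community phylogenetic structure.

Mean pairwise distance (MPD) and mean nearest-taxon distance (MNTD) for
species assemblages, a tip-pool null model that draws equally sized
random assemblages from all tips of the phylogeny, and the standardized
indices NRI (from MPD) and NTI (from MNTD) with rank p-values.

Sign convention: the index is the *negated* standardized effect size,
so positive values indicate phylogenetic clustering and negative values
overdispersion. Both a one-tailed clustering p-value and a two-sided
p-value are always reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tree import DistanceMatrix, Phylogeny, patristic_distances

__all__ = [
    "UndefinedMetricError",
    "NullModelResult",
    "Assemblage",
    "mpd",
    "mntd",
    "phylogeny_pool_null",
    "ses_index",
    "regional_structure",
    "read_assemblages_csv",
    "write_assemblages_csv",
]

_METRICS = ("MPD", "MNTD")


class UndefinedMetricError(ValueError):
    """Raised when a metric is requested for an assemblage of < 2 species."""


@dataclass(frozen=True)
class Assemblage:
    """A named set of co-occurring species, all present in the tree."""

    region_name: str
    members: frozenset[str]

    def __init__(self, region_name: str, members):
        object.__setattr__(self, "region_name", region_name)
        object.__setattr__(self, "members", frozenset(members))
        if len(self.members) < 1:
            raise ValueError(f"assemblage {region_name!r} is empty")


@dataclass
class NullModelResult:
    """Observed metric vs a null distribution, with the negated SES."""

    metric_name: str
    observed: float
    null_mean: float
    null_sd: float
    index: float | None
    p_clustering: float
    p_two_sided: float
    n_reps: int
    seed: int
    diagnostic: str = ""


def _member_indices(dist: DistanceMatrix, members) -> np.ndarray:
    members = set(members)
    missing = members - set(dist.labels)
    if missing:
        raise KeyError(f"species not in distance matrix: {sorted(missing)}")
    idx = [i for i, lab in enumerate(dist.labels) if lab in members]
    return np.asarray(idx, dtype=int)


def mpd(dist: DistanceMatrix, members) -> float:
    """Mean patristic distance over all unordered pairs of members."""
    idx = _member_indices(dist, members)
    if idx.size < 2:
        raise UndefinedMetricError(
            f"MPD needs >= 2 species, got {idx.size}"
        )
    sub = dist.values[np.ix_(idx, idx)]
    k = idx.size
    return float(sub.sum() / (k * (k - 1)))


def mntd(dist: DistanceMatrix, members) -> float:
    """Mean distance from each member to its nearest other member."""
    idx = _member_indices(dist, members)
    if idx.size < 2:
        raise UndefinedMetricError(
            f"MNTD needs >= 2 species, got {idx.size}"
        )
    sub = dist.values[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def _metric_over_draws(values: np.ndarray, draws: np.ndarray, metric: str) -> np.ndarray:
    """Vectorized MPD/MNTD over an (n_reps, k) array of tip indices."""
    n_reps, k = draws.shape
    # gather the k x k submatrix for every draw
    sub = values[draws[:, :, None], draws[:, None, :]]
    if metric == "MPD":
        return (sub.sum(axis=(1, 2))) / (k * (k - 1))
    eye = np.eye(k, dtype=bool)
    sub = np.where(eye, np.inf, sub)
    return sub.min(axis=2).mean(axis=1)


def phylogeny_pool_null(
    dist: DistanceMatrix,
    k: int,
    metric: str,
    n_reps: int,
    seed: int,
) -> np.ndarray:
    """Null sample of a metric under the tip-pool randomization.

    Each replicate draws ``k`` tips uniformly without replacement from
    *all* tips of the tree and evaluates the metric. Reproducible for a
    fixed ``seed``.
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}, got {metric!r}")
    n_pool = len(dist.labels)
    if not 2 <= k <= n_pool:
        raise ValueError(f"assemblage size k={k} out of range [2, {n_pool}]")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.empty(n_reps)
    # chunk to bound memory: n_reps * k * k floats per chunk
    chunk = max(1, int(4e6 // max(k * k, n_pool)))
    for lo in range(0, n_reps, chunk):
        hi = min(lo + chunk, n_reps)
        # uniform draws without replacement, vectorized across replicates
        draws = np.argsort(rng.random((hi - lo, n_pool)), axis=1)[:, :k]
        out[lo:hi] = _metric_over_draws(dist.values, draws, metric)
    return out


def ses_index(
    dist: DistanceMatrix,
    members,
    metric: str,
    n_reps: int = 999,
    seed: int = 0,
) -> NullModelResult:
    """Standardized effect size of MPD or MNTD against the tip-pool null.

    ``index = -(obs - null_mean)/null_sd`` — i.e. NRI for MPD, NTI for
    MNTD. ``p_clustering`` is the one-tailed rank probability
    ``(1 + #{null <= obs}) / (n_reps + 1)`` (ties count toward
    clustering); ``p_two_sided`` doubles the smaller tail, capped at 1.
    """
    obs = mpd(dist, members) if metric == "MPD" else mntd(dist, members)
    k = len(set(members))
    null = phylogeny_pool_null(dist, k, metric, n_reps, seed)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if n_reps > 1 else 0.0
    n_le = int(np.count_nonzero(null <= obs))
    p_clust = (1 + n_le) / (n_reps + 1)
    p_other = 1 - p_clust + 1 / (n_reps + 1)
    p_two = min(1.0, 2 * min(p_clust, p_other))
    # guard against a numerically degenerate null (e.g. k = pool size)
    if null_sd > 1e-12 * max(1.0, abs(null_mean)):
        index = -(obs - null_mean) / null_sd
        diagnostic = ""
    else:
        index = None
        diagnostic = "degenerate null: null distribution has zero variance"
    return NullModelResult(
        metric_name=metric,
        observed=obs,
        null_mean=null_mean,
        null_sd=null_sd,
        index=index,
        p_clustering=p_clust,
        p_two_sided=p_two,
        n_reps=n_reps,
        seed=seed,
        diagnostic=diagnostic,
    )


def regional_structure(
    tree: Phylogeny,
    assemblages: list[Assemblage],
    n_reps: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """NRI and NTI rows for every assemblage against the full tip pool.

    Returns a DataFrame with columns ``region, metric, obs, null_mean,
    null_sd, index, p_clustering, p_two_sided, n_reps, seed``. Regions
    with fewer than 2 members present are flagged in the ``diagnostic``
    column and carry missing values. Sub-seeds are spawned
    deterministically from ``seed`` per (region, metric).
    """
    dist = patristic_distances(tree)
    pool = set(dist.labels)
    rows = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * len(assemblages))
    for i, asm in enumerate(assemblages):
        extraneous = set(asm.members) - pool
        if extraneous:
            raise KeyError(
                f"region {asm.region_name!r} has species absent from the "
                f"tree: {sorted(extraneous)}"
            )
        for j, (metric, index_name) in enumerate(
            (("MPD", "NRI"), ("MNTD", "NTI"))
        ):
            sub_seed = int(children[2 * i + j].generate_state(1)[0])
            base = {
                "region": asm.region_name,
                "metric": index_name,
                "n_reps": n_reps,
                "seed": sub_seed,
            }
            if len(asm.members) < 2:
                rows.append(
                    {
                        **base,
                        "obs": np.nan,
                        "null_mean": np.nan,
                        "null_sd": np.nan,
                        "index": np.nan,
                        "p_clustering": np.nan,
                        "p_two_sided": np.nan,
                        "diagnostic": "fewer than 2 members",
                    }
                )
                continue
            res = ses_index(dist, asm.members, metric, n_reps, sub_seed)
            rows.append(
                {
                    **base,
                    "obs": res.observed,
                    "null_mean": res.null_mean,
                    "null_sd": res.null_sd,
                    "index": np.nan if res.index is None else res.index,
                    "p_clustering": res.p_clustering,
                    "p_two_sided": res.p_two_sided,
                    "diagnostic": res.diagnostic,
                }
            )
    return pd.DataFrame(rows)


def read_assemblages_csv(path) -> list[Assemblage]:
    """Read long-format ``region,species`` CSV into assemblages."""
    df = pd.read_csv(path)
    if not {"region", "species"} <= set(df.columns):
        raise ValueError("assemblage CSV needs 'region' and 'species' columns")
    return [
        Assemblage(region, group["species"].tolist())
        for region, group in df.groupby("region", sort=True)
    ]


def write_assemblages_csv(assemblages: list[Assemblage], path) -> None:
    rows = [
        {"region": a.region_name, "species": s}
        for a in assemblages
        for s in sorted(a.members)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
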