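"""Synthetic study generator.

Produces complete, seeded study bundles with the statistical structure
the analysis pipeline assumes: a dated (ultrametric) pure-birth tree,
Brownian/lambda continuous traits, regional assemblages with
controllable phylogenetic structure, coastal-strip rectangular ranges,
IUCN categories, per-species use sets, and a global-decline variable
with a configurable dependence on terminal branch length ("older
species decline more").

All randomness flows from ``StudyConfig.seed`` through a fixed
``SeedSequence`` spawning scheme, so a bundle is bit-for-bit
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .community import Assemblage, write_assemblages_csv
from .risk import USE_VOCABULARY
from .grids import write_ranges_csv
from .tree import (
    Node,
    Phylogeny,
    patristic_distances,
    phylo_vcv,
    terminal_branch_lengths,
    write_newick_file,
)

__all__ = [
    "StudyConfig",
    "StudyBundle",
    "simulate_yule_tree",
    "simulate_trait",
    "simulate_assemblage",
    "simulate_species_table",
    "simulate_ranges",
    "generate_study",
]

_DEFAULT_CATEGORY_PROBS = {
    "LC": 0.60,
    "NT": 0.10,
    "VU": 0.15,
    "EN": 0.10,
    "CR": 0.05,
}

# relative longitudinal range width per category: less threatened
# species get wider strips
_DEFAULT_WIDTH_BY_CATEGORY = {
    "LC": 1.0,
    "NT": 0.8,
    "VU": 0.6,
    "EN": 0.4,
    "CR": 0.25,
    "DD": 0.5,
    "EW": 0.1,
    "EX": 0.1,
}


@dataclass
class StudyConfig:
    n_species: int = 54
    n_regions: int = 6
    birth_rate: float = 0.05  # per Myr
    assemblage_mode: str = "random"  # random | clustered | overdispersed
    region_size: int | None = None  # default: n_species // 3
    decline_intercept: float = 5.0  # percent of population in decline
    decline_slope_on_bl: float = 1.5  # percent per Myr of terminal branch
    decline_noise_sd: float = 10.0
    use_vocabulary: tuple[str, ...] = USE_VOCABULARY
    use_probability: float = 0.25
    category_probabilities: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CATEGORY_PROBS)
    )
    # range geometry: regions are equal longitudinal sectors; species get
    # latitudinally thin strips along a per-region synthetic coastline
    strip_height_deg: float = 2.0
    base_width_frac: float = 0.5
    width_by_category: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_WIDTH_BY_CATEGORY)
    )
    coast_lat_range: tuple[float, float] = (-20.0, 20.0)
    include_fd: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be > 0")
        if self.assemblage_mode not in ("random", "clustered", "overdispersed"):
            raise ValueError(f"unknown assemblage_mode {self.assemblage_mode!r}")
        if not 0.0 <= self.use_probability <= 1.0:
            raise ValueError("use_probability must be in [0, 1]")
        total = sum(self.category_probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"category probabilities must sum to 1, got {total}"
            )
        if any(p < 0 for p in self.category_probabilities.values()):
            raise ValueError("category probabilities must be >= 0")


@dataclass
class StudyBundle:
    tree: Phylogeny
    species_table: pd.DataFrame
    assemblages: list[Assemblage]
    ranges: dict[str, list[tuple[float, float, float, float]]]
    config: StudyConfig


def _rng_for(seed: int, stream: int) -> np.random.Generator:
    """Deterministic per-stage generator: stream 0 = tree, 1 = traits,
    2 = assemblages, 3 = species table, 4 = ranges."""
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(5)[stream])


def simulate_yule_tree(
    n_tips: int, birth_rate: float = 0.05, seed=0
) -> Phylogeny:
    """Ultrametric pure-birth tree grown forward in time.

    Starts from the root split (2 lineages); waiting times between
    birth events are Exp(k * birth_rate) for k extant lineages; the
    lineage that splits is uniform. After the (n_tips - 1)-th split one
    extra Exp(n_tips * birth_rate) interval is appended so pendant
    edges are nonzero.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    root = Node()
    first, second = Node(), Node()
    root.children = [first, second]
    t = 0.0
    active: list[tuple[Node, float]] = [(first, 0.0), (second, 0.0)]
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        i = int(rng.integers(k))
        node, born = active.pop(i)
        node.length = t - born
        left, right = Node(), Node()
        node.children = [left, right]
        active.append((left, t))
        active.append((right, t))
    t += rng.exponential(1.0 / (n_tips * birth_rate))
    for node, born in active:
        node.length = t - born

    tree = Phylogeny(root, validate=False)
    width = max(3, len(str(n_tips)))
    for i, tip in enumerate(tree.tips, start=1):
        tip.label = f"sp{str(i).zfill(width)}"
    tree._validate()
    return tree


def simulate_trait(
    tree: Phylogeny,
    sigma2: float = 1.0,
    root_value: float = 0.0,
    lambda_: float = 1.0,
    seed=0,
) -> dict[str, float]:
    """Multivariate-normal trait with covariance sigma2 * V(lambda),
    where V(lambda) is the tree covariance with off-diagonals scaled."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    if not 0.0 <= lambda_ <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vcv = phylo_vcv(tree)
    V = lambda_ * vcv.values.copy()
    np.fill_diagonal(V, np.diag(vcv.values))
    n = len(vcv.labels)
    jitter = 1e-10 * np.trace(V) / n  # relative, so the sigma2 -> 0 limit holds
    L = np.linalg.cholesky(sigma2 * (V + jitter * np.eye(n)))
    values = root_value + L @ rng.standard_normal(n)
    return dict(zip(vcv.labels, map(float, values)))


def _clades(tree: Phylogeny) -> list[list[str]]:
    """Tip-label sets of all internal nodes except the root."""
    out = []
    for node in tree.root.preorder():
        if node is tree.root or node.is_leaf:
            continue
        tips = [n.label for n in node.preorder() if n.is_leaf]
        out.append(tips)
    return out


def simulate_assemblage(
    tree: Phylogeny, size: int, mode: str = "random", seed=0,
    region_name: str = "region",
) -> Assemblage:
    """Draw one assemblage of ``size`` tips.

    * ``random`` — uniform without replacement from all tips;
    * ``clustered`` — all members from one randomly chosen clade among
      the smallest clades holding >= size tips;
    * ``overdispersed`` — greedy max-min patristic distance selection,
      seeded with the most distant tip pair.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = tree.tip_labels
    n = len(labels)
    if not 1 <= size <= n:
        raise ValueError(f"size {size} out of range [1, {n}]")
    if size == n:
        return Assemblage(region_name, labels)

    if mode == "random":
        members = list(rng.choice(labels, size=size, replace=False))
    elif mode == "clustered":
        candidates = [c for c in _clades(tree) if len(c) >= size]
        if not candidates:
            raise ValueError(
                f"no clade holds >= {size} tips; cannot build a clustered "
                "assemblage"
            )
        smallest = min(len(c) for c in candidates)
        candidates = [c for c in candidates if len(c) == smallest]
        clade = candidates[int(rng.integers(len(candidates)))]
        members = list(rng.choice(clade, size=size, replace=False))
    elif mode == "overdispersed":
        dist = patristic_distances(tree).values
        i, j = np.unravel_index(np.argmax(dist), dist.shape)
        chosen = [int(i), int(j)]
        while len(chosen) < size:
            remaining = [k for k in range(n) if k not in chosen]
            min_d = dist[np.ix_(remaining, chosen)].min(axis=1)
            chosen.append(remaining[int(np.argmax(min_d))])
        members = [labels[k] for k in chosen[:size]]
    else:
        raise ValueError(f"unknown assemblage mode {mode!r}")
    return Assemblage(region_name, members)


def simulate_species_table(
    tree: Phylogeny, config: StudyConfig, rng=None,
    assemblages: list[Assemblage] | None = None,
) -> pd.DataFrame:
    """Per-species table with decline planted on terminal branch length.

    ``global_decline = max(0, a + slope * BL + noise)`` (percent);
    categories are i.i.d. from ``category_probabilities``; uses are
    i.i.d. Bernoulli per vocabulary entry; H_max and propagule size are
    log-normal.
    """
    config.validate()
    if rng is None:
        rng = _rng_for(config.seed, 3)
    bl = terminal_branch_lengths(tree)
    species = tree.tip_labels

    noise = rng.normal(0.0, config.decline_noise_sd, size=len(species)) \
        if config.decline_noise_sd > 0 else np.zeros(len(species))
    decline = np.maximum(
        0.0,
        config.decline_intercept
        + config.decline_slope_on_bl * np.array([bl[s] for s in species])
        + noise,
    )

    cats = list(config.category_probabilities)
    probs = np.array([config.category_probabilities[c] for c in cats])
    categories = rng.choice(cats, size=len(species), p=probs / probs.sum())

    vocab = list(config.use_vocabulary)
    use_draws = rng.random((len(species), len(vocab))) < config.use_probability

    h_max = rng.lognormal(mean=2.3, sigma=0.6, size=len(species))
    propagule = rng.lognormal(mean=1.0, sigma=1.0, size=len(species))
    fd = rng.lognormal(mean=0.0, sigma=1.0, size=len(species)) \
        if config.include_fd else None

    region_of: dict[str, list[str]] = {s: [] for s in species}
    if assemblages:
        for asm in assemblages:
            for s in asm.members:
                region_of[s].append(asm.region_name)

    rows = []
    for i, sp in enumerate(species):
        uses = [u for u, flag in zip(vocab, use_draws[i]) if flag]
        rows.append(
            {
                "species": sp,
                "iucn_category": categories[i],
                "global_decline": float(decline[i]),
                "h_max": float(h_max[i]),
                "propagule_size": float(propagule[i]),
                "uses": ";".join(uses),
                "human_pressure": len(uses),
                "bl": float(bl[sp]),
                "region": ";".join(sorted(region_of[sp])),
            }
        )
    df = pd.DataFrame(rows)
    if fd is not None:
        df["fd"] = fd
    return df


def simulate_ranges(
    species_table: pd.DataFrame, config: StudyConfig, rng=None
) -> dict[str, list[tuple[float, float, float, float]]]:
    """Rectangular coastal-strip ranges.

    Regions occupy equal longitudinal sectors of [-180, 180]; each
    carries one synthetic coastline latitude. A species receives one
    latitudinally thin rectangle per region it belongs to (or, for
    region-less species, one in a random sector), with longitudinal
    width scaled down for more threatened categories.
    """
    config.validate()
    if rng is None:
        rng = _rng_for(config.seed, 4)
    n_regions = config.n_regions
    sector_width = 360.0 / n_regions
    lat_lo, lat_hi = config.coast_lat_range
    coast_lat = rng.uniform(lat_lo, lat_hi, size=n_regions)
    half = config.strip_height_deg / 2.0

    region_index = {f"region_{i + 1}": i for i in range(n_regions)}
    out: dict[str, list[tuple[float, float, float, float]]] = {}
    for rec in species_table.itertuples(index=False):
        sp = rec.species
        regions = [r for r in str(getattr(rec, "region", "") or "").split(";") if r]
        if not regions:
            regions = [f"region_{int(rng.integers(n_regions)) + 1}"]
        mult = config.width_by_category.get(str(rec.iucn_category), 0.5)
        width = max(1.0, sector_width * config.base_width_frac * mult)
        rects = []
        for reg in regions:
            idx = region_index.get(reg, int(rng.integers(n_regions)))
            lon0 = -180.0 + idx * sector_width
            start = lon0 + rng.uniform(0.0, max(sector_width - width, 1e-9))
            lat_c = float(coast_lat[idx])
            rects.append(
                (
                    float(np.clip(start, -180.0, 180.0)),
                    float(np.clip(lat_c - half, -90.0, 90.0)),
                    float(np.clip(start + width, -180.0, 180.0)),
                    float(np.clip(lat_c + half, -90.0, 90.0)),
                )
            )
        out[sp] = rects
    return out


def generate_study(config: StudyConfig, out_dir=None) -> StudyBundle:
    """Generate a full synthetic study, optionally writing it to disk
    (``tree.nwk``, ``species.csv``, ``assemblages.csv``, ``ranges.csv``,
    ``config.yaml``). Deterministic per ``config.seed``."""
    config.validate()
    tree = simulate_yule_tree(
        config.n_species, config.birth_rate, _rng_for(config.seed, 0)
    )
    asm_rng = _rng_for(config.seed, 2)
    size = config.region_size or max(2, config.n_species // 3)
    assemblages = [
        simulate_assemblage(
            tree, size, config.assemblage_mode, asm_rng,
            region_name=f"region_{i + 1}",
        )
        for i in range(config.n_regions)
    ]
    table = simulate_species_table(
        tree, config, _rng_for(config.seed, 3), assemblages=assemblages
    )
    ranges = simulate_ranges(table, config, _rng_for(config.seed, 4))
    bundle = StudyBundle(tree, table, assemblages, ranges, config)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_newick_file(tree, out / "tree.nwk")
        table.to_csv(out / "species.csv", index=False)
        write_assemblages_csv(assemblages, out / "assemblages.csv")
        write_ranges_csv(ranges, out / "ranges.csv")
        cfg = asdict(config)
        cfg["use_vocabulary"] = list(cfg["use_vocabulary"])
        cfg["coast_lat_range"] = list(cfg["coast_lat_range"])
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)
    return bundle
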