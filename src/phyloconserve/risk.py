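"""Threat-side transforms and tests.

* IUCN Red List category -> 50-year extinction probability (a
  user-configurable monotone mapping; a default is shipped as package
  data and never treated as ground truth),
* human-pressure index = number of distinct recorded uses per species,
* Yates-corrected chi-squared tests of per-use association with global
  decline,
* assembly of log10-transformed, listwise-complete model frames aligned
  with a pruned phylogenetic covariance for PGLS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .comparative import PGLSFit  # noqa: F401  (re-export convenience)
from .tree import Phylogeny, PhyloCovariance, phylo_vcv

__all__ = [
    "IUCN_CATEGORIES",
    "USE_VOCABULARY",
    "ExtinctionProbabilityMap",
    "ContingencyResult",
    "ModelFrame",
    "DegenerateMarginError",
    "load_probability_map",
    "default_probability_map",
    "extinction_probability",
    "human_pressure",
    "chisq_yates",
    "use_decline_association",
    "build_model_frame",
    "read_species_table",
    "write_species_table",
]

IUCN_CATEGORIES = ("LC", "NT", "VU", "EN", "CR", "EW", "EX", "DD")
_RANKED = ("LC", "NT", "VU", "EN", "CR")

# Controlled vocabulary of recorded uses (16 labels). Canonical form is
# lower-case with underscores; `canonical_use` folds common variants.
USE_VOCABULARY = (
    "firewood",
    "charcoal",
    "building",
    "structural",
    "carving",
    "cultural",
    "spiritual",
    "food",
    "forage",
    "fodder",
    "medicinal",
    "ornamental",
    "shade",
    "chemical_compounds",
    "tannin",
    "fishing",
)


class DegenerateMarginError(ValueError):
    """A 2x2 table has an all-zero row or column margin."""


class UnknownCategoryError(KeyError):
    """IUCN category missing from the probability mapping."""


@dataclass(frozen=True)
class ExtinctionProbabilityMap:
    """Category -> extinction probability over a fixed horizon."""

    probabilities: dict[str, float]
    horizon_label: str = "IUCN50"

    def __post_init__(self):
        probs = self.probabilities
        for cat, p in probs.items():
            if not 0.0 < p < 1.0:
                raise ValueError(
                    f"probability for {cat} must be in (0, 1), got {p}"
                )
        ranked = [probs[c] for c in _RANKED if c in probs]
        if any(b <= a for a, b in zip(ranked, ranked[1:])):
            raise ValueError(
                "probabilities must increase strictly from LC to CR"
            )

    def __getitem__(self, category: str) -> float:
        try:
            return self.probabilities[category]
        except KeyError:
            raise UnknownCategoryError(
                f"no extinction probability for category {category!r}"
            ) from None

    def __contains__(self, category: str) -> bool:
        return category in self.probabilities


def load_probability_map(path) -> ExtinctionProbabilityMap:
    """Read a category->probability mapping from a small YAML file with
    keys ``horizon`` and ``probabilities``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return ExtinctionProbabilityMap(
        probabilities={str(k): float(v) for k, v in raw["probabilities"].items()},
        horizon_label=str(raw.get("horizon", "IUCN50")),
    )


def default_probability_map() -> ExtinctionProbabilityMap:
    ref = resources.files("phyloconserve.data") / "iucn50.yaml"
    raw = yaml.safe_load(ref.read_text())
    return ExtinctionProbabilityMap(
        probabilities={str(k): float(v) for k, v in raw["probabilities"].items()},
        horizon_label=str(raw.get("horizon", "IUCN50")),
    )


def extinction_probability(category: str, mapping: ExtinctionProbabilityMap) -> float:
    """Look up the extinction probability for one category."""
    return mapping[category]


def canonical_use(label: str) -> str:
    return str(label).strip().lower().replace("-", "_").replace(" ", "_")


def human_pressure(uses, strict: bool = False) -> int:
    """Number of distinct uses after canonicalization against the
    16-label vocabulary; duplicates collapse, unknown labels warn (or
    raise with ``strict=True``)."""
    canon = {canonical_use(u) for u in uses if str(u).strip()}
    unknown = canon - set(USE_VOCABULARY)
    if unknown:
        msg = f"unknown use labels (kept in the count): {sorted(unknown)}"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    return len(canon)


@dataclass
class ContingencyResult:
    table: np.ndarray
    chi_squared: float
    df: int
    p_value: float


def chisq_yates(table) -> ContingencyResult:
    """Pearson chi-squared with Yates' continuity correction on a 2x2
    table.

    chi2 = N (|ad - bc| - N/2)^2 / (r1 r2 c1 c2), with the corrected
    numerator floored at zero when |ad - bc| <= N/2; p from the upper
    tail of chi-squared with 1 df.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("cell counts must be nonnegative")
    a, b = t[0]
    c, d = t[1]
    n = t.sum()
    if n <= 0:
        raise DegenerateMarginError("empty table")
    r1, r2 = t.sum(axis=1)
    c1, c2 = t.sum(axis=0)
    if min(r1, r2, c1, c2) == 0:
        raise DegenerateMarginError(
            "degenerate margin: a row or column of the 2x2 table is all zero"
        )
    corrected = max(abs(a * d - b * c) - n / 2.0, 0.0)
    chi2 = n * corrected**2 / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(chi2, df=1))
    return ContingencyResult(table=t, chi_squared=float(chi2), df=1, p_value=p)


def use_decline_association(
    table: pd.DataFrame,
    use: str,
    decline_threshold: float = 0.0,
) -> ContingencyResult:
    """2x2 association between having a use and being in decline.

    "Declining" means ``global_decline > decline_threshold``. The use
    column may be a wide 0/1 column ``use_<name>`` or derived from the
    semicolon-delimited ``uses`` column.
    """
    use = canonical_use(use)
    col = f"use_{use}"
    if col in table.columns:
        has_use = table[col].astype(bool)
    elif "uses" in table.columns:
        has_use = table["uses"].fillna("").map(
            lambda s: use in {canonical_use(u) for u in str(s).split(";") if u.strip()}
        )
    else:
        raise KeyError(f"no '{col}' or 'uses' column in the species table")
    declining = table["global_decline"].astype(float) > decline_threshold
    counts = np.array(
        [
            [int((has_use & declining).sum()), int((has_use & ~declining).sum())],
            [int((~has_use & declining).sum()), int((~has_use & ~declining).sum())],
        ]
    )
    return chisq_yates(counts)


# ---------------------------------------------------------------------
# Model-frame assembly
# ---------------------------------------------------------------------

# variables that can legitimately be zero get the log10(x + 1) offset;
# strictly positive variables are transformed as log10(x). Any other
# variable containing a non-positive value falls back to the offset.
_OFFSET_VARS = {"global_decline", "human_pressure"}
_EXCLUDED_CATEGORIES = ("DD", "EW", "EX")


@dataclass
class ModelFrame:
    """Aligned, transformed response and predictors plus the matching
    pruned covariance; row order is shared by every field."""

    species: list[str]
    response_name: str
    predictor_names: list[str]
    y: np.ndarray
    X: np.ndarray
    vcv: PhyloCovariance
    dropped: dict[str, str] = field(default_factory=dict)
    transform_log: dict[str, str] = field(default_factory=dict)


def _log10_transform(name: str, values: np.ndarray) -> tuple[np.ndarray, str]:
    values = np.asarray(values, dtype=float)
    if name in _OFFSET_VARS or np.nanmin(values) <= 0:
        return np.log10(values + 1.0), "log10(x+1)"
    return np.log10(values), "log10(x)"


def build_model_frame(
    table: pd.DataFrame,
    tree: Phylogeny,
    response: str,
    predictors: list[str],
    probability_map: ExtinctionProbabilityMap | None = None,
    include_unrankable: bool = False,
) -> ModelFrame:
    """Assemble a complete-case, log10-transformed PGLS frame.

    Species are dropped (with a reason recorded in ``dropped``) when
    they are absent from the tree, lack any model variable, or carry a
    DD/EW/EX category while ``response == "extinction_probability"``.
    The covariance matrix is pruned to the retained species, in frame
    row order.
    """
    df = table.copy()
    if "species" not in df.columns:
        raise ValueError("species table needs a 'species' column")
    df = df.set_index("species", drop=False)

    dropped: dict[str, str] = {}
    tips = set(tree.tip_labels)
    for sp in df.index:
        if sp not in tips:
            dropped[sp] = "not in tree"
    df = df.loc[[s for s in df.index if s not in dropped]]

    if response == "extinction_probability" and "extinction_probability" not in df.columns:
        mapping = probability_map or default_probability_map()
        probs = {}
        for sp, cat in df["iucn_category"].items():
            cat = str(cat).strip().upper()
            if cat in _EXCLUDED_CATEGORIES and not include_unrankable:
                dropped[sp] = f"category {cat} excluded from probability models"
            elif cat not in mapping:
                dropped[sp] = f"unmapped category {cat}"
            else:
                probs[sp] = mapping[cat]
        df = df.loc[[s for s in df.index if s not in dropped]]
        df["extinction_probability"] = pd.Series(probs)

    needed = [response] + list(predictors)
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise KeyError(f"missing model columns: {missing_cols}")

    for sp in df.index:
        vals = df.loc[sp, needed]
        if pd.isna(pd.to_numeric(vals, errors="coerce")).any():
            dropped[sp] = "missing value (listwise deletion)"
    df = df.loc[[s for s in df.index if s not in dropped]]

    q = len(predictors)
    if len(df) < q + 2:
        raise ValueError(
            f"only {len(df)} complete cases for {q} predictors; need >= {q + 2}"
        )

    transform_log: dict[str, str] = {}
    y, transform_log[response] = _log10_transform(
        response, df[response].to_numpy(dtype=float)
    )
    cols = []
    for name in predictors:
        col, transform_log[name] = _log10_transform(
            name, df[name].to_numpy(dtype=float)
        )
        cols.append(col)
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))

    vcv = phylo_vcv(tree).subset(df.index.tolist())
    return ModelFrame(
        species=df.index.tolist(),
        response_name=response,
        predictor_names=list(predictors),
        y=y,
        X=X,
        vcv=vcv,
        dropped=dropped,
        transform_log=transform_log,
    )


# ---------------------------------------------------------------------
# Species-table I/O
# ---------------------------------------------------------------------


def read_species_table(path) -> pd.DataFrame:
    """Read the per-species CSV; derives ``human_pressure`` from the
    semicolon-delimited ``uses`` column when absent."""
    df = pd.read_csv(path)
    if "species" not in df.columns:
        raise ValueError("species table needs a 'species' column")
    if "human_pressure" not in df.columns:
        if "uses" in df.columns:
            df["human_pressure"] = df["uses"].fillna("").map(
                lambda s: len({canonical_use(u) for u in str(s).split(";") if u.strip()})
            )
        else:
            use_cols = [c for c in df.columns if c.startswith("use_")]
            if use_cols:
                df["human_pressure"] = df[use_cols].astype(int).sum(axis=1)
    return df


def write_species_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
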