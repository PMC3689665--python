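"""Config-driven orchestration of the full analysis sequence.

Stages, in order: spatial layers and their pairwise correlations;
regional NRI/NTI; phylogenetic signal (Blomberg's K) in extinction
probability and global decline; PGLS model tables for both responses;
per-use chi-squared tests of association with decline (raw and
Holm-adjusted p). Every stage writes plain CSV (grids additionally as
ESRI ASCII) and a machine-readable JSON manifest records seeds and
dropped-record counts.

All randomness flows from one master seed, split per stage with a fixed
``SeedSequence`` scheme: stream 0 -> community null models, stream 1 ->
signal permutations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community as comm
from . import comparative, grids, risk, tree as treemod

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "default_models"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    tree_path: str
    species_path: str
    assemblages_path: str
    ranges_path: str
    out_dir: str
    probability_map_path: str | None = None
    seed: int = 0
    n_reps: int = 999
    n_perm: int = 999
    cell_size_deg: float = 0.25
    decline_threshold: float = 0.0
    min_richness: int = 1
    extent: tuple[float, float, float, float] | None = None
    models: list[dict] | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        base = Path(path).parent
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("tree_path", "species_path", "assemblages_path",
                    "ranges_path", "probability_map_path", "out_dir"):
            if raw.get(key):
                p = Path(raw[key])
                raw[key] = str(p if p.is_absolute() else base / p)
        if raw.get("extent"):
            raw["extent"] = tuple(float(v) for v in raw["extent"])
        return cls(**raw)

    def validate(self) -> None:
        missing = [
            p
            for p in (
                self.tree_path,
                self.species_path,
                self.assemblages_path,
                self.ranges_path,
                self.probability_map_path,
            )
            if p and not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")


def default_models(table: pd.DataFrame) -> list[dict]:
    """The fixed model set: per response, univariate models on every
    available predictor plus two 4-predictor multivariate models."""
    base = ["human_pressure", "bl", "ed", "fd", "h_max", "propagule_size"]
    predictors = [p for p in base if p == "ed" or p in table.columns]
    models = []
    for response in ("global_decline", "extinction_probability"):
        for pred in predictors:
            models.append({"response": response, "predictors": [pred]})
        models.append(
            {
                "response": response,
                "predictors": ["propagule_size", "h_max", "bl", "human_pressure"],
            }
        )
        models.append(
            {
                "response": response,
                "predictors": ["propagule_size", "h_max", "ed", "human_pressure"],
            }
        )
    return models


def _holm(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment with monotonicity enforcement."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def _check_names(tree, table, assemblages, ranges) -> list[str]:
    problems = []
    tips = set(tree.tip_labels)
    table_sp = set(table["species"])
    for asm in assemblages:
        extra = set(asm.members) - tips
        if extra:
            problems.append(
                f"assemblage {asm.region_name!r}: species not in tree: {sorted(extra)}"
            )
    extra_ranges = set(ranges) - table_sp
    if extra_ranges:
        problems.append(
            f"ranges for species not in table: {sorted(extra_ranges)}"
        )
    return problems


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to
    ``manifest.json`` in the output directory)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "load-inputs"
    try:
        tree = treemod.read_newick_file(config.tree_path)
        table = risk.read_species_table(config.species_path)
        assemblages = comm.read_assemblages_csv(config.assemblages_path)
        ranges = grids.read_ranges_csv(config.ranges_path)
        prob_map = (
            risk.load_probability_map(config.probability_map_path)
            if config.probability_map_path
            else risk.default_probability_map()
        )
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    problems = _check_names(tree, table, assemblages, ranges)
    if problems:
        raise PipelineError(
            "stage preflight: name mismatches:\n  " + "\n  ".join(problems)
        )

    ss = np.random.SeedSequence(config.seed)
    streams = ss.spawn(2)
    seed_community = int(streams[0].generate_state(1)[0])
    seed_signal = int(streams[1].generate_state(1)[0])

    manifest: dict = {
        "seed": config.seed,
        "stage_seeds": {"community": seed_community, "signal": seed_signal},
        "n_species_table": int(len(table)),
        "n_tips": tree.n_tips,
        "counts_dropped": {},
        "outputs": [],
    }

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, index=False, float_format="%.10g")
        manifest["outputs"].append(name)

    # -- stage 1: per-species metrics + spatial layers ------------------
    stage = "metrics"
    try:
        ed = treemod.fair_proportion_ed(tree)
        bl = treemod.terminal_branch_lengths(tree)
        treemod.write_metrics_csv(out / "metrics.csv", tree)
        manifest["outputs"].append("metrics.csv")
        if "ed" not in table.columns:
            table = table.assign(ed=table["species"].map(ed))
        if "bl" not in table.columns:
            table = table.assign(bl=table["species"].map(bl))
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    stage = "grid"
    try:
        if config.extent is not None:
            extent = config.extent
        else:
            rects = [r for shapes in ranges.values() for r in shapes]
            extent = (
                min(r[0] for r in rects),
                min(r[1] for r in rects),
                max(r[2] for r in rects),
                max(r[3] for r in rects),
            )
        grid = grids.make_grid(extent, config.cell_size_deg)
        occ = grids.rasterize_ranges(ranges, grid)
        decline = dict(zip(table["species"], table["global_decline"].astype(float)))
        layers = {
            "richness": grids.richness_layer(occ),
            "mean_decline": grids.mean_metric_layer(occ, decline),
            "mean_ed": grids.mean_metric_layer(occ, ed),
            "mean_bl": grids.mean_metric_layer(occ, bl),
        }
        for name, layer in layers.items():
            grids.write_ascii_grid(layer, out / f"layer_{name}.asc")
            grids.write_layer_csv(layer, out / f"layer_{name}.csv")
            manifest["outputs"] += [f"layer_{name}.asc", f"layer_{name}.csv"]
        rows = []
        names = list(layers)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                r, p, n_cells = grids.layer_correlation(
                    layers[names[i]],
                    layers[names[j]],
                    min_richness=config.min_richness,
                    richness=layers["richness"],
                )
                rows.append(
                    {
                        "layer_a": names[i],
                        "layer_b": names[j],
                        "pearson_r": r,
                        "p_value": p,
                        "n_cells": n_cells,
                    }
                )
        emit("layer_correlations.csv", pd.DataFrame(rows))
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    # -- stage 2: regional community structure --------------------------
    stage = "community"
    try:
        community_df = comm.regional_structure(
            tree, assemblages, n_reps=config.n_reps, seed=seed_community
        )
        emit("community.csv", community_df)
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    # -- stage 3: phylogenetic signal ------------------------------------
    stage = "signal"
    try:
        vcv = treemod.phylo_vcv(tree)
        signal_rows = []
        sig_ss = np.random.SeedSequence(seed_signal).spawn(2)
        for k, trait_name in enumerate(("extinction_probability", "global_decline")):
            frame = risk.build_model_frame(
                table, tree, trait_name, [], probability_map=prob_map
            )
            res = comparative.k_signal_test(
                frame.vcv,
                dict(zip(frame.species, frame.y)),
                n_perm=config.n_perm,
                seed=int(sig_ss[k].generate_state(1)[0]),
            )
            signal_rows.append(
                {
                    "trait": trait_name,
                    "k": res.k_value,
                    "p_permutation": res.p_permutation,
                    "n_perm": res.n_perm,
                    "n_species": len(frame.species),
                    "seed": res.seed,
                }
            )
            manifest["counts_dropped"][f"signal_{trait_name}"] = len(frame.dropped)
        emit("signal.csv", pd.DataFrame(signal_rows))
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    # -- stage 4: PGLS model tables --------------------------------------
    stage = "pgls"
    try:
        models = config.models or default_models(table)
        pgls_rows = []
        for m_idx, model in enumerate(models):
            response = model["response"]
            predictors = list(model["predictors"])
            frame = risk.build_model_frame(
                table, tree, response, predictors, probability_map=prob_map
            )
            fit = comparative.pgls_fit(
                frame.vcv,
                frame.y,
                frame.X,
                lambda_spec=model.get("lambda", "ML"),
                response_name=response,
                predictor_names=predictors,
            )
            multivariate = len(predictors) > 1
            r2 = fit.r_squared_adjusted if multivariate else fit.r_squared_multiple
            for c_idx, name in enumerate(fit.coef_names):
                pgls_rows.append(
                    {
                        "model": f"{response} ~ {' + '.join(predictors)}",
                        "model_index": m_idx,
                        "response": response,
                        "term": name,
                        "estimate": fit.coefficients[c_idx],
                        "std_error": fit.standard_errors[c_idx],
                        "t_value": fit.t_values[c_idx],
                        "p_value": fit.p_values[c_idx],
                        "lambda": fit.lambda_,
                        "log_likelihood": fit.log_likelihood,
                        "r_squared": r2,
                        "r_squared_kind": "adjusted" if multivariate else "multiple",
                        "model_p": fit.model_p,
                        "n_species": fit.n_species,
                    }
                )
            manifest["counts_dropped"][f"pgls_model_{m_idx}"] = len(frame.dropped)
        emit("pgls.csv", pd.DataFrame(pgls_rows))
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    # -- stage 5: per-use chi-squared tests -------------------------------
    stage = "uses"
    try:
        use_rows = []
        for use in risk.USE_VOCABULARY:
            try:
                res = risk.use_decline_association(
                    table, use, config.decline_threshold
                )
                use_rows.append(
                    {
                        "use": use,
                        "chi_squared": res.chi_squared,
                        "df": res.df,
                        "p_value": res.p_value,
                        "n_with_use": int(res.table[0].sum()),
                        "diagnostic": "",
                    }
                )
            except risk.DegenerateMarginError as exc:
                use_rows.append(
                    {
                        "use": use,
                        "chi_squared": np.nan,
                        "df": 1,
                        "p_value": np.nan,
                        "n_with_use": np.nan,
                        "diagnostic": str(exc),
                    }
                )
        uses_df = pd.DataFrame(use_rows)
        valid = uses_df["p_value"].notna()
        adjusted = np.full(len(uses_df), np.nan)
        if valid.any():
            adjusted[valid.to_numpy()] = _holm(uses_df.loc[valid, "p_value"].to_numpy())
        uses_df["p_holm"] = adjusted
        emit("uses_chisq.csv", uses_df)
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    manifest["outputs"].append("manifest.json")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
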