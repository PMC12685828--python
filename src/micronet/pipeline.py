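"""End-to-end orchestration: simulate or ingest, then run every analysis
stage and write a consolidated JSON report.

Each stochastic stage gets its own seed derived by hashing
(global seed, stage name), so adding a stage never shifts another
stage's random stream, and the whole run is byte-identical under a fixed
global seed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .coocnet import (
    build_network, complexity_index, robustness, topology, vulnerability,
)
from .dbrda import dbrda_fit
from .diversity import alpha_diversity, bray_curtis, permanova
from .exceptions import MicronetError, StageError, ValidationError
from .lefse import run_lefse
from .soil_stats import lsd_letters, marginal_means, two_factor_block_anova
from .synthetic import DOMAINS, PRESETS, SimulationResult, simulate_dataset
from .tables_io import (
    SOIL_VARIABLES, TREATMENTS, read_feature_table, read_metadata,
    read_soil_table, read_taxonomy, write_feature_table, write_metadata,
    write_soil_table,
)

REPORT_SCHEMA_VERSION = 1


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    """Inputs (or a simulation preset) plus per-stage parameters."""

    seed: int = 0
    out_dir: str | Path | None = None
    preset: str | None = "paper"
    design: "object | None" = None  # a CommunityDesign overrides preset
    feature_tables: dict[str, str | Path] | None = None  # domain -> path
    metadata_path: str | Path | None = None
    soil_path: str | Path | None = None
    taxonomy_paths: dict[str, str | Path] | None = None
    n_permutations: int = 999
    lefse_alpha: float = 0.05
    lda_threshold: float = 2.0
    lefse_n_boot: int = 30
    network_method: str = "spearman"
    r_threshold: float = 0.6
    q_threshold: float = 0.05
    min_prevalence: float = 1.0 / 3.0
    removal_fractions: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9)
    robustness_repetitions: int = 100
    dbrda_variables: tuple[str, ...] = ("TP", "AP", "pH", "EOC")
    soil_variables: tuple[str, ...] = SOIL_VARIABLES


def _load_inputs(config: RunConfig):
    if config.design is not None:
        sim = simulate_dataset(
            config.design, seed=stage_seed(config.seed, "simulate")
        )
        return sim.feature_tables, sim.metadata, sim.soil, {d: None
                                                            for d in DOMAINS}
    if config.preset is not None:
        if config.preset not in PRESETS:
            raise ValidationError(
                f"unknown preset {config.preset!r}; allowed: "
                f"{sorted(PRESETS)}"
            )
        sim = simulate_dataset(
            PRESETS[config.preset](), seed=stage_seed(config.seed, "simulate")
        )
        return sim.feature_tables, sim.metadata, sim.soil, {d: None
                                                            for d in DOMAINS}
    if not (config.feature_tables and config.metadata_path
            and config.soil_path):
        raise ValidationError(
            "either a preset or feature_tables + metadata_path + soil_path "
            "must be given"
        )
    tables = {
        domain: read_feature_table(path)
        for domain, path in config.feature_tables.items()
    }
    first = next(iter(tables.values()))
    meta = read_metadata(config.metadata_path, feature_table=first)
    soil = read_soil_table(config.soil_path, metadata=meta)
    taxonomies = {
        domain: (
            read_taxonomy(config.taxonomy_paths[domain])
            if config.taxonomy_paths and domain in config.taxonomy_paths
            else None
        )
        for domain in tables
    }
    return tables, meta, soil, taxonomies


def _soil_stage(config: RunConfig, soil: pd.DataFrame,
                meta: pd.DataFrame) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for var in config.soil_variables:
        if var not in soil.columns:
            continue
        values = soil[var]
        anova = two_factor_block_anova(values, meta)
        letters = lsd_letters(
            values, meta,
            ms_residual=anova.ms_residual,
            df_residual=anova.df_residual,
        )
        out[var] = {
            "anova": {
                term: {
                    "df": int(anova.table.loc[term, "df"]),
                    "SS": float(anova.table.loc[term, "SS"]),
                    "F": _maybe_float(anova.table.loc[term, "F"]),
                    "p": _maybe_float(anova.table.loc[term, "p"]),
                }
                for term in ("block", "location", "treatment",
                             "location:treatment")
            },
            "groups": {
                g: {
                    "mean": float(row["mean"]),
                    "sd": float(row["sd"]),
                    "letters": row["letters"],
                }
                for g, row in letters.table.iterrows()
            },
            "marginal_means": {
                factor: {
                    str(level): float(v)
                    for level, v in marginal_means(values, meta,
                                                   factor).items()
                }
                for factor in ("location", "treatment")
            },
        }
    return out


def _maybe_float(x) -> float | None:
    return float(x) if np.isfinite(x) else None


def run_all(config: RunConfig) -> dict[str, Any]:
    """Run every stage; returns (and optionally writes) the report."""
    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "manifest": {
            "package_version": __version__,
            "seed": config.seed,
            "preset": config.preset,
            "parameters": {
                "n_permutations": config.n_permutations,
                "lefse_alpha": config.lefse_alpha,
                "lda_threshold": config.lda_threshold,
                "network_method": config.network_method,
                "r_threshold": config.r_threshold,
                "q_threshold": config.q_threshold,
                "min_prevalence": config.min_prevalence,
                "removal_fractions": list(config.removal_fractions),
                "robustness_repetitions": config.robustness_repetitions,
                "dbrda_variables": list(config.dbrda_variables),
            },
            "stage_seeds": {
                stage: stage_seed(config.seed, stage)
                for stage in ("simulate", "permanova", "lefse",
                              "robustness", "dbrda")
            },
        },
    }

    stage = "load"
    try:
        tables, meta, soil, taxonomies = _load_inputs(config)

        stage = "soil_stats"
        report["soil"] = _soil_stage(config, soil, meta)

        report["domains"] = {}
        for domain, table in tables.items():
            dom: dict[str, Any] = {}

            stage = f"diversity:{domain}"
            alpha = alpha_diversity(table)
            dom["alpha_diversity"] = {
                "per_group_mean": {
                    g: {
                        k: float(v)
                        for k, v in alpha.loc[
                            meta.index[meta["group"] == g]
                        ].mean().items()
                    }
                    for g in sorted(set(meta["group"]))
                }
            }
            dm = bray_curtis(table)

            stage = f"permanova:{domain}"
            perm = permanova(
                dm, list(meta.loc[table.sample_ids, "group"]),
                n_permutations=config.n_permutations,
                seed=stage_seed(config.seed, f"permanova:{domain}"),
            )
            dom["permanova"] = {
                "pseudo_F": perm.pseudo_f,
                "R2": perm.r_squared,
                "p": perm.p_value,
                "n_permutations": perm.n_permutations,
            }

            stage = f"lefse:{domain}"
            lefse_frame = run_lefse(
                table,
                list(meta.loc[table.sample_ids, "treatment"]),
                taxonomy=taxonomies.get(domain),
                alpha=config.lefse_alpha,
                lda_threshold=config.lda_threshold,
                n_boot=config.lefse_n_boot,
                seed=stage_seed(config.seed, f"lefse:{domain}"),
            )
            hits = lefse_frame[lefse_frame["reported"]]
            dom["lefse"] = {
                "n_features_tested": int(len(lefse_frame)),
                "n_reported": int(len(hits)),
                "hits": [
                    {
                        "feature": row["feature"],
                        "rank": row["rank"],
                        "class": row["class"],
                        "p": float(row["p"]),
                        "effect": float(row["effect"]),
                    }
                    for _, row in hits.iterrows()
                ],
            }

            stage = f"network:{domain}"
            summaries = {}
            networks = {}
            for treatment in TREATMENTS:
                sample_ids = list(meta.index[meta["treatment"] == treatment])
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    net = build_network(
                        table, sample_ids,
                        method=config.network_method,
                        r_threshold=config.r_threshold,
                        q_threshold=config.q_threshold,
                        min_prevalence=config.min_prevalence,
                        taxonomy=taxonomies.get(domain),
                    )
                networks[treatment] = net
                summaries[treatment] = topology(net)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    complexity = complexity_index(summaries)
            except ValidationError:
                complexity = {t: None for t in TREATMENTS}
            dom["networks"] = {}
            for treatment, net in networks.items():
                summ = summaries[treatment]
                entry: dict[str, Any] = {
                    "topology": summ.as_dict(),
                    "complexity": complexity[treatment],
                }
                try:
                    curve = robustness(
                        net,
                        removal_fractions=config.removal_fractions,
                        repetitions=config.robustness_repetitions,
                        seed=stage_seed(
                            config.seed,
                            f"robustness:{domain}:{treatment}",
                        ),
                    )
                    entry["robustness"] = {
                        f"{row.p:g}": {"mean": row.mean, "sd": row.sd}
                        for row in curve.itertuples(index=False)
                    }
                except ValidationError:
                    entry["robustness"] = None
                try:
                    entry["vulnerability"] = vulnerability(net)
                except ValidationError:
                    entry["vulnerability"] = None
                dom["networks"][treatment] = entry

            stage = f"dbrda:{domain}"
            variables = [
                v for v in config.dbrda_variables if v in soil.columns
            ]
            result = dbrda_fit(
                dm, soil, variables,
                n_permutations=config.n_permutations,
                seed=stage_seed(config.seed, f"dbrda:{domain}"),
            )
            dom["dbrda"] = {
                "axis_percent": [float(v) for v in result.axis_percent],
                "constrained_percent": result.constrained_percent,
                "variables": {
                    var: {
                        "r2": float(row["r2"]),
                        "p": float(row["p"]),
                        "axis1_correlation": float(row["axis1_correlation"]),
                    }
                    for var, row in result.variable_tests.iterrows()
                },
            }

            report["domains"][domain] = dom
    except MicronetError as exc:
        report["partial"] = True
        report["failed_stage"] = stage
        if config.out_dir is not None:
            _write_report(report, config.out_dir)
        raise StageError(stage, str(exc)) from exc

    report["partial"] = False
    if config.out_dir is not None:
        _write_report(report, config.out_dir)
    return report


def _write_report(report: dict[str, Any], out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(report_json(report))


def report_json(report: dict[str, Any]) -> str:
    return json.dumps(report, indent=2, sort_keys=True)


def write_simulation(sim: SimulationResult, out_dir: str | Path) -> None:
    """Write the four TSVs plus a truth JSON for a simulated dataset."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for domain, table in sim.feature_tables.items():
        write_feature_table(table, out_dir / f"features_{domain}.tsv")
    write_metadata(sim.metadata, out_dir / "metadata.tsv")
    write_soil_table(sim.soil, out_dir / "soil.tsv")
    truth = {
        "differential": sim.truth.differential.to_dict(orient="records"),
        "modules": [
            {
                "domain": m.domain,
                "treatment": m.treatment,
                "taxon_ids": m.taxon_ids,
                "rho": m.rho,
                "signs": [float(s) for s in m.signs],
            }
            for m in sim.truth.modules
        ],
        "env_links": {
            k: list(v) for k, v in sim.truth.env_links.items()
        },
    }
    (out_dir / "truth.json").write_text(
        json.dumps(truth, indent=2, sort_keys=True)
    )
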