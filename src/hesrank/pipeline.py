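"""Orchestration of the four-stage assessment workflow.

compile -> weight -> rank -> cluster (-> compare), driven by a single
declarative YAML configuration.  Every (region, period) input matrix is
weighted by entropy, ranked by CoCoSo and tiered by K-means; when two
comparison periods are configured the weight deltas and rank shifts are
added, and a sub-indicator panel (if given) yields per-tier profile
means.  All artifacts are written to the output directory together with
a run manifest (config echo, seed, package versions) and a structured
per-stage log, so a run can be reproduced from its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import (
    DEFAULT_LEVEL_NAMES,
    TierAssignment,
    assign_levels,
    attach_silhouette,
    kmeans_1d_optimal,
    kmeans_lloyd,
)
from .cocoso import CoCoSoResult, run_cocoso, write_ranking_csv
from .comparison import cluster_profiles, compare_regions, rank_shifts, weight_deltas
from .data_model import (
    DecisionMatrix,
    aggregate_periods,
    read_decision_matrix,
    read_subindicator_panel,
    write_decision_matrix,
)
from .entropy import WeightVector, compute_entropy_weights, write_weights_csv
from .synthetic import GeneratorSpec, TierStructure, generate_matrix, generate_tiered_matrix

__all__ = ["PipelineConfig", "run_assessment", "load_config"]

logger = logging.getLogger("hesrank")


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative description of one assessment run.

    ``inputs`` maps period label -> CSV path or generator spec mapping.
    ``aggregate`` optionally lists periods to combine into a mean matrix
    under ``aggregate_label``.  ``delta_periods`` names the (early, late)
    pair used for weight deltas and rank shifts.
    """

    inputs: Mapping[str, Any]
    region: str = ""
    lam: float = 0.5
    K: int = 5
    level_names: tuple[str, ...] = DEFAULT_LEVEL_NAMES
    solver: str = "exact"
    seed: int = 42
    output_dir: str = "hesrank_out"
    aggregate: tuple[str, ...] = ()
    aggregate_label: str = ""
    aggregate_method: str = "mean"
    delta_periods: tuple[str, str] | None = None
    panel: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lambda must be in [0, 1], got {self.lam}")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if len(self.level_names) != self.K:
            raise ValueError(
                f"need {self.K} level names, got {len(self.level_names)}"
            )
        if self.solver not in ("exact", "lloyd"):
            raise ValueError(f"solver must be 'exact' or 'lloyd', got {self.solver!r}")
        if not self.inputs:
            raise ValueError("at least one input matrix is required")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline configuration from YAML."""
    raw = yaml.safe_load(Path(path).read_text())
    agg = raw.get("aggregate") or {}
    return PipelineConfig(
        inputs=raw["inputs"],
        region=raw.get("region", ""),
        lam=float(raw.get("lambda", 0.5)),
        K=int(raw.get("K", 5)),
        level_names=tuple(raw.get("level_names", DEFAULT_LEVEL_NAMES)),
        solver=raw.get("solver", "exact"),
        seed=int(raw.get("seed", 42)),
        output_dir=raw.get("output_dir", "hesrank_out"),
        aggregate=tuple(agg.get("periods", ())),
        aggregate_label=agg.get("label", ""),
        aggregate_method=agg.get("method", "mean"),
        delta_periods=tuple(raw["delta_periods"]) if raw.get("delta_periods") else None,
        panel=raw.get("panel"),
    )


def _load_input(period: str, source: Any, region: str, seed: int) -> DecisionMatrix:
    if isinstance(source, (str, Path)):
        return read_decision_matrix(source, region=region, period=period)
    if isinstance(source, Mapping):
        tiers = None
        if "tiers" in source:
            t = source["tiers"]
            tiers = TierStructure(
                means=tuple(t["means"]), sigma=float(t["sigma"]),
                sizes=tuple(t["sizes"]),
            )
        spec = GeneratorSpec(
            m=int(source.get("m", 27)),
            n=int(source.get("n", 6)),
            dispersion=tuple(source["dispersion"]) if "dispersion" in source else None,
            tiers=tiers,
            seed=int(source.get("seed", seed)),
        )
        matrix = (generate_tiered_matrix(spec)[0] if tiers is not None
                  else generate_matrix(spec))
        return DecisionMatrix(
            countries=matrix.countries,
            indicators=matrix.indicators,
            scores=matrix.scores,
            region=region or matrix.region,
            period=period,
            ghsi_scaled=matrix.ghsi_scaled,
        )
    raise TypeError(f"input for period {period!r} must be a path or generator spec")


def _cluster(values: np.ndarray, countries: Sequence[str],
             config: PipelineConfig) -> TierAssignment:
    if config.solver == "exact":
        ta = kmeans_1d_optimal(values, config.K, countries=countries)
    else:
        ta = kmeans_lloyd(values, config.K, seed=config.seed, countries=countries)
    ta = assign_levels(ta, config.level_names)
    return attach_silhouette(ta) if config.K > 1 else ta


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_assessment(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full workflow and write the report bundle.

    Returns the in-memory report: per-period weights
    (:class:`WeightVector`), CoCoSo results and tier assignments, plus
    comparison outputs when configured.  Artifacts written:
    ``weights.csv``, ``cocoso.csv``, ``clusters.csv``, ``deltas.csv``,
    ``rank_shifts.csv``, ``cluster_profiles.csv``, ``report.json`` and
    ``run_manifest.json``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    matrices: dict[str, DecisionMatrix] = {}
    for period, source in config.inputs.items():
        logger.info("stage=compile period=%s", period)
        matrices[period] = _load_input(period, source, config.region, config.seed)

    if config.aggregate:
        try:
            members = [matrices[p] for p in config.aggregate]
        except KeyError as exc:
            raise ValueError(f"aggregate period {exc} has no input") from exc
        label = config.aggregate_label or "-".join(config.aggregate)
        logger.info("stage=aggregate periods=%s label=%s", config.aggregate, label)
        matrices[label] = aggregate_periods(
            members, method=config.aggregate_method, period_label=label
        )

    weights: dict[str, WeightVector] = {}
    rankings: dict[str, CoCoSoResult] = {}
    tiers: dict[str, TierAssignment] = {}
    for period, matrix in matrices.items():
        logger.info("stage=weight period=%s m=%d n=%d", period, matrix.m, matrix.n)
        weights[period] = compute_entropy_weights(matrix)
        logger.info("stage=rank period=%s lambda=%s", period, config.lam)
        rankings[period] = run_cocoso(matrix, weights[period], lam=config.lam)
        logger.info("stage=cluster period=%s K=%d solver=%s",
                    period, config.K, config.solver)
        tiers[period] = _cluster(rankings[period].C, matrix.countries, config)

    write_weights_csv(list(weights.values()), out / "weights.csv")
    cocoso_frames = []
    cluster_frames = []
    for period, res in rankings.items():
        frame = res.to_frame()
        frame.insert(0, "region", res.region)
        frame.insert(1, "period", period)
        cocoso_frames.append(frame)
        ta = tiers[period]
        cluster_frames.append(
            pd.DataFrame(
                {
                    "country": list(ta.countries),
                    "period": period,
                    "C": ta.values,
                    "level": ta.levels,
                    "level_name": [ta.level_name(lv) for lv in ta.levels],
                    "silhouette": (ta.per_point_silhouette
                                   if ta.per_point_silhouette is not None
                                   else np.nan),
                }
            )
        )
    pd.concat(cocoso_frames).to_csv(out / "cocoso.csv", index=False,
                                    float_format="%.17g")
    pd.concat(cluster_frames).to_csv(out / "clusters.csv", index=False,
                                     float_format="%.17g")

    report: dict[str, Any] = {
        "periods": {
            period: {
                "weights": dict(zip(wv.indicator_ids, wv.weights.tolist())),
                "entropy": dict(zip(wv.indicator_ids, wv.entropy.tolist())),
                "ranking": rankings[period].ordered_countries(),
                "centroids": sorted(tiers[period].centroids.tolist(), reverse=True),
                "cluster_sizes": {
                    int(lv): int((tiers[period].levels == lv).sum())
                    for lv in range(1, config.K + 1)
                },
                "silhouette_mean": tiers[period].silhouette_mean,
            }
            for period, wv in weights.items()
        }
    }

    if config.delta_periods is not None:
        early, late = config.delta_periods
        if early not in weights or late not in weights:
            raise ValueError(
                f"delta periods {config.delta_periods} not among inputs "
                f"{sorted(weights)}"
            )
        logger.info("stage=compare early=%s late=%s", early, late)
        delta = weight_deltas(weights[early], weights[late])
        pd.DataFrame(
            {
                "region": config.region,
                "indicator": list(delta.indicator_ids),
                "delta": delta.deltas,
            }
        ).to_csv(out / "deltas.csv", index=False, float_format="%.17g")
        shifts = rank_shifts(rankings[early], rankings[late])
        shifts.to_frame().to_csv(out / "rank_shifts.csv", index=False)
        report["comparison"] = {
            "delta_periods": [early, late],
            "weight_deltas": dict(zip(delta.indicator_ids, delta.deltas.tolist())),
            "rank_shift_counts": shifts.counts,
            "rank_shift_percentages": shifts.percentages,
        }

    if config.panel is not None:
        panel = read_subindicator_panel(config.panel)
        profile_frames = []
        for period, ta in tiers.items():
            prof = cluster_profiles(panel, ta).reset_index()
            prof.insert(0, "period", period)
            profile_frames.append(prof)
        pd.concat(profile_frames).to_csv(out / "cluster_profiles.csv",
                                         index=False, float_format="%.17g")

    comparison_table = compare_regions(
        list(weights.values()), delta_periods=config.delta_periods
    )
    comparison_table.to_csv(out / "comparison.csv", index=False,
                            float_format="%.17g")

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config": {
            "region": config.region,
            "lambda": config.lam,
            "K": config.K,
            "level_names": list(config.level_names),
            "solver": config.solver,
            "output_dir": str(config.output_dir),
            "aggregate": list(config.aggregate),
            "aggregate_label": config.aggregate_label,
            "delta_periods": (list(config.delta_periods)
                              if config.delta_periods else None),
            "panel": config.panel,
            "inputs": {
                p: (str(s) if isinstance(s, (str, Path)) else s)
                for p, s in config.inputs.items()
            },
        },
        "input_digests": {
            p: _digest(Path(s))
            for p, s in config.inputs.items()
            if isinstance(s, (str, Path)) and Path(s).exists()
        },
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "report.json").write_text(json.dumps(report, indent=2))

    return {
        "matrices": matrices,
        "weights": weights,
        "rankings": rankings,
        "tiers": tiers,
        "report": report,
        "manifest": manifest,
        "output_dir": out,
    }
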