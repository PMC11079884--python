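"""End-to-end orchestration: read -> grade filter -> impute -> compare ->
overabundance -> class-trend summary, with deterministic file outputs.

A run is fully described by a :class:`RunConfig`; running twice with the
same config and inputs produces byte-identical output files, and a JSON
manifest records the config, seed, and input checksums for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io_preprocess as iop
from .diffstats import ComparisonSpec, DiffResult, run_comparison, unique_significant_union
from .nomenclature import ClassCategory
from .overabundance import (
    DEFAULT_ALPHA_GRID,
    OverabundanceResult,
    make_overabundance_curve,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "class_trend_summary"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    intensities: str
    metadata: str | None = None
    comparisons: tuple[ComparisonSpec, ...] = (
        ComparisonSpec("cSCC", "Healthy"),
        ComparisonSpec("BCC", "Healthy"),
        ComparisonSpec("cSCC", "BCC"),
    )
    grades: frozenset[str] = frozenset({"A", "B"})
    impute_strategy: str = "none"
    t_variant: str = "student"
    log_scale: bool = False
    p_threshold: float = 0.05
    log2_threshold: float = 1.0
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID
    null_replicates: int = 2000
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self):
        if not self.comparisons:
            raise ValueError("at least one comparison is required")
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0, 1)")
        if self.log2_threshold <= 0:
            raise ValueError("log2_threshold must be positive")


@dataclass
class PipelineResult:
    diff_results: dict  # ComparisonSpec -> list[DiffResult]
    over_results: dict  # ComparisonSpec -> OverabundanceResult
    class_summary: pd.DataFrame
    union_count: int
    n_lipids_input: int
    n_lipids_tested: int
    written: list[Path] = field(default_factory=list)


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, write: bool = True) -> PipelineResult:
    """Execute the full differential-abundance analysis.

    Stages: read intensity + metadata tables, keep only lipids whose
    reliability grade is whitelisted, optionally impute missing values,
    run every configured two-group comparison (t test, fold change,
    volcano call), build the overabundance curve with its Monte-Carlo
    null envelope per comparison, summarize per-class trends, and count
    the union of significant lipids across comparisons. Outputs are
    written as deterministic CSVs plus a JSON run manifest.
    """
    table = iop.read_lipid_table(config.intensities, config.metadata)
    n_input = table.n_lipids
    table = iop.filter_by_grade(table, set(config.grades))
    table = iop.impute_missing(table, config.impute_strategy)
    logger.info("testing %d of %d lipids", table.n_lipids, n_input)

    diff_results: dict[ComparisonSpec, list[DiffResult]] = {}
    over_results: dict[ComparisonSpec, OverabundanceResult] = {}
    for spec in config.comparisons:
        results = run_comparison(
            table,
            spec,
            variant=config.t_variant,
            log_scale=config.log_scale,
            p_threshold=config.p_threshold,
            log2_threshold=config.log2_threshold,
        )
        diff_results[spec] = results
        over_results[spec] = make_overabundance_curve(
            [r.p_value for r in results],
            table.n_lipids,
            alphas=config.alpha_grid,
            n_null_replicates=config.null_replicates,
            seed=config.seed,
        )
        n_sig = sum(r.p_value < config.p_threshold for r in results)
        logger.info("%s: %d/%d lipids at p < %g", spec.tag, n_sig, table.n_lipids, config.p_threshold)

    summary = class_trend_summary(diff_results)
    union = unique_significant_union(diff_results.values(), config.p_threshold)

    result = PipelineResult(
        diff_results=diff_results,
        over_results=over_results,
        class_summary=summary,
        union_count=union,
        n_lipids_input=n_input,
        n_lipids_tested=table.n_lipids,
    )
    if write:
        result.written = _write_outputs(config, result)
    return result


def _write_outputs(config: RunConfig, result: PipelineResult) -> list[Path]:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = iop.write_results(
        {spec.tag: res for spec, res in result.diff_results.items()},
        {spec.tag: res for spec, res in result.over_results.items()},
        out_dir,
    )
    summary_path = out_dir / "class_trend_summary.csv"
    result.class_summary.to_csv(summary_path, index=False)
    written.append(summary_path)

    manifest = {
        "config": _config_dict(config),
        "inputs": {
            "intensities_sha256": _checksum(config.intensities),
            "metadata_sha256": _checksum(config.metadata) if config.metadata else None,
        },
        "n_lipids_input": result.n_lipids_input,
        "n_lipids_tested": result.n_lipids_tested,
        "union_significant": result.union_count,
    }
    manifest_path = out_dir / "run_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(manifest_path)
    return written


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["comparisons"] = [f"{c.group1}:{c.group2}" for c in config.comparisons]
    d["grades"] = sorted(config.grades)
    d["alpha_grid"] = list(config.alpha_grid)
    return d


def class_trend_summary(diff_results: dict) -> pd.DataFrame:
    """Per-comparison, per-category counts of volcano calls.

    For each comparison and each lipid class category: how many lipids
    were called up, down, or not significant, and the dominant direction
    among the significant ones ('up', 'down', 'mixed', or 'none'). This
    is the table behind statements like "all under-expressed lipids in
    the tumor group were diglycerides".
    """
    rows = []
    for spec, results in diff_results.items():
        by_cat: dict[ClassCategory, dict[str, int]] = {}
        for r in results:
            counts = by_cat.setdefault(r.category, {"up": 0, "down": 0, "not_significant": 0})
            counts[r.call] += 1
        for cat in sorted(by_cat, key=lambda c: c.value):
            counts = by_cat[cat]
            up, down = counts["up"], counts["down"]
            if up and down:
                dominant = "mixed"
            elif up:
                dominant = "up"
            elif down:
                dominant = "down"
            else:
                dominant = "none"
            rows.append(
                {
                    "comparison": spec.tag,
                    "category": cat.value,
                    "up": up,
                    "down": down,
                    "not_significant": counts["not_significant"],
                    "dominant_direction": dominant,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["comparison", "category", "up", "down", "not_significant", "dominant_direction"],
    )
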