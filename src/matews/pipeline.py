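"""End-to-end pipeline: cohort in, report bundle out.

Produces, in an output directory: ``table1.csv`` (triggered proportions per
outcome subgroup), ``table2.csv`` (diagnostic accuracy vs SMO), ``zones.csv``
(ROC-plane efficacy zones), ``missingness.csv``, optionally
``ml_metrics.csv``, and a ``manifest.json`` recording the rule-set checksum,
seed and package version. Re-running on identical inputs and seed reproduces
byte-identical reports.
"""

from __future__ import annotations

import json
import logging
import shutil
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .cohort import PatientRecord, read_cohort
from .diagnostics import format_performance_report, performance_report, triggered_proportions
from .missingness import missing_rates
from .ml import MLProtocolConfig, cross_validate, feature_table, rank_attributes, stratified_split
from .scores import Registry, load_score_definitions, score_cohort
from .zones import DEFAULT_ZONES, ZoneConfig, zone_table

log = logging.getLogger("matews")

__all__ = ["run_pipeline", "PipelineWarning"]


class PipelineWarning(UserWarning):
    pass


def run_pipeline(
    cohort: Sequence[PatientRecord] | str | Path,
    out_dir: str | Path,
    score_config: Optional[str] = None,
    zone_config: ZoneConfig = DEFAULT_ZONES,
    stratify_by: Optional[str] = None,
    run_ml: bool = False,
    seed: int = 0,
    strict: bool = False,
) -> dict:
    """Run scoring, diagnostics, zones, missingness (and optionally the ML
    protocol) and write the report bundle. Returns a summary dict with file
    paths and warnings. Partial outputs are removed on failure."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    warnings_seen: list[str] = []

    try:
        if not isinstance(cohort, (list, tuple)):
            log.info("reading cohort from %s", cohort)
            cohort = read_cohort(cohort)
        registry = load_score_definitions(score_config)
        log.info("scoring %d women against %d systems", len(cohort), len(registry))
        matrix = score_cohort(registry, cohort)

        t1 = triggered_proportions(matrix, cohort)
        _write(t1, out / "table1.csv", written)

        report = performance_report(matrix, cohort, stratify_by=stratify_by)
        if report["undefined"].astype(str).str.len().gt(0).any():
            warnings_seen.append("some diagnostic metrics undefined (degenerate strata/cells)")
        _write(format_performance_report(report), out / "table2.csv", written)

        zones = zone_table(report, zone_config)
        _write(zones, out / "zones.csv", written)

        miss = missing_rates(cohort, by_day=True)
        miss["pct_missing"] = miss["pct_missing"].round(1)
        _write(miss, out / "missingness.csv", written)

        if run_ml:
            log.info("running marker-combination ML protocol")
            ft = feature_table(cohort)
            y = ft.pop("smo")
            cfg = MLProtocolConfig(seed=seed)
            X_tr, _, y_tr, _ = stratified_split(ft, y, cfg)
            ranked = rank_attributes(X_tr, y_tr, cfg.n_bins)
            metrics = cross_validate(X_tr, y_tr, cfg, ranked)
            _write(metrics, out / "ml_metrics.csv", written)

        manifest = {
            "package_version": __version__,
            "seed": seed,
            "n_women": len(cohort),
            "n_scores": len(registry),
            "score_config_sha256": registry.sha256,
            "score_config_source": registry.source,
            "stratify_by": stratify_by,
            "outputs": sorted(p.name for p in written),
            "warnings": warnings_seen,
        }
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written.append(manifest_path)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise

    if strict and warnings_seen:
        raise RuntimeError("degenerate-data warnings escalated under strict mode: "
                           + "; ".join(warnings_seen))
    return {"outputs": [str(p) for p in written], "warnings": warnings_seen}


def _write(df, path: Path, written: list[Path]) -> None:
    df.to_csv(path, index=False)
    written.append(path)
    log.info("wrote %s (%d rows)", path, len(df))
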