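"""End-to-end orchestration: pool -> instrument -> harmonize -> MR -> coloc -> report.

A single structured config drives the whole drug-target analysis.  Every
filtering step logs counts in/out (window, significance, concordance, LD
pruning, harmonization) so instrument provenance can be reconstructed from
the run log, and the report carries enough to re-run each stage directly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .coloc import (
    DEFAULT_PRIORS,
    SUPPORT_THRESHOLD,
    coloc_posteriors,
    define_region,
)
from .gwas_io import (
    LDMatrix,
    SummaryStatsTable,
    harmonize_pair,
    read_ld_matrix,
    read_summary_stats,
)
from .instruments import (
    DEFAULT_P_THRESHOLD,
    DEFAULT_R2_MAX,
    DEFAULT_WINDOW_BP,
    GeneRegion,
    Instrument,
    instrument_from_variants,
    ld_prune_greedy,
    select_cis_candidates,
)
from .meta_pool import concordance_filter, pool_tables, pooled_to_table
from .mr import (
    MREstimate,
    apply_multiplicity,
    ivw_correlated,
    leave_one_out,
    make_input_set,
    scale_odds_ratio,
)

logger = logging.getLogger(__name__)

COLOC_TRIGGER_P = 0.05


@dataclass
class AnalysisConfig:
    """Inputs and thresholds for one full drug-target MR run."""

    exposure_paths: list[str]
    outcome_paths: dict[str, str]
    ld_path: str
    regions: list[GeneRegion]
    window_kb: float = DEFAULT_WINDOW_BP / 1000
    p_threshold: float = DEFAULT_P_THRESHOLD
    r2_max: float = DEFAULT_R2_MAX
    coloc_window_kb: float = 300.0
    coloc_support: float = SUPPORT_THRESHOLD
    coloc_trigger_p: float = COLOC_TRIGGER_P
    alpha: float = 0.05
    palindrome_eaf_band: float = 0.08
    orientation: str = "per_unit_lower_exposure"
    scale: float = 1.0
    r2_mode: str = "eaf_beta"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= len(self.exposure_paths) <= 2):
            raise ValueError("provide one or two exposure GWAS paths")
        for t in ("window_kb", "p_threshold", "r2_max", "coloc_window_kb", "alpha", "scale"):
            if getattr(self, t) <= 0:
                raise ValueError(f"{t} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        regions = [
            GeneRegion(
                gene_symbol=r["gene_symbol"],
                chrom=str(r["chrom"]),
                start=int(r["start"]),
                end=int(r["end"]),
                window_bp=int(float(raw.get("window_kb", 100)) * 1000),
            )
            for r in raw.pop("regions")
        ]
        return cls(regions=regions, **raw)

    def validate_paths(self) -> None:
        paths = list(self.exposure_paths) + list(self.outcome_paths.values()) + [self.ld_path]
        for p in paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")

    def content_hash(self) -> str:
        payload = {
            k: (str(v) if isinstance(v, (Path,)) else v)
            for k, v in sorted(self.__dict__.items())
            if k != "regions"
        }
        payload["regions"] = [
            (r.gene_symbol, r.chrom, r.start, r.end, r.window_bp) for r in self.regions
        ]
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _estimate_record(est: MREstimate) -> dict[str, Any]:
    return {
        "theta": est.theta,
        "se": est.se_theta,
        "odds_ratio": est.odds_ratio,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "pvalue": est.pvalue,
        "phi": est.phi,
        "j": est.j,
        "method": est.method,
        "orientation": est.orientation,
    }


def run_pipeline(config: AnalysisConfig) -> dict[str, Any]:
    """Execute the full analysis and return the machine-readable report."""
    config.validate_paths()
    filter_log: list[dict[str, Any]] = []

    def log_step(stage: str, **counts) -> None:
        filter_log.append({"stage": stage, **counts})
        logger.info("%s: %s", stage, counts)

    # --- exposure: read, optionally pool two GWAS ---
    exposures = [read_summary_stats(p) for p in config.exposure_paths]
    if len(exposures) == 2:
        pooled = pool_tables(exposures[0], exposures[1])
        retained = concordance_filter(pooled, config.p_threshold)
        log_step(
            "pool",
            snps_in=len(exposures[0]),
            shared=len(pooled),
            concordant_significant=len(retained),
        )
        exposure = pooled_to_table(retained, exposures[0], trait_label="pooled")
    else:
        exposure = exposures[0]

    outcomes = {label: read_summary_stats(p) for label, p in config.outcome_paths.items()}

    report: dict[str, Any] = {
        "provenance": {
            "config_hash": config.content_hash(),
            "seed": config.seed,
            "version": __version__,
        },
        "instruments": {},
        "results": [],
        "filter_log": filter_log,
    }

    estimates_for_tiers: dict[str, MREstimate] = {}
    for region in config.regions:
        candidates = select_cis_candidates(exposure, region, config.p_threshold)
        if not candidates:
            log_step("instrument", target=region.gene_symbol, candidates=0, kept=0)
            continue
        ld = read_ld_matrix(config.ld_path, [c.snp_id for c in candidates])
        kept = ld_prune_greedy(candidates, ld, config.r2_max)
        log_step(
            "instrument",
            target=region.gene_symbol,
            candidates=len(candidates),
            kept=len(kept),
        )
        instrument = instrument_from_variants(
            kept,
            ld,
            exposure_label=exposure.trait_label,
            r2_mode=config.r2_mode,
            target=region.gene_symbol,
        )
        report["instruments"][region.gene_symbol] = {
            "snp_ids": instrument.snp_ids,
            "r2_total": instrument.r2_total,
            "f_stat": instrument.f_stat,
            "n_gwas": instrument.n_gwas,
        }

        exp_table = SummaryStatsTable(
            list(instrument.variants), trait_label=exposure.trait_label
        )
        for label, outcome in outcomes.items():
            result = _analyse_pair(
                instrument, exp_table, exposure, outcome, label, config, log_step
            )
            if result is None:
                continue
            report["results"].append(result)
            estimates_for_tiers[f"{region.gene_symbol}|{label}"] = result["_estimate"]

    # evidence tiers across the full target x outcome family
    if estimates_for_tiers:
        tiers = {
            t.label: t.tier
            for t in apply_multiplicity(estimates_for_tiers, alpha=config.alpha)
        }
        for rec in report["results"]:
            rec["tier"] = tiers[f"{rec['target']}|{rec['outcome']}"]
            del rec["_estimate"]
        report["n_tests"] = len(estimates_for_tiers)
        report["bonferroni_threshold"] = config.alpha / len(estimates_for_tiers)
    return report


def _analyse_pair(
    instrument: Instrument,
    exp_table: SummaryStatsTable,
    full_exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    label: str,
    config: AnalysisConfig,
    log_step,
) -> dict[str, Any] | None:
    harm = harmonize_pair(exp_table, outcome, config.palindrome_eaf_band)
    log_step(
        "harmonize",
        target=instrument.target,
        outcome=label,
        pairs=len(harm.pairs),
        dropped={d.snp_id: d.reason for d in harm.dropped},
    )
    if not harm.pairs:
        return None
    input_set = make_input_set(harm.pairs, instrument.ld)
    est = ivw_correlated(input_set)
    if config.orientation == "per_unit_lower_exposure":
        est = est.flipped()
    reported = scale_odds_ratio(est, config.scale) if config.scale != 1.0 else est

    record: dict[str, Any] = {
        "target": instrument.target,
        "outcome": label,
        **_estimate_record(reported),
        "or_ci": reported.format_or_ci(),
        "scale": config.scale,
        "leave_one_out": [],
        "coloc": None,
        "_estimate": reported,
    }
    if len(input_set) >= 2:
        loo = leave_one_out(input_set)
        record["leave_one_out"] = [
            {
                "excluded": snp,
                **_estimate_record(
                    e.flipped() if config.orientation == "per_unit_lower_exposure" else e
                ),
            }
            for snp, e in loo
        ]

    if reported.pvalue < config.coloc_trigger_p:
        record["coloc"] = _coloc_stage(instrument, full_exposure, outcome, config)
    return record


def _coloc_stage(
    instrument: Instrument,
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    config: AnalysisConfig,
) -> dict[str, Any] | None:
    top = instrument.variants[0].snp_id  # most significant by construction
    window = int(config.coloc_window_kb * 1000)
    try:
        t1 = define_region(exposure, top, window, trait_type="quantitative")
        t2 = define_region(outcome, top, window, trait_type="case_control")
        res = coloc_posteriors(t1, t2, priors=DEFAULT_PRIORS)
    except (KeyError, ValueError) as exc:
        logger.warning("coloc skipped for %s: %s", instrument.target, exc)
        return None
    return {
        "top_snp": top,
        "n_snps": res.n_snps,
        "pp": res.pp,
        "supported_h4": res.pp["H4"] >= config.coloc_support,
    }


TSV_COLUMNS = [
    "target", "outcome", "j", "odds_ratio", "ci_low", "ci_high",
    "pvalue", "phi", "tier", "or_ci",
]


def render_report(report: dict[str, Any], outdir: str | Path, fmt: str = "both") -> list[Path]:
    """Write the report as JSON (lossless) and/or a result-table TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    if fmt in ("json", "both"):
        p = outdir / "report.json"
        p.write_text(json.dumps(report, indent=2, default=_json_default) + "\n")
        written.append(p)
    if fmt in ("tsv", "both"):
        p = outdir / "results.tsv"
        p.write_text(render_results_tsv(report))
        written.append(p)
    return written


def render_results_tsv(report: dict[str, Any]) -> str:
    lines = ["\t".join(TSV_COLUMNS)]
    for rec in report.get("results", []):
        lines.append(
            "\t".join(_format_cell(rec.get(c)) for c in TSV_COLUMNS)
        )
    return "\n".join(lines) + "\n"


def _format_cell(v: Any) -> str:
    if v is None:
        return "NA"
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def _json_default(o: Any):
    import numpy as np

    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
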