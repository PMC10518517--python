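"""End-to-end orchestration of the bidirectional MR analysis.

``run_direction`` executes one exposure -> outcome analysis: scale
conversion (binary BOLT-LMM traits to log odds), significance-threshold
choice, LD clumping, confounder/outcome screens, weak-instrument filtering,
LD-proxy substitution, harmonization, the estimator battery (IVW with
multiplicative random effects, MR-Egger, weighted median, weighted mode, or
a single-SNP Wald ratio), heterogeneity statistics, leave-one-out and
funnel diagnostics, and MR-PRESSO.  ``run_bidirectional`` pairs a panel of
inflammatory-factor exposures with one disease dataset in both directions,
reusing the disease's instrument selection across all reverse analyses.

Multiple testing across the factor panel is handled by Bonferroni
adjustment; both raw and adjusted p-values are reported, and significance
flags use the raw p at ``alpha`` so the adjusted column can be judged
alongside.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import instruments as ins
from .harmonize import EmptyHarmonizedSetError, harmonize_pair
from .model import MRModel, MRResults
from .presso import PressoResult, run_presso
from .summary_io import SummaryDataset, convert_boltlmm_to_logor, write_results_table

logger = logging.getLogger("bidirmr")

__all__ = ["AnalysisConfig", "DirectionReport", "select_instruments",
           "run_direction", "run_bidirectional", "adjust_pvalues", "render_report"]


@dataclass
class AnalysisConfig:
    """Tunable settings of one analysis run (thresholds, filters, seeds)."""

    direction: str = "both"            # forward | reverse | both
    strict_p: float = 5e-8
    relaxed_p: float = 1e-5
    min_gs_snps: int = 3
    clump_r2: float = 0.001
    clump_window_bp: int = 10_000_000
    f_min: float = 10.0
    proxy_r2: float = 0.9
    pre_clumped: bool = False
    n_boot: int = 1000
    presso_n_sim: int = 1000
    run_presso: bool = True
    second_order_se: bool = False
    mode_phi: float = 1.0
    alpha: float = 0.05
    bonferroni_m: int | None = None    # defaults to the number of exposures tested
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0,1)")
        if self.direction not in ("forward", "reverse", "both"):
            raise ValueError(f"unknown direction {self.direction!r}")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class InstrumentSelection:
    """Outcome of the instrument-selection filter chain for one exposure."""

    exposure_id: str
    threshold: float
    selected: list[str]
    diagnostics: list[ins.InstrumentDiagnostics]
    exclusions: list[tuple[str, str, str]]  # (stage, variant_id, reason)


@dataclass
class DirectionReport:
    """All results and diagnostics of one exposure -> outcome analysis."""

    exposure_id: str
    outcome_id: str
    status: str                           # "ok" or "not estimable: <stage>"
    threshold: float | None = None
    estimates: list[MRResults] = field(default_factory=list)
    instrument_ids: list[str] = field(default_factory=list)
    exclusions: list[tuple[str, str, str]] = field(default_factory=list)
    loo: list[tuple[str, MRResults]] = field(default_factory=list)
    loo_all_same_side: bool | None = None
    funnel: pd.DataFrame | None = None
    funnel_symmetry: float | None = None
    presso: PressoResult | None = None

    def rows(self, m: int = 1, alpha: float = 0.05) -> list[dict]:
        out = []
        for est in self.estimates:
            row = est.to_row()
            row["status"] = self.status
            row["threshold"] = self.threshold
            row["p_adjusted"] = adjust_pvalues([est.p_value], m=m)[0]
            row["significant_raw"] = est.p_value < alpha
            out.append(row)
        if not self.estimates:
            out.append({"method": None, "exposure": self.exposure_id,
                        "outcome": self.outcome_id, "status": self.status,
                        "threshold": self.threshold})
        return out


def _auto_convert(ds: SummaryDataset) -> SummaryDataset:
    if ds.meta.trait_type == "binary" and ds.meta.scale == "linear-boltlmm":
        if ds.meta.case_fraction is None:
            raise ValueError(f"{ds.trait_id}: binary BOLT-LMM dataset needs a case_fraction")
        logger.info("%s: converting BOLT-LMM linear effects to log odds", ds.trait_id)
        return convert_boltlmm_to_logor(ds)
    return ds


def select_instruments(exposure: SummaryDataset, config: AnalysisConfig,
                       ld: ins.LDReference | None = None,
                       screens: dict[str, SummaryDataset] | None = None
                       ) -> InstrumentSelection:
    """Threshold choice -> clump -> confounder/outcome screens -> weak filter."""
    exposure = _auto_convert(exposure)
    exclusions: list[tuple[str, str, str]] = []
    threshold = ins.choose_p_threshold(exposure, config.strict_p,
                                       config.relaxed_p, config.min_gs_snps)
    candidates = set(exposure.table.index[exposure.table["p_value"] < threshold])
    kept = ins.clump(exposure, threshold, ld, config.clump_r2,
                     config.clump_window_bp, config.pre_clumped)
    for vid in sorted(candidates - set(kept)):
        exclusions.append(("clump", vid, "clumped"))

    if screens:
        kept, screen_log = ins.screen_confounders_and_outcome(kept, screens, config.alpha)
        for vid, reason in screen_log:
            stage = "screen" if not reason.startswith("not testable") else "screen-info"
            exclusions.append((stage, vid, reason))

    diags = ins.diagnostics_for(exposure, kept)
    strong = ins.filter_weak(diags, config.f_min)
    strong_ids = {d.variant_id for d in strong}
    for d in diags:
        if d.variant_id not in strong_ids:
            exclusions.append(("weak-filter", d.variant_id, "weak"))
    selected = [v for v in kept if v in strong_ids]
    return InstrumentSelection(exposure.trait_id, threshold, selected, diags, exclusions)


def run_direction(exposure: SummaryDataset, outcome: SummaryDataset,
                  config: AnalysisConfig,
                  ld: ins.LDReference | None = None,
                  screens: dict[str, SummaryDataset] | None = None,
                  preselected: InstrumentSelection | None = None
                  ) -> DirectionReport:
    """One exposure -> outcome MR analysis; never raises on an empty pair,
    reporting ``not estimable`` with the stage that emptied it instead."""
    exposure = _auto_convert(exposure)
    outcome = _auto_convert(outcome)
    sel = preselected or select_instruments(exposure, config, ld, screens)
    report = DirectionReport(exposure.trait_id, outcome.trait_id, "ok",
                             threshold=sel.threshold,
                             exclusions=list(sel.exclusions))
    if not sel.selected:
        report.status = "not estimable: instrument-selection"
        return report

    missing = [v for v in sel.selected if v not in outcome]
    proxy_map, proxy_drops = ins.find_proxies(missing, ld, outcome, config.proxy_r2)
    for vid, reason in proxy_drops:
        report.exclusions.append(("proxy", vid, reason))

    try:
        hset = harmonize_pair([exposure.record(v) for v in sel.selected
                               if v in outcome or v in proxy_map],
                              outcome, exposure.trait_id, outcome.trait_id,
                              proxy_map=proxy_map)
    except (EmptyHarmonizedSetError, ValueError) as err:
        if isinstance(err, EmptyHarmonizedSetError):
            for vid, reason in err.exclusions:
                report.exclusions.append(("harmonization", vid, reason))
        report.status = "not estimable: harmonization"
        return report
    for vid, reason in hset.exclusions:
        report.exclusions.append(("harmonization", vid, reason))
    report.instrument_ids = hset.variant_ids

    model = MRModel(hset, second_order_se=config.second_order_se)
    rng = np.random.default_rng(config.seed)
    report.estimates = model.fit_all(n_boot=config.n_boot, seed=rng, phi=config.mode_phi)

    J = len(hset)
    if J >= 3:
        report.loo, report.loo_all_same_side = model.leave_one_out()
        report.funnel, report.funnel_symmetry = model.funnel_data()
    if config.run_presso and J >= 4:
        report.presso = run_presso(hset, config.presso_n_sim, seed=config.seed)
    return report


def run_bidirectional(factors: list[SummaryDataset], disease: SummaryDataset,
                      config: AnalysisConfig,
                      ld: ins.LDReference | None = None,
                      screens: dict[str, SummaryDataset] | None = None
                      ) -> dict[str, list[DirectionReport]]:
    """Paired forward (factor -> disease) and reverse (disease -> factor)
    analyses.  The disease's instrument selection runs once and is reused
    across all reverse pairs; per-factor proxying and harmonization still
    run pair by pair.  Failures are reported per pair, never aborting the
    batch."""
    disease = _auto_convert(disease)
    out: dict[str, list[DirectionReport]] = {"forward": [], "reverse": []}

    if config.direction in ("forward", "both"):
        for factor in factors:
            try:
                out["forward"].append(run_direction(factor, disease, config, ld, screens))
            except Exception as err:  # defensive: a bad pair must not kill the batch
                logger.error("forward %s failed: %s", factor.trait_id, err)
                out["forward"].append(DirectionReport(
                    factor.trait_id, disease.trait_id, f"not estimable: error ({err})"))

    if config.direction in ("reverse", "both"):
        disease_sel = select_instruments(disease, config, ld, screens)
        for factor in factors:
            try:
                out["reverse"].append(run_direction(
                    disease, factor, config, ld, screens, preselected=disease_sel))
            except Exception as err:
                logger.error("reverse %s failed: %s", factor.trait_id, err)
                out["reverse"].append(DirectionReport(
                    disease.trait_id, factor.trait_id, f"not estimable: error ({err})"))
    return out


def adjust_pvalues(p_values, method: str = "bonferroni", m: int | None = None) -> list[float]:
    """Bonferroni adjustment: min(1, p * m).  ``m`` defaults to len(p_values)."""
    p = list(p_values)
    if m is None:
        m = len(p)
    if m < 1:
        raise ValueError("m must be >= 1")
    if method != "bonferroni":
        raise ValueError(f"unsupported method {method!r}")
    return [min(1.0, float(pi) * m) for pi in p]


def render_report(reports: dict[str, list[DirectionReport]], config: AnalysisConfig,
                  out_dir) -> dict[str, str]:
    """Write the full analysis bundle to ``out_dir``.

    Files: results.tsv, exclusions.tsv, loo.tsv, funnel.tsv, presso.tsv,
    run_config.yaml and summary.json.  Numeric output is deterministic
    given (inputs, config, seeds).
    """
    os.makedirs(out_dir, exist_ok=True)
    all_reports = [r for block in reports.values() for r in block]

    result_rows, excl_rows, loo_rows, funnel_rows, presso_rows = [], [], [], [], []
    for direction, block in sorted(reports.items()):
        m = config.bonferroni_m or max(1, len(block))
        for rep in block:
            for row in rep.rows(m=m, alpha=config.alpha):
                row["direction"] = direction
                result_rows.append(row)
            for stage, vid, reason in rep.exclusions:
                excl_rows.append({"direction": direction, "exposure": rep.exposure_id,
                                  "outcome": rep.outcome_id, "stage": stage,
                                  "variant_id": vid, "reason": reason})
            for vid, est in rep.loo:
                loo_rows.append({"direction": direction, "exposure": rep.exposure_id,
                                 "outcome": rep.outcome_id, "dropped": vid,
                                 "theta": est.theta, "se": est.se,
                                 "ci_low": est.ci_low, "ci_high": est.ci_high,
                                 "p": est.p_value})
            if rep.funnel is not None:
                for _, frow in rep.funnel.iterrows():
                    funnel_rows.append({"direction": direction,
                                        "exposure": rep.exposure_id,
                                        "outcome": rep.outcome_id,
                                        "variant_id": frow["variant_id"],
                                        "ratio": frow["ratio"],
                                        "precision": frow["precision"],
                                        "symmetry": rep.funnel_symmetry})
            if rep.presso is not None:
                for prow in rep.presso.to_rows():
                    prow.update({"direction": direction, "exposure": rep.exposure_id,
                                 "outcome": rep.outcome_id,
                                 "global_p": rep.presso.global_p,
                                 "distortion_p": rep.presso.distortion_p,
                                 "n_sim": rep.presso.n_sim})
                    presso_rows.append(prow)

    paths = {}
    for name, rows, cols in (
        ("results", result_rows, None),
        ("exclusions", excl_rows, ["direction", "exposure", "outcome", "stage",
                                   "variant_id", "reason"]),
        ("loo", loo_rows, ["direction", "exposure", "outcome", "dropped", "theta",
                           "se", "ci_low", "ci_high", "p"]),
        ("funnel", funnel_rows, ["direction", "exposure", "outcome", "variant_id",
                                 "ratio", "precision", "symmetry"]),
        ("presso", presso_rows, ["direction", "exposure", "outcome", "row",
                                 "variant_id", "rss", "p", "p_bonferroni", "outlier",
                                 "global_p", "distortion_p", "n_sim"]),
    ):
        path = os.path.join(out_dir, f"{name}.tsv")
        df = pd.DataFrame(rows, columns=cols) if cols else pd.DataFrame(rows)
        write_results_table(df, path)
        paths[name] = path

    cfg_path = os.path.join(out_dir, "run_config.yaml")
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)
    paths["run_config"] = cfg_path

    summary = {
        "n_pairs": len(all_reports),
        "n_estimable": sum(r.status == "ok" for r in all_reports),
        "directions": {d: len(b) for d, b in reports.items()},
        "significant_raw": [
            {"direction": d, "exposure": r.exposure_id, "outcome": r.outcome_id,
             "method": e.method, "p": e.p_value}
            for d, b in sorted(reports.items()) for r in b for e in r.estimates
            if e.method == "ivw_mre" and e.p_value < config.alpha
        ],
    }
    sum_path = os.path.join(out_dir, "summary.json")
    with open(sum_path, "w") as fh:
        json.dump(summary, fh, indent=2)
    paths["summary"] = sum_path
    return paths
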