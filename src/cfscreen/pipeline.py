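"""End-to-end analysis: cohort in, scored tables and a reproducible report out.

``run_analysis`` chains the whole method: descriptive summary per outcome
group, cfDNA threshold performance at the configured cutoffs, apparent and
over-optimism-corrected AUROC for each of the four predictors (cfDNA,
main-nodule size, Lung-RADS rank, Brock score) against benign nodules —
overall and separately for prevalent and incident cancers — stratified
predictive-value tables, and the VDT-vs-cfDNA correlation block for
malignant solid nodules with serial exams.

The report is deterministic given the seed: the JSON serialization of two
same-seed runs on the same cohort is byte-identical, and the metadata
(seed, config hash, package version, cohort size) suffices to re-run it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .cohort import OutcomeClass, SubjectRecord, percent_round, read_cohort
from .stats import (
    STRATIFIERS,
    chi_square_2x2,
    cohort_frame,
    confusion_at_threshold,
    corrected_auroc,
    ols_regression,
    pearson_ci,
    stratified_pv,
    youden_threshold,
)
from .vdt import VdtError, vdt_from_series

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "AnalysisReport", "run_analysis", "compare_thresholds", "vdt_pairs"]

PREDICTORS = ("cfdna_ng_ml", "size_mm", "lungrads_rank", "brock_score")


@dataclass(frozen=True)
class AnalysisConfig:
    cutoffs: tuple[float, ...] = (3.15, 5.0)
    n_replications: int = 100
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            cutoffs=tuple(float(c) for c in raw.get("cutoffs", (3.15, 5.0))),
            n_replications=int(raw.get("n_replications", 100)),
            seed=int(raw.get("seed", 0)),
        )

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class AnalysisReport:
    descriptive: dict
    threshold_performance: dict | None
    predictor_performance: dict | None
    stratified: dict | None
    vdt_block: dict | None
    threshold_comparison: dict | None
    notices: tuple[str, ...]
    metadata: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2, allow_nan=False)

    def to_markdown(self) -> str:
        lines = ["# Screening-cohort analysis report", ""]
        lines.append(f"Seed {self.metadata['seed']}, config hash {self.metadata['config_hash']}, "
                     f"n = {self.metadata['n_subjects']} subjects.")
        for notice in self.notices:
            lines.append(f"\n> NOTE: {notice}")
        lines.append("\n## Descriptive summary (per outcome group)\n")
        for group, d in self.descriptive.items():
            lines.append(
                f"- **{group}**: n={d['n']}, mean age {d['age_mean']:.1f}, "
                f"median pack-years {d['pack_years_median']:.1f}, mean cfDNA {d['cfdna_mean']:.1f} ng/mL, "
                f"cfDNA categories {d['cfdna_categories']}"
            )
        if self.threshold_performance:
            lines.append("\n## cfDNA threshold performance (cancer vs benign)\n")
            lines.append("| cutoff (ng/mL) | sensitivity | specificity | TP | FP | TN | FN |")
            lines.append("|---|---|---|---|---|---|---|")
            for cut, perf in self.threshold_performance.items():
                lines.append(
                    f"| {cut} | {percent_round(perf['sensitivity'])}% | {percent_round(perf['specificity'])}% "
                    f"| {perf['tp']} | {perf['fp']} | {perf['tn']} | {perf['fn']} |"
                )
        if self.predictor_performance:
            lines.append("\n## Predictor discrimination (apparent and corrected AUROC)\n")
            lines.append("| comparison | predictor | apparent | corrected | 95% interval |")
            lines.append("|---|---|---|---|---|")
            for comp, preds in self.predictor_performance.items():
                for name, res in preds.items():
                    lines.append(
                        f"| {comp} | {name} | {res['apparent_auc']:.2f} | {res['corrected_auc']:.2f} "
                        f"| ({res['interval_lo']:.2f}-{res['interval_hi']:.2f}) |"
                    )
        if self.stratified:
            for strat, table in self.stratified.items():
                lines.append(f"\n## Predictive values by {strat} (cutoff {table['cutoff']} ng/mL)\n")
                lines.append("| stratum | benign< | cancer< | benign>= | cancer>= | NPV | PPV |")
                lines.append("|---|---|---|---|---|---|---|")
                for stratum, row in table["rows"].items():
                    npv = "-" if row["npv"] is None else f"{percent_round(row['npv'])}%"
                    ppv = "-" if row["ppv"] is None else f"{percent_round(row['ppv'])}%"
                    lines.append(
                        f"| {stratum} | {row['benign_below']} | {row['cancer_below']} "
                        f"| {row['benign_above']} | {row['cancer_above']} | {npv} | {ppv} |"
                    )
        if self.vdt_block:
            v = self.vdt_block
            lines.append("\n## VDT vs baseline cfDNA (malignant solid nodules with serial exams)\n")
            lines.append(
                f"n = {v['n']}, mean VDT {v['mean_vdt_days']:.0f} days, "
                f"Pearson r(ln cfDNA, VDT) = {v['r']:.2f} "
                f"(95% CI {v['ci_lo']:.2f} to {v['ci_hi']:.2f})"
            )
        return "\n".join(lines) + "\n"


def vdt_pairs(records: Sequence[SubjectRecord]) -> list[tuple[str, float, float]]:
    """(subject_id, cfdna, vdt_days) for cancer subjects whose main solid
    nodule has at least two exams with measurable axes."""
    out = []
    for rec in records:
        if not rec.outcome.is_cancer:
            continue
        by_nodule: dict[str, list] = {}
        for n in rec.nodules:
            by_nodule.setdefault(n.nodule_id, []).append(n)
        series = [obs for obs in by_nodule.values() if len(obs) >= 2]
        if not series:
            continue
        # main followed nodule: largest baseline diameter among followed ones
        series.sort(key=lambda obs: -max(o.mean_diameter_mm for o in obs))
        try:
            est = vdt_from_series(series[0])
        except VdtError:
            continue
        out.append((rec.subject_id, rec.cfdna_ng_ml, est.vdt_days))
    return out


def _corrected_result_dict(x, y, n_rep, seed) -> dict:
    res = corrected_auroc(x, y, n_rep=n_rep, seed=seed)
    return {
        "apparent_auc": res.apparent_auc,
        "corrected_auc": res.corrected_auc,
        "interval_lo": res.interval_lo,
        "interval_hi": res.interval_hi,
        "n_replications": res.n_replications,
    }


def compare_thresholds(records: Sequence[SubjectRecord], cutoffs: Sequence[float]) -> dict:
    """Per-cutoff positivity (score >= cutoff) by outcome group with
    benign-vs-cancer chi-square tests."""
    groups = {
        g.value: [r for r in records if r.outcome.outcome_class is g] for g in OutcomeClass
    }
    out: dict = {}
    for cut in cutoffs:
        entry: dict = {"groups": {}, "tests": {}}
        npos = {}
        for gname, members in groups.items():
            if not members:
                continue
            n_pos = sum(r.cfdna_ng_ml >= cut for r in members)
            npos[gname] = (n_pos, len(members))
            entry["groups"][gname] = {
                "n": len(members),
                "n_positive": n_pos,
                "fraction": n_pos / len(members),
                "percent": percent_round(n_pos / len(members)),
            }
        benign = npos.get("benign")
        if benign:
            for gname, (p, n) in npos.items():
                if gname == "benign":
                    continue
                table = [[p, n - p], [benign[0], benign[1] - benign[0]]]
                try:
                    test = chi_square_2x2(table)
                    entry["tests"][f"benign_vs_{gname}"] = {
                        "chi2": test.chi2_stat,
                        "p_value": test.p_value,
                    }
                except ValueError:
                    entry["tests"][f"benign_vs_{gname}"] = None
        out[f"{cut:g}"] = entry
    return out


def run_analysis(
    cohort, config: AnalysisConfig | None = None, out_dir=None
) -> AnalysisReport:
    """Run the full analysis on a cohort (path to a cohort CSV, or a list of
    SubjectRecords) and optionally write report.json / report.md / CSV
    tables under ``out_dir``."""
    config = config or AnalysisConfig()
    if isinstance(cohort, (str, Path)):
        records = read_cohort(cohort)
    else:
        records = list(cohort)
    if not records:
        raise ValueError("empty cohort")
    from .cohort import summarize_cohort

    notices: list[str] = []
    descriptive = summarize_cohort(records)
    frame = cohort_frame(records)
    y = frame["is_cancer"].to_numpy()

    single_class = y.min() == y.max()
    threshold_performance = None
    predictor_performance = None
    stratified = None
    comparison = None
    if single_class:
        notices.append(
            "single-class cohort: discrimination and predictive-value tables are undefined"
        )
    else:
        cf = frame["cfdna_ng_ml"].to_numpy()
        threshold_performance = {}
        for cut in config.cutoffs:
            perf = confusion_at_threshold(cf, y, cut)
            threshold_performance[f"{cut:g}"] = dataclasses.asdict(perf)
        youden = youden_threshold(cf, y)
        threshold_performance["youden"] = dataclasses.asdict(youden)

        rng = np.random.default_rng(config.seed)
        all_rows = frame["outcome"].notna()
        comparisons = {
            "all_lc_vs_benign": all_rows,
            "prevalent_vs_benign": frame["outcome"].isin(["benign", "prevalent_lc"]),
            "incident_vs_benign": frame["outcome"].isin(["benign", "incident_lc"]),
        }
        predictor_performance = {}
        for comp_name, mask in comparisons.items():
            sub = frame[mask]
            ysub = sub["is_cancer"].to_numpy()
            if ysub.sum() < 2 or (1 - ysub).sum() < 2 or ysub.min() == ysub.max():
                continue
            preds = {}
            for pred in PREDICTORS:
                seed_b = int(rng.integers(0, 2**31 - 1))
                preds[pred] = _corrected_result_dict(
                    sub[pred].to_numpy(), ysub, config.n_replications, seed_b
                )
            predictor_performance[comp_name] = preds

        stratified = {
            strat: dataclasses.asdict(stratified_pv(frame, strat, config.cutoffs[0]))
            for strat in STRATIFIERS
        }
        comparison = compare_thresholds(records, config.cutoffs)

    # VDT block
    pairs = vdt_pairs(records)
    vdt_block = None
    if len(pairs) >= 4:
        cf_v = np.array([p[1] for p in pairs])
        vdt_v = np.array([p[2] for p in pairs])
        frame_sizes = dict(zip(frame["subject_id"], frame["size_mm"]))
        size_v = np.array([frame_sizes[p[0]] for p in pairs])
        ci = pearson_ci(np.log(cf_v), vdt_v)
        reg = ols_regression(
            vdt_v, np.column_stack([np.log(cf_v), size_v]), names=("ln_cfdna", "size_mm")
        )
        vdt_block = {
            "n": len(pairs),
            "mean_vdt_days": float(vdt_v.mean()),
            "r": ci.r,
            "ci_lo": ci.ci_lo,
            "ci_hi": ci.ci_hi,
            "regression": {
                "names": list(reg.names),
                "coef": reg.params.tolist(),
                "stderr": reg.bse.tolist(),
                "p_values": reg.pvalues.tolist(),
            },
        }
    elif any(r.outcome.is_cancer for r in records):
        notices.append("fewer than 4 serial-exam malignant nodules: VDT correlation omitted")

    report = AnalysisReport(
        descriptive=descriptive,
        threshold_performance=threshold_performance,
        predictor_performance=predictor_performance,
        stratified=stratified,
        vdt_block=vdt_block,
        threshold_comparison=comparison,
        notices=tuple(notices),
        metadata={
            "seed": config.seed,
            "config_hash": config.hash(),
            "package_version": __version__,
            "n_subjects": len(records),
            "n_replications": config.n_replications,
            "cutoffs": list(config.cutoffs),
        },
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(report.to_json(), encoding="utf-8")
        (out_dir / "report.md").write_text(report.to_markdown(), encoding="utf-8")
        frame.to_csv(out_dir / "scored_cohort.csv", index=False)
        logger.info("wrote report to %s", out_dir)
    return report
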