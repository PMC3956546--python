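"""Sample QA/QC gating.

A tumor biopsy passes through four quality gates before expression
profiling: histopathology review (ordinal tumor-content and necrosis
categories), total-RNA quality (yield, A260/A280 purity, RIN), amplified
cDNA quality (yield, purity), and array hybridization metrics (background,
percent present calls, scale factor).  A sample proceeds only if every
gate that could be evaluated passes; metrics that were never measured
(e.g. a stage not reached) do not veto.

All thresholds are held in :class:`QcThresholds` and default to the study
gates: tumor surface/nuclei in the top ordinal category, necrosis not in
the worst category, RNA yield >= 20 ng with A260/A280 >= 1.8 and
RIN >= 8.0, cDNA >= 5 ug at ratio >= 1.8, array background < 100 with
present calls >= 30% and scale factor near 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

PCT_CATEGORIES = ("0-24%", "25-49%", "50-74%", "75-100%")
NECROSIS_CATEGORIES = ("<10%", "10-20%", ">20%")

PASS = "pass"
FAIL = "fail"
NOT_EVALUATED = "not-evaluated"

STAGES = ("histopathology", "rna", "cdna", "array")


@dataclass(frozen=True)
class QcRecord:
    """One sample's QC metrics; ``None`` marks a metric never measured."""

    sample_id: str
    cohort: str = ""
    tumor_surface_category: Optional[str] = None
    tumor_nuclei_category: Optional[str] = None
    necrosis_category: Optional[str] = None
    rna_conc: Optional[float] = None          # ng/ul
    rna_volume: Optional[float] = 14.0        # ul
    rna_ratio: Optional[float] = None         # A260/A280
    rin: Optional[float] = None               # 1-10
    cdna_yield: Optional[float] = None        # ug
    cdna_ratio: Optional[float] = None
    array_background: Optional[float] = None
    array_present_call: Optional[float] = None  # percent
    array_scale_factor: Optional[float] = None

    def __post_init__(self) -> None:
        for name, allowed in (
            ("tumor_surface_category", PCT_CATEGORIES),
            ("tumor_nuclei_category", PCT_CATEGORIES),
            ("necrosis_category", NECROSIS_CATEGORIES),
        ):
            val = getattr(self, name)
            if val is not None and val not in allowed:
                raise ValueError(f"{name}={val!r} not in {allowed}")
        if self.rin is not None and not (1.0 <= self.rin <= 10.0):
            raise ValueError(f"rin={self.rin} outside [1, 10]")


@dataclass(frozen=True)
class QcThresholds:
    passing_pct_category: str = "75-100%"
    necrosis_fail_category: str = ">20%"
    rna_yield_ng: float = 20.0
    rna_ratio: float = 1.8
    rin: float = 8.0
    cdna_yield_ug: float = 5.0
    cdna_ratio: float = 1.8
    array_background: float = 100.0
    array_present_call_pct: float = 30.0
    array_scale_factor_target: float = 100.0
    array_scale_factor_fold: float = 3.0  # pass if within [target/fold, target*fold]


@dataclass
class StageVerdict:
    stage: str
    status: str  # pass / fail / not-evaluated
    reasons: list[tuple[str, object, str]] = field(default_factory=list)


@dataclass
class QcVerdict:
    sample_id: str
    stages: dict[str, StageVerdict]
    overall: bool

    def failure_reasons(self) -> list[tuple[str, object, str]]:
        out: list[tuple[str, object, str]] = []
        for sv in self.stages.values():
            if sv.status == FAIL:
                out.extend(sv.reasons)
        return out


def _verdict(stage: str, checks: list[tuple[str, object, str, Optional[bool]]]) -> StageVerdict:
    """Combine per-metric checks. ``ok=None`` means the metric was not measured.

    A stage with no measured metric is not-evaluated; otherwise it passes
    iff every measured metric passes.
    """
    measured = [c for c in checks if c[3] is not None]
    if not measured:
        return StageVerdict(stage, NOT_EVALUATED,
                            [(m, v, thr) for (m, v, thr, _) in checks])
    failures = [(m, v, thr) for (m, v, thr, ok) in measured if not ok]
    return StageVerdict(stage, FAIL if failures else PASS, failures)


def evaluate_histopathology(rec: QcRecord, thr: QcThresholds = QcThresholds()) -> StageVerdict:
    checks = []
    for name, val in (("tumor_surface_category", rec.tumor_surface_category),
                      ("tumor_nuclei_category", rec.tumor_nuclei_category)):
        ok = None if val is None else val == thr.passing_pct_category
        checks.append((name, val, f"== {thr.passing_pct_category}", ok))
    nec = rec.necrosis_category
    ok = None if nec is None else nec != thr.necrosis_fail_category
    checks.append(("necrosis_category", nec, f"!= {thr.necrosis_fail_category}", ok))
    return _verdict("histopathology", checks)


def evaluate_rna(rec: QcRecord, thr: QcThresholds = QcThresholds()) -> StageVerdict:
    for name in ("rna_conc", "rna_volume", "rna_ratio", "rin"):
        val = getattr(rec, name)
        if val is not None and val < 0:
            raise ValueError(f"{rec.sample_id}: negative {name}={val}")
    if rec.rna_conc is None or rec.rna_volume is None:
        total_yield, yield_ok = None, None
    else:
        total_yield = rec.rna_conc * rec.rna_volume
        yield_ok = total_yield >= thr.rna_yield_ng
    checks = [
        ("rna_total_yield_ng", total_yield, f">= {thr.rna_yield_ng}", yield_ok),
        ("rna_ratio", rec.rna_ratio, f">= {thr.rna_ratio}",
         None if rec.rna_ratio is None else rec.rna_ratio >= thr.rna_ratio),
        ("rin", rec.rin, f">= {thr.rin}",
         None if rec.rin is None else rec.rin >= thr.rin),
    ]
    return _verdict("rna", checks)


def evaluate_cdna(rec: QcRecord, thr: QcThresholds = QcThresholds()) -> StageVerdict:
    checks = [
        ("cdna_ratio", rec.cdna_ratio, f">= {thr.cdna_ratio}",
         None if rec.cdna_ratio is None else rec.cdna_ratio >= thr.cdna_ratio),
        ("cdna_yield_ug", rec.cdna_yield, f">= {thr.cdna_yield_ug}",
         None if rec.cdna_yield is None else rec.cdna_yield >= thr.cdna_yield_ug),
    ]
    return _verdict("cdna", checks)


def evaluate_array(rec: QcRecord, thr: QcThresholds = QcThresholds()) -> StageVerdict:
    sf_lo = thr.array_scale_factor_target / thr.array_scale_factor_fold
    sf_hi = thr.array_scale_factor_target * thr.array_scale_factor_fold
    checks = [
        ("array_background", rec.array_background, f"< {thr.array_background}",
         None if rec.array_background is None
         else rec.array_background < thr.array_background),
        ("array_present_call", rec.array_present_call, f">= {thr.array_present_call_pct}",
         None if rec.array_present_call is None
         else rec.array_present_call >= thr.array_present_call_pct),
        ("array_scale_factor", rec.array_scale_factor, f"in [{sf_lo:g}, {sf_hi:g}]",
         None if rec.array_scale_factor is None
         else sf_lo <= rec.array_scale_factor <= sf_hi),
    ]
    return _verdict("array", checks)


_STAGE_FUNCS = {
    "histopathology": evaluate_histopathology,
    "rna": evaluate_rna,
    "cdna": evaluate_cdna,
    "array": evaluate_array,
}


def evaluate_record(rec: QcRecord, thr: QcThresholds = QcThresholds()) -> QcVerdict:
    stages = {name: fn(rec, thr) for name, fn in _STAGE_FUNCS.items()}
    overall = all(sv.status != FAIL for sv in stages.values())
    return QcVerdict(rec.sample_id, stages, overall)


def gate_cohort(records: Sequence[QcRecord],
                thr: QcThresholds = QcThresholds()) -> tuple[list[QcVerdict], dict]:
    """Gate every record and summarize pass counts per stage and overall.

    Overall percent is rounded to the nearest integer (reporting
    convention); per-stage percents are over evaluated records only.
    """
    if not records:
        raise ValueError("gate_cohort requires at least one record")
    verdicts = [evaluate_record(r, thr) for r in records]
    summary: dict = {"n": len(records)}
    for stage in STAGES:
        evaluated = [v for v in verdicts if v.stages[stage].status != NOT_EVALUATED]
        passed = [v for v in evaluated if v.stages[stage].status == PASS]
        summary[stage] = {
            "evaluated": len(evaluated),
            "passed": len(passed),
            "percent": round(100.0 * len(passed) / len(evaluated), 2) if evaluated else None,
        }
    n_pass = sum(v.overall for v in verdicts)
    summary["overall"] = {
        "passed": n_pass,
        "percent": round(100.0 * n_pass / len(records)),
    }
    return verdicts, summary
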