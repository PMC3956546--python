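"""Personalized-medicine report assembly.

Each prediction method emits drug calls with a p-value; calls are
transformed to scores -log10(p) and summed per drug across the methods
that indicated it, so a drug suggested by several methods accumulates a
stronger indication than an equally significant single-method drug.
Drugs contraindicated by a resistance biomarker are excluded from the
ranked list and reported in a separate contraindications section.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

METHODS = (
    "target-expression",
    "biomarker-sensitive",
    "biomarker-resistant",
    "response-signature",
    "sensitivity-signature",
    "network-activity",
)

SCHEMA_VERSION = "1.0"


def score_call(p: float, base: float = 10.0) -> float:
    """-log_base(p); the per-method drug score."""
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p={p} outside (0, 1]")
    return -math.log(p, base)


@dataclass
class MethodCall:
    """One drug called by one method."""

    drug: str
    method: str
    verdict: str  # indicated / contraindicated
    p: float
    genes: list[str] = field(default_factory=list)
    score: float = field(init=False)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.verdict not in ("indicated", "contraindicated"):
            raise ValueError(f"unknown verdict {self.verdict!r}")
        self.score = score_call(self.p)


def as_method_call(result) -> MethodCall:
    """Adapt a predictor result (RuleCall / ConnectivityResult / ...) to a MethodCall."""
    genes = getattr(result, "genes", [])
    if genes and isinstance(genes[0], tuple):  # RuleCall carries (gene, z)
        genes = [g for g, _ in genes]
    drugs = getattr(result, "drugs", None)
    if drugs is not None:  # network result may implicate several drugs
        raise ValueError("expand multi-drug results before adapting")
    return MethodCall(result.drug, result.method, result.verdict,
                      result.p, list(genes))


def expand_calls(results: Iterable) -> list[MethodCall]:
    """Flatten heterogeneous predictor results into MethodCalls.

    Network results carry several drugs per target; they expand to one
    call per drug with the same p.
    """
    calls: list[MethodCall] = []
    for r in results:
        drugs = getattr(r, "drugs", None)
        if drugs is None:
            calls.append(as_method_call(r))
        else:
            for drug in drugs:
                calls.append(MethodCall(drug, r.method, r.verdict, r.p,
                                        list(getattr(r, "genes", []))))
    return calls


@dataclass
class DrugSummary:
    drug: str
    summary_score: float
    n_methods: int
    methods: list[str]
    contraindicated: bool


@dataclass
class PMedReport:
    sample_id: str
    calls: list[MethodCall]
    ranked: list[DrugSummary]            # indicated drugs, score-descending
    contraindicated: list[DrugSummary]   # excluded drugs

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "sample_id": self.sample_id,
            "calls": [
                {"drug": c.drug, "method": c.method, "verdict": c.verdict,
                 "p": c.p, "score": c.score, "genes": list(c.genes)}
                for c in self.calls
            ],
            "ranked": [vars(d).copy() for d in self.ranked],
            "contraindicated": [vars(d).copy() for d in self.contraindicated],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PMedReport":
        calls = [MethodCall(c["drug"], c["method"], c["verdict"], c["p"],
                            list(c["genes"])) for c in d["calls"]]
        ranked = [DrugSummary(**{k: v for k, v in r.items()}) for r in d["ranked"]]
        contra = [DrugSummary(**{k: v for k, v in r.items()})
                  for r in d["contraindicated"]]
        return cls(d["sample_id"], calls, ranked, contra)


def summarize(sample_id: str, calls: Sequence[MethodCall]) -> PMedReport:
    """Aggregate method calls into the ranked drug summary.

    Per drug the summary score is the sum of -log10(p) over indicating
    methods (duplicate calls from the same method keep the best p); any
    contraindicated verdict flags the drug and removes it from the
    ranked list.  Ties in score break alphabetically by drug name.
    """
    per_drug: dict[str, dict[str, MethodCall]] = {}
    contra_flag: dict[str, bool] = {}
    for c in calls:
        contra_flag.setdefault(c.drug, False)
        if c.verdict == "contraindicated":
            contra_flag[c.drug] = True
            continue
        best = per_drug.setdefault(c.drug, {})
        if c.method not in best or c.p < best[c.method].p:
            best[c.method] = c
    summaries: list[DrugSummary] = []
    for drug in sorted(set(per_drug) | set(contra_flag)):
        best = per_drug.get(drug, {})
        summaries.append(DrugSummary(
            drug=drug,
            summary_score=sum(c.score for c in best.values()),
            n_methods=len(best),
            methods=sorted(best),
            contraindicated=contra_flag.get(drug, False),
        ))
    ranked = sorted((s for s in summaries if not s.contraindicated),
                    key=lambda s: (-s.summary_score, s.drug))
    contra = [s for s in summaries if s.contraindicated]
    return PMedReport(sample_id, list(calls), ranked, contra)


def render(report: PMedReport) -> tuple[str, str]:
    """(JSON document, human-readable Markdown summary)."""
    doc = json.dumps(report.to_dict(), indent=2)
    lines = [f"# Personalized medicine report — sample {report.sample_id}", ""]
    if not report.ranked and not report.contraindicated:
        lines.append("No drug indications were identified for this sample.")
    if report.ranked:
        lines += ["## Ranked drug summary", "",
                  "| rank | drug | summary score | methods |",
                  "|---|---|---|---|"]
        for i, s in enumerate(report.ranked, 1):
            lines.append(f"| {i} | {s.drug} | {s.summary_score:.2f} | "
                         f"{', '.join(s.methods)} |")
        lines.append("")
    if report.contraindicated:
        lines += ["## Contraindicated drugs", ""]
        for s in report.contraindicated:
            lines.append(f"- {s.drug} (resistance biomarker)")
        lines.append("")
    by_method: dict[str, list[MethodCall]] = {}
    for c in report.calls:
        by_method.setdefault(c.method, []).append(c)
    for method in METHODS:
        if method not in by_method:
            continue
        lines += [f"## {method}", ""]
        for c in sorted(by_method[method], key=lambda c: (c.p, c.drug)):
            genes = f" [{', '.join(c.genes)}]" if c.genes else ""
            lines.append(f"- {c.drug}: {c.verdict}, p={c.p:.3g}, "
                         f"score={c.score:.2f}{genes}")
        lines.append("")
    return doc, "\n".join(lines)
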