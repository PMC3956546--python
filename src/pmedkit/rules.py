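"""Rule-based drug prediction: Drug Target Expression and Biomarker Rules.

Drug Target Expression indicates an antagonist when its known molecular
target is over-expressed (z >= +3 by default), e.g.
``IF EGFR z >= +3 THEN INDICATE cetuximab``.  Biomarker Rules extend
this to curated sensitivity *and* resistance markers in either
direction, e.g. ``IF ERCC1 z >= +3 THEN CONTRAINDICATE oxaliplatin`` or
sensitivity triggered by under-expression (z <= -3).

Each triggered rule carries a p-value derived from the triggering
z-score via the one-sided standard-normal tail P(Z >= |z|): the greater
the z-score, the lower the p.  When several rules fire for the same drug
within a method, the call keeps the minimum p and lists every
triggering gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import pandas as pd
from scipy import stats as sps

from .crossmap import ZProfile

INDICATED = "indicated"
CONTRAINDICATED = "contraindicated"

METHOD_TARGET = "target-expression"
METHOD_BIOMARKER_SENS = "biomarker-sensitive"
METHOD_BIOMARKER_RES = "biomarker-resistant"


def normal_tail_p(z: float) -> float:
    """One-sided standard-normal tail P(Z >= |z|); the default p-from-z map."""
    return float(sps.norm.sf(abs(z)))


@dataclass(frozen=True)
class DrugTargetRule:
    gene: str
    drug: str
    threshold: float = 3.0
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


@dataclass(frozen=True)
class BiomarkerRule:
    gene: str
    drug: str
    direction: str = "over"     # over: z >= +thr; under: z <= -thr
    effect: str = "sensitive"   # sensitive -> indicated; resistant -> contraindicated
    threshold: float = 3.0
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.direction not in ("over", "under"):
            raise ValueError(f"direction {self.direction!r}")
        if self.effect not in ("sensitive", "resistant"):
            raise ValueError(f"effect {self.effect!r}")
        if self.threshold <= 0:
            raise ValueError("threshold magnitude must be positive")


@dataclass
class RuleCall:
    drug: str
    method: str
    verdict: str
    genes: list[tuple[str, float]]  # (gene, z) for every triggering rule
    p: float
    score: float = field(init=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p={self.p} outside (0, 1]")
        import math
        self.score = -math.log10(self.p)


def _dedupe(rules: Sequence, key: Callable) -> list:
    seen, out = set(), []
    for r in rules:
        k = key(r)
        if k in seen:
            warnings.warn(f"duplicate rule for {k}; keeping the first")
            continue
        seen.add(k)
        out.append(r)
    return out


def _collapse(triggered: list[tuple[str, str, str, float, float]]) -> list[RuleCall]:
    """Group triggered (drug, method, verdict, gene, z) rows into per-drug calls."""
    calls: dict[tuple[str, str, str], list[tuple[str, float]]] = {}
    for drug, method, verdict, gene, z in triggered:
        calls.setdefault((drug, method, verdict), []).append((gene, z))
    out = []
    for (drug, method, verdict), genes in sorted(calls.items()):
        p = min(normal_tail_p(z) for _, z in genes)
        out.append(RuleCall(drug, method, verdict, sorted(genes), p))
    return out


def apply_target_rules(zp: ZProfile, rules: Sequence[DrugTargetRule]) -> list[RuleCall]:
    """Indicate a drug for every rule whose target gene is over-expressed."""
    rules = _dedupe(rules, key=lambda r: (r.gene, r.drug))
    triggered = []
    for r in rules:
        if r.gene not in zp.values.index:
            continue
        z = float(zp.values[r.gene])
        if z >= r.threshold:
            triggered.append((r.drug, METHOD_TARGET, INDICATED, r.gene, z))
    return _collapse(triggered)


def apply_biomarker_rules(zp: ZProfile, rules: Sequence[BiomarkerRule]) -> list[RuleCall]:
    """Sensitivity rules emit indicated calls, resistance rules contraindicated."""
    rules = _dedupe(rules, key=lambda r: (r.gene, r.drug, r.direction, r.effect))
    triggered = []
    for r in rules:
        if r.gene not in zp.values.index:
            continue
        z = float(zp.values[r.gene])
        fired = z >= r.threshold if r.direction == "over" else z <= -r.threshold
        if not fired:
            continue
        if r.effect == "sensitive":
            triggered.append((r.drug, METHOD_BIOMARKER_SENS, INDICATED, r.gene, z))
        else:
            triggered.append((r.drug, METHOD_BIOMARKER_RES, CONTRAINDICATED, r.gene, z))
    return _collapse(triggered)


def read_target_rules(path) -> list[DrugTargetRule]:
    df = pd.read_csv(path, sep="\t")
    return [DrugTargetRule(r.gene, r.drug, float(r.threshold), getattr(r, "evidence", ""))
            for r in df.itertuples()]


def write_target_rules(rules: Iterable[DrugTargetRule], path) -> None:
    pd.DataFrame([vars(r) for r in rules]).to_csv(path, sep="\t", index=False)


def read_biomarker_rules(path) -> list[BiomarkerRule]:
    df = pd.read_csv(path, sep="\t")
    return [BiomarkerRule(r.gene, r.drug, r.direction, r.effect,
                          float(r.threshold), getattr(r, "evidence", ""))
            for r in df.itertuples()]


def write_biomarker_rules(rules: Iterable[BiomarkerRule], path) -> None:
    pd.DataFrame([vars(r) for r in rules]).to_csv(path, sep="\t", index=False)
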