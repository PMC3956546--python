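"""End-to-end orchestration: expression matrices -> per-sample drug reports.

Thin glue over the library modules: run the cross-species profiling
chain, apply all six prediction methods to each human-probeset profile,
and assemble one personalized report per sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from . import crossmap, network, report, rules, signatures
from .synthetic import SyntheticWorld


@dataclass
class MethodSettings:
    n_permutations: int = 50_000
    seed: int = 0
    alpha: float = 0.05
    query_threshold: float = 2.0
    network_mode: str = "threshold"


def predict_drugs(zp: crossmap.ZProfile, world: SyntheticWorld,
                  settings: MethodSettings = MethodSettings()) -> list[report.MethodCall]:
    """All six methods on one z-profile, flattened to method calls."""
    results: list = []
    results += rules.apply_target_rules(zp, world.target_rules)
    results += rules.apply_biomarker_rules(zp, world.biomarker_rules)
    results += signatures.run_response_method(
        zp, world.response_signatures, n_perm=settings.n_permutations,
        seed=settings.seed, alpha=settings.alpha,
        query_threshold=settings.query_threshold)
    results += signatures.run_sensitivity_method(
        zp, world.sensitivity_signatures, alpha=settings.alpha)
    results += network.run_network_method(
        zp, world.network, mode=settings.network_mode, alpha=settings.alpha)
    return report.expand_calls(results)


def profile_world(world: SyntheticWorld,
                  mode: str = "strict") -> list[crossmap.ZProfile]:
    """Tumor matrices through the full z-profiling chain to human probesets."""
    return crossmap.tumor_to_human_probes(
        world.tumors, world.reference, world.canine_annot,
        world.homologs, world.human_annot, mode=mode)


def run_study(world: SyntheticWorld,
              settings: MethodSettings = MethodSettings()
              ) -> tuple[list[crossmap.ZProfile], list[report.PMedReport]]:
    """Profile every tumor and generate its personalized report."""
    profiles = profile_world(world)
    reports = [report.summarize(zp.sample_id, predict_drugs(zp, world, settings))
               for zp in profiles]
    return profiles, reports
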