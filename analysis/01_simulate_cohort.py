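#!/usr/bin/env python
"""Generate the synthetic study cohort.

Builds a 40-sample normal-tissue reference and four tumor cohorts
(lymphoma 5, transitional cell carcinoma 4, melanoma 5, open histology
10) with shared cancer-type signatures and four patient-specific planted
conditions — one per signature/network prediction method — alongside the
full knowledge-base family (260 drug-target rules over 123 drugs, 34
biomarker rules, 107 response signatures, 11 sensitivity signatures, a
directed interaction network, a 184-drug pool).

Writes small summary tables to results/; the full matrices and
knowledge bases go to scratch/synthetic_study/ (regenerable from the
seed).
"""

import json
from pathlib import Path

import pandas as pd

from pmedkit import synthetic

SEED = 20140317
ROOT = Path(__file__).resolve().parents[1]

CONFIG = synthetic.SimulationConfig(
    seed=SEED,
    planted_targets=(("lymphoma01", "TOP2A", 5.0),),
    planted_response=(("tcc01", "drug100"),),
    planted_sensitivity=(("melanoma01", "drug050"),),
    planted_network=(("open01", "cetuximab"),),
)


def main() -> None:
    world = synthetic.generate_world(CONFIG)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    scratch = ROOT / "scratch" / "synthetic_study"
    synthetic.write_world(world, scratch)

    cohorts = pd.Series(world.truth.type_label).value_counts().rename("n_samples")
    cohorts.to_csv(results / "cohorts.csv", index_label="cohort")
    summary = {
        "seed": SEED,
        "n_reference_samples": world.reference.data.shape[1],
        "n_probes": world.reference.data.shape[0],
        "n_retained_genes": len(world.retained_genes),
        "n_ambiguous_canine_genes": len(world.ambiguous_canine),
        "knowledge_bases": {
            "target_rules": len(world.target_rules),
            "target_drugs": len({r.drug for r in world.target_rules}),
            "biomarker_rules": len(world.biomarker_rules),
            "response_signature_drugs": len(world.response_signatures),
            "sensitivity_signature_drugs": len(world.sensitivity_signatures),
            "network_nodes": world.network.graph.number_of_nodes(),
            "network_edges": world.network.graph.number_of_edges(),
            "drug_pool": len(world.drug_pool),
        },
        "planted": {s: {m: sorted(d) for m, d in per.items()}
                    for s, per in world.truth.expected.items() if per},
    }
    (results / "study_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"cohorts: {dict(cohorts)}")
    print(f"knowledge bases: {summary['knowledge_bases']}")
    print(f"planted conditions: {summary['planted']}")
    print(f"full artifacts under {scratch}")


if __name__ == "__main__":
    main()
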