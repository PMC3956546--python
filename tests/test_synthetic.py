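"""Synthetic-study generator: determinism, structure, planted-truth closure."""

import numpy as np
import pandas as pd
import pytest

from pmedkit import crossmap, synthetic
from pmedkit.synthetic import KbSizes, SimulationConfig, generate_world
from conftest import SMALL_KB


class TestDeterminism:
    def test_same_seed_regenerates_identical_artifacts(self):
        cfg = SimulationConfig(seed=8, n_probes=400, kb_sizes=SMALL_KB,
                               n_tumors_per_type={"open": 3})
        w1, w2 = generate_world(cfg), generate_world(cfg)
        assert w1.reference.data.equals(w2.reference.data)
        assert w1.tumors.data.equals(w2.tumors.data)
        assert w1.homologs.rows.equals(w2.homologs.rows)
        assert [r for r in w1.target_rules] == [r for r in w2.target_rules]
        assert sorted(w1.network.graph.edges) == sorted(w2.network.graph.edges)

    def test_different_seeds_differ(self):
        w1 = generate_world(SimulationConfig(seed=1, n_probes=400, kb_sizes=SMALL_KB,
                                             n_tumors_per_type={"open": 2}))
        w2 = generate_world(SimulationConfig(seed=2, n_probes=400, kb_sizes=SMALL_KB,
                                             n_tumors_per_type={"open": 2}))
        assert not w1.tumors.data.equals(w2.tumors.data)


class TestExpression:
    def test_reference_has_requested_columns(self, small_world):
        assert small_world.reference.data.shape[1] == 20
        assert small_world.tumors.data.shape[0] == 600

    def test_null_cohort_z_scores_are_standard(self):
        """With no type effect and no planted targets, tumor z-scores
        against the reference behave like N(0, 1) per probe."""
        cfg = SimulationConfig(seed=21, n_probes=1000, type_effect=0.0,
                               n_tumors_per_type={"open": 6})
        ref, tum, truth = synthetic.generate_expression(cfg)
        stats = crossmap.compute_reference_stats(ref)
        zbar = []
        for c in tum.data.columns:
            zp = crossmap.zscore_sample(tum.data[c], stats)
            zbar.append(zp.values.mean())
        assert abs(np.mean(zbar)) < 0.2
        assert np.std(crossmap.zscore_sample(tum.data.iloc[:, 0], stats).values) \
            == pytest.approx(1.0, abs=0.15)

    def test_planted_truth_records_every_effect(self):
        cfg = SimulationConfig(seed=5, n_probes=800, kb_sizes=SMALL_KB,
                               n_tumors_per_type={"open": 2},
                               planted_targets=(("open01", "TOP2A", 5.0),))
        _, _, truth = synthetic.generate_expression(cfg)
        assert truth.z_shift["open01"]["TOP2A"] == 5.0
        assert truth.type_label["open02"] == "open"

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_probes=-5)
        with pytest.raises(ValueError):
            SimulationConfig(frac_ambiguous_homologs=1.0)
        with pytest.raises(ValueError):
            SimulationConfig(n_tumors_per_type={"open": 0})


class TestKnowledgeBases:
    def test_default_sizes_mirror_the_study(self, default_world):
        w = default_world
        assert len(w.target_rules) == 260
        assert len({r.drug for r in w.target_rules}) == 123
        assert len(w.biomarker_rules) == 34
        assert len({r.drug for r in w.biomarker_rules}) == 20
        assert len(w.response_signatures) == 107
        assert len(w.sensitivity_signatures) == 11
        assert len(w.drug_pool) == 184

    def test_custom_rule_count(self):
        cfg = SimulationConfig(seed=3, n_probes=400,
                               n_tumors_per_type={"open": 2},
                               kb_sizes=KbSizes(target_rules=5, target_drugs=5,
                                                biomarker_rules=10,
                                                biomarker_sensitive_drugs=6,
                                                biomarker_unique_drugs=9,
                                                response_drugs=12,
                                                sensitivity_drugs=5,
                                                sensitivity_genes=10,
                                                drug_pool=60,
                                                network_extra_nodes=15))
        assert len(generate_world(cfg).target_rules) == 5

    def test_network_contains_every_rule_target(self, default_world):
        w = default_world
        targets = {r.gene for r in w.target_rules}
        assert targets <= set(w.network.graph.nodes)
        assert set(w.network.target_drugs) == targets

    def test_exemplar_rules_present(self, default_world):
        w = default_world
        assert any(r.gene == "EGFR_at" and r.drug == "cetuximab"
                   for r in w.target_rules)
        assert any(r.gene == "ERCC1_at" and r.drug == "oxaliplatin"
                   and r.effect == "resistant" for r in w.biomarker_rules)

    def test_planted_closure_every_planted_drug_has_a_trigger(self):
        cfg = SimulationConfig(
            seed=13, n_probes=1500,
            n_tumors_per_type={"open": 4},
            planted_targets=(("open01", "TOP2A", 5.0),),
            planted_response=(("open02", "drug100"),),
            planted_sensitivity=(("open03", "drug050"),),
            planted_network=(("open04", "cetuximab"),))
        w = generate_world(cfg)
        # target: some rule keyed on the planted gene's probeset
        assert any(r.gene == "TOP2A_at" for r in w.target_rules)
        # response: the planted drug has a signature
        assert any(s.drug == "drug100" for s in w.response_signatures)
        # sensitivity: signature exists and its genes were shifted
        sig = next(s for s in w.sensitivity_signatures if s.drug == "drug050")
        shifts = w.truth.z_shift["open03"]
        assert all(g.removesuffix("_at") in shifts for g, _ in sig.genes)
        # network: the planted drug's hub target is a network node with drugs
        assert any("cetuximab" in drugs for drugs in w.network.target_drugs.values())
        for s, per in w.truth.expected.items():
            for method, drugs in per.items():
                assert drugs  # every planted entry resolves to >= 1 drug


class TestHomologTable:
    def test_zero_fraction_is_a_bijection(self):
        cfg = SimulationConfig(seed=4, n_probes=300, frac_ambiguous_homologs=0.0,
                               kb_sizes=SMALL_KB,
                               n_tumors_per_type={"open": 2})
        table, ambiguous = synthetic.generate_homolog_table(cfg)
        assert not ambiguous
        assert table.rows["canine_gene"].is_unique
        assert table.rows["human_gene"].is_unique

    def test_flagged_fraction_by_construction(self):
        cfg = SimulationConfig(seed=4, n_probes=100,
                               probes_per_gene=(1.0, 0.0, 0.0),
                               frac_unannotated_probes=0.0,
                               frac_ambiguous_homologs=0.2,
                               kb_sizes=SMALL_KB,
                               n_tumors_per_type={"open": 2})
        table, ambiguous = synthetic.generate_homolog_table(cfg)
        assert len(ambiguous) == 20
        assert len(table.concise()) == 80


class TestQcFixtureAndLogs:
    def test_fixture_has_31_records_with_printed_values(self):
        recs = {r.sample_id: r for r in synthetic.generate_qc_fixture()}
        assert len(recs) == 31
        assert recs["0507"].rin == 2.60
        assert recs["0506"].tumor_nuclei_category == "0-24%"
        assert recs["0503"].necrosis_category == ">20%"
        assert recs["1301"].rna_conc == 16.67

    def test_fixture_roundtrips_through_gate(self):
        from pmedkit.qc import gate_cohort
        _, summary = gate_cohort(synthetic.generate_qc_fixture())
        assert summary["overall"]["passed"] == 24

    def test_null_profiles_are_standard_normal(self):
        ids = [f"g{i}" for i in range(2000)]
        zps = synthetic.generate_null_profiles(ids, 3, seed=9)
        flat = np.concatenate([zp.values.to_numpy() for zp in zps])
        assert abs(flat.mean()) < 0.05
        assert flat.std() == pytest.approx(1.0, abs=0.05)


def test_write_world_emits_text_artifacts(tmp_path, small_world):
    synthetic.write_world(small_world, tmp_path)
    expected = {"reference.tsv", "tumors.tsv", "homologs.tsv", "target_rules.tsv",
                "biomarker_rules.tsv", "response_signatures.tsv",
                "sensitivity_signatures.tsv", "network_edges.tsv",
                "network_targets.tsv", "planted_truth.json",
                "canine_annotation.tsv", "human_annotation.tsv"}
    assert expected <= {p.name for p in tmp_path.iterdir()}
    back = pd.read_csv(tmp_path / "tumors.tsv", sep="\t", index_col=0)
    assert np.allclose(back.to_numpy(), small_world.tumors.data.to_numpy())
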