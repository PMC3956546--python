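"""Synthetic study generator.

Everything the pipeline consumes can be generated here with planted
ground truth: a normal-tissue reference compendium and tumor cohorts on
a two-platform probe/gene structure, a canine->human homolog table with
a controlled fraction of ambiguous mappings, the five knowledge bases
(drug-target rules, biomarker rules, ranked response signatures, signed
sensitivity signatures, a directed interaction network with a
target->drug map), a 31-record QC fixture carrying the study's printed
failure metrics, and timestamped event logs with prescribed
business-hour spans.

Default sizes mirror the study: a 40-sample normal reference, cohorts of
5/4/5/10 tumors (lymphoma, transitional cell carcinoma, melanoma, open
histology), 260 drug-target rules covering 123 drugs, 34 biomarker
rules over 20 unique drugs, 107 response-signature drugs, 11
sensitivity-signature drugs, and a pool of 184 agents.

The expression model is per-probe Gaussian on log-scale intensities: a
probe's reference distribution has mean mu_p ~ U(5, 11) and sd
sigma_p ~ U(0.2, 0.6); tumor values add the cancer-type signature and
any patient-specific planted effect, both expressed in z units (i.e.
multiples of sigma_p), plus N(0, sigma_p) noise.  Z-scores are the only
downstream consumer, so the distributional family is a stand-in rather
than microarray physics.

A fixed seed makes every artifact bit-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, time, timedelta
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .crossmap import ExpressionMatrix, HomologTable, PlatformAnnotation, ZProfile
from .network import InteractionNetwork
from .qc import QcRecord
from .rules import BiomarkerRule, DrugTargetRule
from .signatures import ResponseSignature, SensitivitySignature
from .turnaround import EASTERN, BusinessCalendar, EventLog, add_business_hours

EXEMPLAR_GENES = ("EGFR", "ERCC1", "TOP2A", "TYMS", "VEGFA", "KIT")
EXEMPLAR_DRUGS = ("cetuximab", "oxaliplatin", "mitoxantrone", "sunitinib", "theophylline")


@dataclass(frozen=True)
class KbSizes:
    target_rules: int = 260
    target_drugs: int = 123
    biomarker_rules: int = 34
    biomarker_sensitive_drugs: int = 14
    biomarker_unique_drugs: int = 20
    response_drugs: int = 107
    sensitivity_drugs: int = 11
    sensitivity_genes: int = 20
    drug_pool: int = 184
    network_extra_nodes: int = 40
    network_out_degree: float = 1.5

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if isinstance(v, int) and v <= 0:
                raise ValueError(f"kb size {name} must be positive")


def _default_cohorts() -> dict[str, int]:
    # Cases passing QA/QC per study cohort; "open" is the mixed-histology cohort.
    return {"lymphoma": 5, "tcc": 4, "melanoma": 5, "open": 10}


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_ref_samples: int = 40
    n_probes: int = 2000
    #: probabilities that a gene owns 1, 2 or 3 probes
    probes_per_gene: tuple[float, ...] = (0.6, 0.3, 0.1)
    n_tumors_per_type: Mapping[str, int] = field(default_factory=_default_cohorts)
    type_effect: float = 2.5          # z units added on each type-signature gene
    genes_per_type: int = 50          # signature size per (non-open) cancer type
    #: patient-specific perturbations: (sample id, human gene, z units)
    planted_targets: tuple[tuple[str, str, float], ...] = ()
    #: (sample id, drug) pairs whose response signature the sample reverses
    planted_response: tuple[tuple[str, str], ...] = ()
    #: (sample id, drug) pairs enriched for the drug's sensitivity signature
    planted_sensitivity: tuple[tuple[str, str], ...] = ()
    #: (sample id, drug) pairs whose over-expressed genes funnel through
    #: one of the drug's network targets
    planted_network: tuple[tuple[str, str], ...] = ()
    kb_sizes: KbSizes = field(default_factory=KbSizes)
    frac_ambiguous_homologs: float = 0.1
    frac_unannotated_probes: float = 0.02
    baseline_range: tuple[float, float] = (5.0, 11.0)
    noise_sd_range: tuple[float, float] = (0.2, 0.6)
    response_plant_genes: int = 25    # up and down set sizes for planted reversal
    network_funnel_genes: int = 12

    def __post_init__(self) -> None:
        if self.n_ref_samples <= 0 or self.n_probes <= 0:
            raise ValueError("sample and probe counts must be positive")
        if any(n <= 0 for n in self.n_tumors_per_type.values()):
            raise ValueError("tumor counts must be positive")
        if not (0.0 <= self.frac_ambiguous_homologs < 1.0):
            raise ValueError("frac_ambiguous_homologs must be in [0, 1)")
        if abs(sum(self.probes_per_gene) - 1.0) > 1e-9:
            raise ValueError("probes_per_gene probabilities must sum to 1")


@dataclass
class PlantedTruth:
    """Everything injected into the cohort, for recovery checks."""

    z_shift: dict[str, dict[str, float]]          # sample -> human gene -> z units
    type_label: dict[str, str]                    # sample -> cancer type
    type_signature_genes: dict[str, tuple[str, ...]]
    expected: dict[str, dict[str, set[str]]]      # sample -> method -> drugs


@dataclass
class SyntheticWorld:
    config: SimulationConfig
    reference: ExpressionMatrix
    tumors: ExpressionMatrix
    truth: PlantedTruth
    canine_annot: PlatformAnnotation
    human_annot: PlatformAnnotation
    homologs: HomologTable
    ambiguous_canine: frozenset[str]
    retained_genes: tuple[str, ...]               # human gene ids surviving the chain
    target_rules: list[DrugTargetRule]
    biomarker_rules: list[BiomarkerRule]
    response_signatures: list[ResponseSignature]
    sensitivity_signatures: list[SensitivitySignature]
    network: InteractionNetwork
    drug_pool: tuple[str, ...]

    def probe_of(self, gene: str) -> str:
        return f"{gene}_at"


# ----------------------------------------------------------------------
# gene / probe / homolog scaffolding


def _gene_structure(cfg: SimulationConfig, rng: np.random.Generator):
    """Human genes, canine genes, probe assignments and the homolog table."""
    n_unann = int(round(cfg.frac_unannotated_probes * cfg.n_probes))
    n_assigned = cfg.n_probes - n_unann
    sizes = []
    total = 0
    while total < n_assigned:
        k = int(rng.choice((1, 2, 3), p=cfg.probes_per_gene))
        k = min(k, n_assigned - total)
        sizes.append(k)
        total += k
    n_genes = len(sizes)
    human_genes = list(EXEMPLAR_GENES[:min(len(EXEMPLAR_GENES), n_genes)])
    human_genes += [f"HG{i:04d}" for i in range(n_genes - len(human_genes))]
    canine_genes = [f"cf{g}" for g in human_genes]

    n_amb = int(round(cfg.frac_ambiguous_homologs * n_genes))
    # flag the tail of the gene list; exemplars and signature/KB genes are
    # drawn from the retained head so planted biology always survives mapping
    ambiguous = canine_genes[n_genes - n_amb:]
    retained_c = canine_genes[:n_genes - n_amb]
    rows = [{"canine_gene": c, "human_gene": h}
            for c, h in zip(retained_c, human_genes[:n_genes - n_amb])]
    # ambiguity, two flavours: a canine gene with two human partners, and
    # two canine genes sharing one human partner
    i = 0
    amb = list(ambiguous)
    while amb:
        if len(amb) >= 2 and i % 2 == 1:
            c1, c2 = amb.pop(), amb.pop()
            shared = f"HGS{i:04d}"
            rows.append({"canine_gene": c1, "human_gene": shared})
            rows.append({"canine_gene": c2, "human_gene": shared})
        else:
            c = amb.pop()
            rows.append({"canine_gene": c, "human_gene": f"HGX{i:04d}a"})
            rows.append({"canine_gene": c, "human_gene": f"HGX{i:04d}b"})
        i += 1
    homologs = HomologTable(pd.DataFrame(rows, columns=["canine_gene", "human_gene"]))

    probe_to_gene = {}
    probes = []
    for g, k in zip(canine_genes, sizes):
        for j in range(k):
            pid = f"{g}_p{j + 1}"
            probes.append(pid)
            probe_to_gene[pid] = g
    for u in range(n_unann):
        probes.append(f"unann_p{u + 1}")
    canine_annot = PlatformAnnotation(pd.Series(probe_to_gene, dtype=object))

    human_side = sorted(set(homologs.rows["human_gene"]))
    human_annot = PlatformAnnotation(
        pd.Series({f"{h}_at": h for h in human_side}, dtype=object))

    retained_h = tuple(human_genes[:n_genes - n_amb])
    return (probes, canine_annot, human_annot, homologs,
            frozenset(ambiguous), retained_h)


# ----------------------------------------------------------------------
# knowledge bases


def _build_drug_pool(cfg: SimulationConfig) -> tuple[str, ...]:
    pool = list(EXEMPLAR_DRUGS)
    i = 1
    while len(pool) < cfg.kb_sizes.drug_pool:
        pool.append(f"drug{i:03d}")
        i += 1
    return tuple(pool[:cfg.kb_sizes.drug_pool])


def _build_knowledge_bases(cfg: SimulationConfig, rng: np.random.Generator,
                           retained: Sequence[str], probe_of,
                           planted_aux: dict) -> dict:
    ks = cfg.kb_sizes
    pool = _build_drug_pool(cfg)
    sig_genes_by_type = planted_aux["type_signature_genes"]
    reserved = set(g for genes in sig_genes_by_type.values() for g in genes)
    reserved |= set(planted_aux.get("aux_region", ()))

    # --- drug-target rules ------------------------------------------------
    # oxaliplatin is reserved as the resistance-rule exemplar drug
    target_drugs = [d for d in pool if d != "oxaliplatin"][:ks.target_drugs]
    if "cetuximab" not in target_drugs:
        target_drugs[0] = "cetuximab"
    must_have = ["EGFR"] + [g for _, g, _ in cfg.planted_targets]
    candidates = [g for g in retained if g not in must_have and g not in reserved]
    n_more = ks.target_rules - len(dict.fromkeys(must_have))
    if n_more > len(candidates):
        raise ValueError("not enough retained genes for the requested rule count")
    chosen = list(dict.fromkeys(must_have)) + \
        list(rng.choice(candidates, size=n_more, replace=False))
    target_rules = []
    for i, gene in enumerate(chosen):
        drug = "cetuximab" if gene == "EGFR" else target_drugs[i % len(target_drugs)]
        target_rules.append(DrugTargetRule(probe_of(gene), drug, 3.0, "synthetic"))

    # --- biomarker rules --------------------------------------------------
    used = set(chosen)
    bm_candidates = [g for g in retained
                     if g not in used and g not in reserved and g != "ERCC1"]
    n_resistant = max(1, ks.biomarker_rules // 4)
    n_sensitive = ks.biomarker_rules - n_resistant
    bm_genes = list(rng.choice(bm_candidates, size=ks.biomarker_rules - 1,
                               replace=False))
    sens_drugs = [d for d in pool if d != "oxaliplatin"][:ks.biomarker_sensitive_drugs]
    n_res_drugs = ks.biomarker_unique_drugs - ks.biomarker_sensitive_drugs
    res_drugs = ["oxaliplatin"] + \
        [d for d in pool if d != "oxaliplatin" and d not in sens_drugs][:n_res_drugs - 1]
    biomarker_rules = [BiomarkerRule(probe_of("ERCC1"), "oxaliplatin",
                                     "over", "resistant", 3.0, "synthetic")]
    gi = iter(bm_genes)
    for i in range(n_sensitive):
        direction = "over" if i % 4 else "under"
        biomarker_rules.append(BiomarkerRule(
            probe_of(next(gi)), sens_drugs[i % len(sens_drugs)],
            direction, "sensitive", 3.0, "synthetic"))
    for i in range(n_resistant - 1):
        biomarker_rules.append(BiomarkerRule(
            probe_of(next(gi)), res_drugs[i % len(res_drugs)],
            "over", "resistant", 3.0, "synthetic"))

    # --- response signatures ---------------------------------------------
    universe = tuple(probe_of(g) for g in retained)
    resp_drugs = list(dict.fromkeys(
        [drug for _, drug in cfg.planted_response] +
        list(pool[ks.drug_pool - ks.response_drugs:])))[:ks.response_drugs]
    planted_resp = {}  # drug -> (up probes, down probes) from the planted sample
    for sample, drug in cfg.planted_response:
        up, down = planted_aux["response_sets"][(sample, drug)]
        planted_resp[drug] = (tuple(probe_of(g) for g in up),
                              tuple(probe_of(g) for g in down))
    response_signatures = []
    for drug in resp_drugs:
        perm = list(rng.permutation(universe))
        if drug in planted_resp:
            up_p, down_p = planted_resp[drug]
            placed = set(up_p) | set(down_p)
            rest = [x for x in perm if x not in placed]
            # tumor-up genes at the bottom, tumor-down genes at the top:
            # the drug's signature is the reversal of the planted profile
            perm = list(down_p) + rest + list(up_p)
        response_signatures.append(ResponseSignature(drug, tuple(perm)))

    # --- sensitivity signatures -------------------------------------------
    sens_sig_drugs = list(dict.fromkeys(
        [drug for _, drug in cfg.planted_sensitivity] +
        [d for d in pool if d not in resp_drugs]))[:ks.sensitivity_drugs]
    used |= {r.gene.removesuffix("_at") for r in biomarker_rules}
    sv_candidates = [g for g in retained if g not in used and g not in reserved]
    sensitivity_signatures = []
    for drug in sens_sig_drugs:
        genes = rng.choice(sv_candidates, size=ks.sensitivity_genes, replace=False)
        signs = rng.choice((1, -1), size=ks.sensitivity_genes)
        sensitivity_signatures.append(SensitivitySignature(
            drug, tuple((probe_of(g), int(s)) for g, s in zip(genes, signs))))

    # --- interaction network ----------------------------------------------
    target_nodes = sorted({r.gene for r in target_rules})
    extra_pool = [probe_of(g) for g in retained
                  if probe_of(g) not in set(target_nodes) and g not in reserved]
    extras = list(rng.choice(extra_pool, size=min(ks.network_extra_nodes,
                                                  len(extra_pool)), replace=False))
    funnel_nodes = [probe_of(g)
                    for genes in planted_aux["network_funnels"].values()
                    for g in genes[1]]
    nodes = sorted(set(target_nodes) | set(extras) | set(funnel_nodes))
    G = nx.DiGraph()
    G.add_nodes_from(nodes)
    n_edges = int(round(ks.network_out_degree * len(nodes)))
    arr = np.array(nodes)
    while G.number_of_edges() < n_edges:
        u, v = rng.choice(arr, size=2, replace=False)
        G.add_edge(str(u), str(v), interaction="synthetic")
    target_drug_map: dict[str, list[str]] = {}
    for r in target_rules:
        target_drug_map.setdefault(r.gene, [])
        if r.drug not in target_drug_map[r.gene]:
            target_drug_map[r.gene].append(r.drug)
    for (sample, drug), (hub_gene, funnel) in planted_aux["network_funnels"].items():
        hub = probe_of(hub_gene)
        for g in funnel:
            fp = probe_of(g)
            G.add_edge(fp, hub, interaction="synthetic-funnel")
            G.add_edge(hub, fp, interaction="synthetic-funnel")
    network = InteractionNetwork(
        G, {n: tuple(d) for n, d in sorted(target_drug_map.items())})

    return {
        "pool": pool,
        "target_rules": target_rules,
        "biomarker_rules": biomarker_rules,
        "response_signatures": response_signatures,
        "sensitivity_signatures": sensitivity_signatures,
        "network": network,
    }


# ----------------------------------------------------------------------
# full world


def generate_world(cfg: SimulationConfig) -> SyntheticWorld:
    """Generate every artifact of one synthetic study, deterministically."""
    rng = np.random.default_rng(cfg.seed)
    (probes, canine_annot, human_annot, homologs,
     ambiguous, retained) = _gene_structure(cfg, rng)

    def probe_of(gene: str) -> str:
        return f"{gene}_at"

    sample_ids = [f"{t}{i + 1:02d}"
                  for t, n in cfg.n_tumors_per_type.items() for i in range(n)]
    type_label = {f"{t}{i + 1:02d}": t
                  for t, n in cfg.n_tumors_per_type.items() for i in range(n)}

    # cancer-type signatures over disjoint retained gene blocks ("open"
    # cohort carries no shared signature — it emulates mixed histologies)
    sig_pool = [g for g in retained if g not in EXEMPLAR_GENES]
    type_sig: dict[str, tuple[str, ...]] = {}
    offset = 0
    for t in cfg.n_tumors_per_type:
        if t == "open":
            continue
        block = sig_pool[offset:offset + cfg.genes_per_type]
        if len(block) < cfg.genes_per_type:
            raise ValueError("not enough retained genes for type signatures")
        type_sig[t] = tuple(block)
        offset += cfg.genes_per_type

    # auxiliary planted gene sets live in a dedicated reserved block of
    # retained genes so knowledge-base rules never key on them; the block
    # is sized from the config, keeping KB construction identical across
    # the two build passes used for network planting
    aux_need = (2 * cfg.response_plant_genes * len(cfg.planted_response)
                + cfg.network_funnel_genes * len(cfg.planted_network))
    aux_region = tuple(sig_pool[offset:offset + aux_need])
    if len(aux_region) < aux_need:
        raise ValueError("not enough retained genes for planted gene sets")
    aux_pool = list(aux_region)
    response_sets: dict[tuple[str, str], tuple[tuple[str, ...], tuple[str, ...]]] = {}
    for sample, drug in cfg.planted_response:
        pick = rng.choice(aux_pool, size=2 * cfg.response_plant_genes, replace=False)
        response_sets[(sample, drug)] = (tuple(pick[:cfg.response_plant_genes]),
                                         tuple(pick[cfg.response_plant_genes:]))
        aux_pool = [g for g in aux_pool if g not in set(pick)]
    network_funnels: dict[tuple[str, str], tuple[str, tuple[str, ...]]] = {}
    planted_aux = {"type_signature_genes": type_sig,
                   "response_sets": response_sets,
                   "network_funnels": network_funnels,
                   "aux_region": aux_region}

    # knowledge bases are built in two passes when network planting is
    # requested: the hub must be one of the drug's rule targets
    kbs = _build_knowledge_bases(cfg, np.random.default_rng(cfg.seed + 1),
                                 retained, probe_of, planted_aux)
    if cfg.planted_network:
        by_drug: dict[str, list[str]] = {}
        for r in kbs["target_rules"]:
            by_drug.setdefault(r.drug, []).append(r.gene)
        for sample, drug in cfg.planted_network:
            if drug not in by_drug:
                raise ValueError(f"planted network drug {drug!r} has no target rule")
            hub_gene = by_drug[drug][0].removesuffix("_at")
            pick = rng.choice(aux_pool, size=cfg.network_funnel_genes, replace=False)
            network_funnels[(sample, drug)] = (hub_gene, tuple(pick))
            aux_pool = [g for g in aux_pool if g not in set(pick)]
        kbs = _build_knowledge_bases(cfg, np.random.default_rng(cfg.seed + 1),
                                     retained, probe_of, planted_aux)

    # --- per-sample planted z shifts (human-gene space) --------------------
    z_shift: dict[str, dict[str, float]] = {s: {} for s in sample_ids}
    for sample, gene, z in cfg.planted_targets:
        z_shift[sample][gene] = z_shift[sample].get(gene, 0.0) + z
    for (sample, drug), (up, down) in response_sets.items():
        for g in up:
            z_shift[sample][g] = z_shift[sample].get(g, 0.0) + 4.0
        for g in down:
            z_shift[sample][g] = z_shift[sample].get(g, 0.0) - 4.0
    sens_by_drug = {s.drug: s for s in kbs["sensitivity_signatures"]}
    for sample, drug in cfg.planted_sensitivity:
        if drug not in sens_by_drug:
            raise ValueError(f"planted sensitivity drug {drug!r} has no signature")
        for probe, sign in sens_by_drug[drug].genes:
            g = probe.removesuffix("_at")
            z_shift[sample][g] = z_shift[sample].get(g, 0.0) + 3.0 * sign
    for (sample, drug), (hub_gene, funnel) in network_funnels.items():
        for g in funnel:
            z_shift[sample][g] = z_shift[sample].get(g, 0.0) + 3.0

    # --- expression matrices ------------------------------------------------
    lo, hi = cfg.baseline_range
    mu = rng.uniform(lo, hi, size=len(probes))
    slo, shi = cfg.noise_sd_range
    sd = rng.uniform(slo, shi, size=len(probes))
    ref_cols = [f"Ref{i + 1:02d}" for i in range(cfg.n_ref_samples)]
    ref = mu[:, None] + rng.normal(0.0, 1.0, (len(probes), cfg.n_ref_samples)) * sd[:, None]
    reference = ExpressionMatrix(
        "canine-probe", pd.DataFrame(ref, index=probes, columns=ref_cols))

    gene_probes: dict[str, list[int]] = {}
    c2h = {f"cf{g}": g for g in retained}
    for idx, p in enumerate(probes):
        cg = canine_annot.probe_to_gene.get(p)
        if cg in c2h:
            gene_probes.setdefault(c2h[cg], []).append(idx)

    tum = mu[:, None] + rng.normal(0.0, 1.0, (len(probes), len(sample_ids))) * sd[:, None]
    for j, s in enumerate(sample_ids):
        shift = dict(z_shift[s])
        t = type_label[s]
        for g in type_sig.get(t, ()):
            shift[g] = shift.get(g, 0.0) + cfg.type_effect
        for g, dz in shift.items():
            for idx in gene_probes.get(g, ()):
                tum[idx, j] += dz * sd[idx]
    tumors = ExpressionMatrix(
        "canine-probe", pd.DataFrame(tum, index=probes, columns=sample_ids))

    # --- expected drugs per sample and method -------------------------------
    rules_by_gene: dict[str, list[DrugTargetRule]] = {}
    for r in kbs["target_rules"]:
        rules_by_gene.setdefault(r.gene, []).append(r)
    expected: dict[str, dict[str, set[str]]] = {s: {} for s in sample_ids}
    for sample, gene, z in cfg.planted_targets:
        for r in rules_by_gene.get(probe_of(gene), ()):
            if z >= r.threshold:
                expected[sample].setdefault("target-expression", set()).add(r.drug)
    for sample, drug in cfg.planted_response:
        expected[sample].setdefault("response-signature", set()).add(drug)
    for sample, drug in cfg.planted_sensitivity:
        expected[sample].setdefault("sensitivity-signature", set()).add(drug)
    for sample, drug in cfg.planted_network:
        expected[sample].setdefault("network-activity", set()).add(drug)

    truth = PlantedTruth(z_shift, type_label, type_sig, expected)
    return SyntheticWorld(
        config=cfg, reference=reference, tumors=tumors, truth=truth,
        canine_annot=canine_annot, human_annot=human_annot, homologs=homologs,
        ambiguous_canine=ambiguous, retained_genes=retained,
        target_rules=kbs["target_rules"], biomarker_rules=kbs["biomarker_rules"],
        response_signatures=kbs["response_signatures"],
        sensitivity_signatures=kbs["sensitivity_signatures"],
        network=kbs["network"], drug_pool=kbs["pool"])


# ----------------------------------------------------------------------
# public generator operations


def generate_expression(cfg: SimulationConfig):
    """(reference matrix, tumor matrix, planted truth) for one synthetic study."""
    world = generate_world(cfg)
    return world.reference, world.tumors, world.truth


def generate_knowledge_bases(cfg: SimulationConfig):
    """(target rules, biomarker rules, response sigs, sensitivity sigs, network, pool)."""
    world = generate_world(cfg)
    return (world.target_rules, world.biomarker_rules, world.response_signatures,
            world.sensitivity_signatures, world.network, world.drug_pool)


def generate_homolog_table(cfg: SimulationConfig) -> tuple[HomologTable, frozenset[str]]:
    """(homolog table, set of canine genes flagged ambiguous/dropped)."""
    world = generate_world(cfg)
    return world.homologs, world.ambiguous_canine


def generate_null_profiles(ids: Sequence[str], n_samples: int,
                           seed: int = 0, space: str = "human-probe") -> list[ZProfile]:
    """Standard-normal z-profiles — the no-signal condition for calibration."""
    rng = np.random.default_rng(seed)
    ids = pd.Index(ids)
    return [ZProfile(f"null{i + 1:03d}", space,
                     pd.Series(rng.normal(size=len(ids)), index=ids))
            for i in range(n_samples)]


# ----------------------------------------------------------------------
# QC fixture (31 enrollment records)


def _passing_record(sample_id: str, cohort: str, i: int) -> QcRecord:
    return QcRecord(
        sample_id=sample_id, cohort=cohort,
        tumor_surface_category="75-100%", tumor_nuclei_category="75-100%",
        necrosis_category="<10%",
        rna_conc=120.0 + 17.0 * (i % 9), rna_volume=14.0,
        rna_ratio=2.0 + 0.01 * (i % 5), rin=8.5 + 0.1 * (i % 10),
        cdna_yield=30.0 + 2.0 * (i % 7), cdna_ratio=1.9 + 0.02 * (i % 4),
        array_background=55.0 + 3.0 * (i % 8), array_present_call=42.0 + (i % 6),
        array_scale_factor=80.0 + 10.0 * (i % 5),
    )


def generate_qc_fixture() -> list[QcRecord]:
    """31 QC records: 7 failures carrying the study's printed metric values
    (metrics recorded as N/A substituted with passing values), 24 passes.

    Stages never reached are left unmeasured: the RNA-failing sample has
    no cDNA or array metrics, the six histopathology failures have cDNA
    metrics (measured for every RNA-passing sample) but no array metrics.
    """
    cdna_ok = {"cdna_yield": 25.0, "cdna_ratio": 2.0}
    failures = [
        # transitional cell carcinoma, trigonal: too little tumor
        QcRecord("0204", "tcc", "75-100%", "25-49%", "10-20%",
                 rna_conc=3.91, rna_ratio=3.76, rin=9.0, **cdna_ok),
        # lymphoma: high necrosis
        QcRecord("0503", "open", "75-100%", "75-100%", ">20%",
                 rna_conc=3092.04, rna_ratio=2.03, rin=9.40, **cdna_ok),
        # appendicular osteosarcoma: too little viable tumor
        QcRecord("0506", "open", "75-100%", "0-24%", "<10%",
                 rna_conc=69.99, rna_ratio=2.08, rin=9.60, **cdna_ok),
        # mast cell tumor: degraded RNA from connective tissue
        QcRecord("0507", "open", "75-100%", "75-100%", "<10%",
                 rna_conc=614.62, rna_ratio=2.10, rin=2.60),
        # mucosal melanoma, mandible: sample too small
        QcRecord("0502", "melanoma", "75-100%", "0-24%", "<10%",
                 rna_conc=536.99, rna_ratio=2.08, rin=8.2, **cdna_ok),
        # lymphoma: sample too small
        QcRecord("1301", "open", "75-100%", "0-24%", "<10%",
                 rna_conc=16.67, rna_ratio=1.93, rin=9.60, **cdna_ok),
        # histiocytic sarcoma: non-cancer diagnosis (panniculitis)
        QcRecord("1302", "open", "75-100%", "0-24%", "<10%",
                 rna_conc=657.76, rna_ratio=2.12, rin=9.80, **cdna_ok),
    ]
    passing_plan = [("tcc", 4), ("lymphoma", 5), ("melanoma", 5), ("open", 10)]
    passing = []
    i = 0
    for cohort, n in passing_plan:
        for j in range(n):
            passing.append(_passing_record(f"{cohort[:3]}{200 + i:03d}", cohort, i))
            i += 1
    records = failures + passing
    assert len(records) == 31
    return records


# ----------------------------------------------------------------------
# event logs


#: Study per-cohort mean turnaround hours for the 24 passing cases.
COHORT_TURNAROUND_HOURS = {
    "open": (10, 114.50, 174.50),
    "lymphoma": (5, 117.00, 165.00),
    "tcc": (4, 116.75, 158.75),
    "melanoma": (5, 119.60, 167.60),
}


def cohort_case_targets() -> list[tuple[str, str, float, float]]:
    """Per-case (sample id, cohort, business hours, total hours) reproducing
    the printed cohort rows: each case carries its cohort's mean."""
    out = []
    for cohort, (n, bh, th) in COHORT_TURNAROUND_HOURS.items():
        for i in range(n):
            out.append((f"{cohort}{i + 1:02d}", cohort, bh, th))
    return out


EVENT_SEQUENCE = ("biopsy", "shipped", "arrived_lab", "qc_complete",
                  "expression_complete", "report_sent")
_EVENT_FRACTIONS = (0.0, 0.08, 0.2, 0.45, 0.8, 1.0)


def generate_event_logs(targets: Sequence[tuple[str, str, float]] | None = None,
                        seed: int = 0,
                        cal: BusinessCalendar = BusinessCalendar()) -> list[EventLog]:
    """Event logs whose biopsy -> report business-hour spans equal the
    requested per-case durations under the business-hours clock.

    ``targets`` rows are (sample id, cohort, business hours); extra
    elements are ignored, so `cohort_case_targets()` rows work directly.
    Start times are staggered weekday mornings across the May-October
    2011 study window; a third of the cases are recorded in their site's
    Central-time zone to exercise zone conversion.
    """
    from zoneinfo import ZoneInfo
    if targets is None:
        targets = cohort_case_targets()
    rng = np.random.default_rng(seed)
    central = ZoneInfo("America/Chicago")
    logs = []
    for i, row in enumerate(targets):
        sample_id, cohort, bh = row[0], row[1], float(row[2])
        day = datetime(2011, 5, 16, tzinfo=EASTERN) + timedelta(days=7 * (i % 20))
        while cal.is_excluded(day.date()):
            day += timedelta(days=1)
        start = day.replace(hour=int(rng.integers(8, 12)),
                            minute=int(rng.integers(0, 60)))
        events = []
        for label, frac in zip(EVENT_SEQUENCE, _EVENT_FRACTIONS):
            ts = add_business_hours(start, bh * frac, cal)
            if i % 3 == 0:
                ts = ts.astimezone(central)
            events.append((label, ts))
        logs.append(EventLog(sample_id, cohort, events))
    return logs


# ----------------------------------------------------------------------
# writers


def write_world(world: SyntheticWorld, outdir) -> None:
    """Emit every artifact as flat text files (TSV/CSV/JSON)."""
    import json
    from pathlib import Path

    from . import rules as rules_io
    from . import signatures as sig_io
    from .network import write_network

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    world.reference.data.to_csv(out / "reference.tsv", sep="\t")
    world.tumors.data.to_csv(out / "tumors.tsv", sep="\t")
    world.canine_annot.probe_to_gene.rename("gene").to_csv(
        out / "canine_annotation.tsv", sep="\t", index_label="probe")
    world.human_annot.probe_to_gene.rename("gene").to_csv(
        out / "human_annotation.tsv", sep="\t", index_label="probe")
    world.homologs.rows.to_csv(out / "homologs.tsv", sep="\t", index=False)
    rules_io.write_target_rules(world.target_rules, out / "target_rules.tsv")
    rules_io.write_biomarker_rules(world.biomarker_rules, out / "biomarker_rules.tsv")
    sig_io.write_response_signatures(world.response_signatures,
                                     out / "response_signatures.tsv")
    sig_io.write_sensitivity_signatures(world.sensitivity_signatures,
                                        out / "sensitivity_signatures.tsv")
    write_network(world.network, out / "network_edges.tsv", out / "network_targets.tsv")
    truth = {
        "z_shift": world.truth.z_shift,
        "type_label": world.truth.type_label,
        "expected": {s: {m: sorted(d) for m, d in per.items()}
                     for s, per in world.truth.expected.items()},
    }
    (out / "planted_truth.json").write_text(json.dumps(truth, indent=2))
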