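"""Tumor expression -> human-probeset z-score profiles.

The profiling chain standardizes each tumor probe against a normal-tissue
reference compendium (z = (x - mu) / sigma per probe), averages probe
z-scores to one value per canine gene, carries values across species
through a strictly one-to-one canine->human homolog table (any ambiguity
on either side drops the gene), and finally keys the profile by human
array probesets so that downstream predictors built on human knowledge
bases can consume it.

Identifier spaces form a fixed chain and every operation checks its
input's space tag:

    canine-probe -> canine-gene -> human-gene -> human-probe

Mapping steps never alter z values; only the probe->gene aggregation
changes magnitudes (by averaging).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd

SPACES = ("canine-probe", "canine-gene", "human-gene", "human-probe")


@dataclass
class ExpressionMatrix:
    """Expression intensities, rows = identifiers, columns = samples."""

    space: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.space not in SPACES:
            raise ValueError(f"unknown identifier space {self.space!r}")
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValueError("duplicate row or column identifiers")
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")


@dataclass
class ReferenceStats:
    """Per-identifier mean/sd over the reference samples (sd uses n-1)."""

    space: str
    mean: pd.Series
    sd: pd.Series
    n_ref: int

    @property
    def zero_sd_ids(self) -> pd.Index:
        return self.sd.index[self.sd == 0.0]


@dataclass
class ZProfile:
    """One sample's z-scores keyed by identifiers of a tagged space."""

    sample_id: str
    space: str
    values: pd.Series

    def __post_init__(self) -> None:
        if self.space not in SPACES:
            raise ValueError(f"unknown identifier space {self.space!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate identifiers in profile")

    def _require_space(self, space: str) -> None:
        if self.space != space:
            raise ValueError(
                f"profile is in space {self.space!r}, expected {space!r}")


@dataclass
class PlatformAnnotation:
    """probe id -> gene id for one array platform (unannotated probes absent)."""

    probe_to_gene: pd.Series

    def __post_init__(self) -> None:
        if self.probe_to_gene.index.has_duplicates:
            raise ValueError("a probe maps to more than one gene")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "PlatformAnnotation":
        return cls(pd.Series(dict(mapping), dtype=object))


@dataclass
class HomologTable:
    """Canine->human gene rows; not necessarily one-to-one before filtering."""

    rows: pd.DataFrame  # columns: canine_gene, human_gene

    def __post_init__(self) -> None:
        missing = {"canine_gene", "human_gene"} - set(self.rows.columns)
        if missing:
            raise ValueError(f"homolog table missing columns {missing}")

    def concise(self) -> pd.DataFrame:
        """Rows whose canine and human genes each appear in exactly one row."""
        c_counts = self.rows["canine_gene"].value_counts()
        h_counts = self.rows["human_gene"].value_counts()
        keep = (self.rows["canine_gene"].map(c_counts) == 1) & \
               (self.rows["human_gene"].map(h_counts) == 1)
        return self.rows[keep]


def compute_reference_stats(ref: ExpressionMatrix) -> ReferenceStats:
    if ref.data.shape[1] < 2:
        raise ValueError("reference stats require at least 2 samples")
    mean = ref.data.mean(axis=1)
    sd = ref.data.std(axis=1, ddof=1)
    stats = ReferenceStats(ref.space, mean, sd, n_ref=ref.data.shape[1])
    if len(stats.zero_sd_ids):
        warnings.warn(f"{len(stats.zero_sd_ids)} identifiers have zero reference "
                      "variance; they will be dropped at z-scoring")
    return stats


def zscore_sample(sample: pd.Series, stats: ReferenceStats,
                  sample_id: str | None = None) -> ZProfile:
    """Standardize one sample column against the reference distribution."""
    missing = stats.mean.index.difference(sample.index)
    if len(missing):
        raise ValueError(f"sample is missing {len(missing)} reference identifiers: "
                         f"{sorted(missing[:5].tolist())}...")
    usable = stats.sd.index[stats.sd > 0.0]
    if len(usable) < len(stats.sd):
        warnings.warn(f"dropping {len(stats.sd) - len(usable)} zero-variance "
                      "identifiers from z-profile")
    z = (sample.loc[usable] - stats.mean.loc[usable]) / stats.sd.loc[usable]
    return ZProfile(sample_id or str(sample.name), stats.space, z)


def zscore_matrix(tumors: ExpressionMatrix, stats: ReferenceStats) -> list[ZProfile]:
    if tumors.space != stats.space:
        raise ValueError("tumor matrix and reference stats are in different spaces")
    return [zscore_sample(tumors.data[c], stats, str(c)) for c in tumors.data.columns]


def aggregate_to_genes(zp: ZProfile, annot: PlatformAnnotation) -> ZProfile:
    """Mean of probe z-scores per annotated gene; unannotated probes dropped."""
    zp._require_space("canine-probe")
    genes = annot.probe_to_gene.reindex(zp.values.index).dropna()
    if genes.empty:
        raise ValueError("no probe in the profile carries a gene annotation")
    agg = zp.values.loc[genes.index].groupby(genes).mean()
    agg.index.name = None
    return ZProfile(zp.sample_id, "canine-gene", agg)


def map_homologs(zp: ZProfile, table: HomologTable) -> ZProfile:
    """Relabel canine genes as human genes through concise one-to-one rows."""
    zp._require_space("canine-gene")
    if table.rows.empty:
        raise ValueError("empty homolog table")
    concise = table.concise().set_index("canine_gene")["human_gene"]
    mapped = concise.reindex(zp.values.index).dropna()
    out = zp.values.loc[mapped.index]
    out.index = mapped.values
    return ZProfile(zp.sample_id, "human-gene", out)


def project_to_probesets(zp: ZProfile, annot: PlatformAnnotation,
                         mode: Literal["strict", "fanout"] = "strict") -> ZProfile:
    """Key the profile by human probesets.

    ``strict`` keeps only genes owning exactly one probeset (mirrors the
    concise-mapping requirement); ``fanout`` replicates a gene's z onto
    every probeset it owns.
    """
    zp._require_space("human-gene")
    gene_to_probes = annot.probe_to_gene.reset_index()
    gene_to_probes.columns = ["probe", "gene"]
    grouped = gene_to_probes.groupby("gene")["probe"]
    values, index = [], []
    for gene, z in zp.values.items():
        try:
            probes = grouped.get_group(gene)
        except KeyError:
            continue
        if mode == "strict" and len(probes) != 1:
            continue
        for p in probes:
            index.append(p)
            values.append(z)
    return ZProfile(zp.sample_id, "human-probe", pd.Series(values, index=index, dtype=float))


def tumor_to_human_probes(tumors: ExpressionMatrix, ref: ExpressionMatrix,
                          canine_annot: PlatformAnnotation, homologs: HomologTable,
                          human_annot: PlatformAnnotation,
                          mode: Literal["strict", "fanout"] = "strict") -> list[ZProfile]:
    """Full chain: probe z-scores -> gene means -> homologs -> human probesets."""
    stats = compute_reference_stats(ref)
    out = []
    for zp in zscore_matrix(tumors, stats):
        zp = aggregate_to_genes(zp, canine_annot)
        zp = map_homologs(zp, homologs)
        out.append(project_to_probesets(zp, human_annot, mode=mode))
    return out


def read_matrix(path, space: str) -> ExpressionMatrix:
    return ExpressionMatrix(space, pd.read_csv(path, sep="\t", index_col=0))


def write_matrix(mat: ExpressionMatrix, path) -> None:
    mat.data.to_csv(path, sep="\t")
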