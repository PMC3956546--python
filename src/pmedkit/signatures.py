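"""Signature-based drug prediction.

Two methods operate on a tumor z-profile:

* **Drug response signatures** — the connectivity-map concept: the
  tumor's strongly over-expressed (z >= +2) and under-expressed
  (z <= -2) identifiers are located within each drug's ranked
  post-exposure expression signature.  A Kolmogorov-Smirnov enrichment
  score per set is combined into a connectivity score in [-1, 1];
  *negative* (inverse) connectivity means the drug's signature reverses
  the tumor profile.  Significance comes from a permutation test on
  random queries of the same sizes.

* **Drug sensitivity signatures** — parametric gene-set enrichment
  (PGSEA): for a signed signature derived from cell-line IC-50 response,
  the signed tumor z-scores of the signature genes are submitted to a
  one-sample t-test; a significantly positive mean marks the tumor as
  resembling the sensitive-line expression pattern.

Both methods report drugs at raw p < 0.05, mirroring per-method
reporting without cross-drug multiplicity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .crossmap import ZProfile

METHOD_RESPONSE = "response-signature"
METHOD_SENSITIVITY = "sensitivity-signature"


@dataclass
class ResponseSignature:
    """Drug's ranked identifier list, most up-regulated by the drug first."""

    drug: str
    ranking: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ranking) < 2:
            raise ValueError("signature universe must have >= 2 identifiers")
        if len(set(self.ranking)) != len(self.ranking):
            raise ValueError("ranking contains duplicate identifiers")


@dataclass
class SensitivitySignature:
    """Signed gene set; sign +1 marks higher expression in sensitive lines."""

    drug: str
    genes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise ValueError("signature needs >= 2 genes")
        if any(s not in (1, -1) for _, s in self.genes):
            raise ValueError("signs must be +1 or -1")


@dataclass
class QuerySet:
    up: frozenset[str]
    down: frozenset[str]

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down query sets overlap")


@dataclass
class ConnectivityResult:
    drug: str
    es_up: float | None
    es_down: float | None
    s: float
    p: float | None = None
    n_permutations: int | None = None
    score: float | None = None
    genes: list = field(default_factory=list)

    method = METHOD_RESPONSE
    verdict = "indicated"


@dataclass
class EnrichmentResult:
    drug: str
    t: float
    df: int
    p: float
    mean_signed_z: float
    m: int
    sd_zero: bool = False
    score: float | None = None
    genes: list = field(default_factory=list)

    method = METHOD_SENSITIVITY
    verdict = "indicated"


def build_query(zp: ZProfile, threshold: float = 2.0) -> QuerySet:
    """Tumor identifiers with z >= +threshold (up) or z <= -threshold (down)."""
    z = zp.values
    return QuerySet(frozenset(z.index[z >= threshold]),
                    frozenset(z.index[z <= -threshold]))


def ks_enrichment(members: set[str], ranking: Sequence[str]) -> float:
    """KS enrichment of ``members`` within a ranked list, in [-1, 1].

    With V(1..t) the ascending ranks of the members among n list
    positions, a = max_j(j/t - V(j)/n), b = max_j(V(j)/n - (j-1)/t);
    ES = a if a > b else -b.  Positive ES: members concentrate at the
    top of the ranking; negative: at the bottom.
    """
    pos = {ident: i + 1 for i, ident in enumerate(ranking)}
    V = sorted(pos[m] for m in members if m in pos)
    if not V:
        raise ValueError("gene set does not intersect the signature universe")
    return _es_from_sorted_ranks(np.asarray(V, dtype=float)[None, :], len(ranking))[0]


def _es_from_sorted_ranks(V: np.ndarray, n: int) -> np.ndarray:
    """Vectorized ES for rows of ascending rank vectors V (k x t) in a list of n."""
    k, t = V.shape
    j = np.arange(1, t + 1, dtype=float)
    a = (j / t - V / n).max(axis=1)
    b = (V / n - (j - 1) / t).max(axis=1)
    return np.where(a > b, a, -b)


def connectivity_score(q: QuerySet, sig: ResponseSignature) -> ConnectivityResult:
    """Combine up/down enrichment into one score; 0 when signs agree.

    s = (ES_up - ES_down)/2 when the two enrichments disagree in sign
    (the informative case); if only one query set intersects the
    universe, its enrichment carries the score alone.
    """
    universe = set(sig.ranking)
    up = q.up & universe
    down = q.down & universe
    if not up and not down:
        raise ValueError("neither query set intersects the signature universe")
    es_up = ks_enrichment(up, sig.ranking) if up else None
    es_down = ks_enrichment(down, sig.ranking) if down else None
    if es_up is None:
        s = -es_down
    elif es_down is None:
        s = es_up
    elif (es_up >= 0) == (es_down >= 0):
        s = 0.0
    else:
        s = (es_up - es_down) / 2.0
    return ConnectivityResult(sig.drug, es_up, es_down, float(s))


@lru_cache(maxsize=64)
def _null_connectivity(t_up: int, t_down: int, n: int,
                       n_perm: int, seed: int) -> np.ndarray:
    """Null connectivity scores for random disjoint query sets of fixed sizes.

    A random query set against a fixed ranking is a uniform random set
    of ranks, so the null depends only on (t_up, t_down, n) — it is
    shared by every drug signature over the same universe.
    """
    rng = np.random.default_rng(seed)
    t = t_up + t_down
    s = np.zeros(n_perm)
    if t == 0:
        return s
    # ranks of a random t-subset of 1..n per permutation, via random keys
    keys = rng.random((n_perm, n))
    subset = np.argpartition(keys, t - 1, axis=1)[:, :t] + 1
    es_up = es_down = None
    if t_up:
        up = np.sort(subset[:, :t_up], axis=1).astype(float)
        es_up = _es_from_sorted_ranks(up, n)
    if t_down:
        down = np.sort(subset[:, t_up:], axis=1).astype(float)
        es_down = _es_from_sorted_ranks(down, n)
    if es_up is None:
        return -es_down
    if es_down is None:
        return es_up
    same_sign = (es_up >= 0) == (es_down >= 0)
    return np.where(same_sign, 0.0, (es_up - es_down) / 2.0)


def permutation_p(s_obs: float, t_up: int, t_down: int, n: int,
                  n_perm: int = 50_000, seed: int = 0) -> float:
    """Add-one permutation p for inverse connectivity: P(s_null <= s_obs).

    p = (1 + #{s_perm <= s_obs}) / (n_perm + 1), so the smallest
    attainable p is 1/(n_perm + 1) and p can never be 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    null = _null_connectivity(t_up, t_down, n, n_perm, seed)
    return float((1 + int((null <= s_obs).sum())) / (n_perm + 1))


def run_response_method(zp: ZProfile, signatures: Sequence[ResponseSignature],
                        n_perm: int = 50_000, seed: int = 0,
                        alpha: float = 0.05,
                        query_threshold: float = 2.0) -> list[ConnectivityResult]:
    """Scan every drug signature; keep inverse-connectivity hits with p < alpha."""
    if not signatures:
        raise ValueError("empty signature database")
    q = build_query(zp, query_threshold)
    results = []
    for sig in signatures:
        universe = set(sig.ranking)
        up, down = q.up & universe, q.down & universe
        if not up and not down:
            continue
        res = connectivity_score(q, sig)
        res.p = permutation_p(res.s, len(up), len(down), len(sig.ranking),
                              n_perm=n_perm, seed=seed)
        res.n_permutations = n_perm
        if res.s < 0 and res.p < alpha:
            res.score = -math.log10(res.p)
            res.genes = sorted(up | down)
            results.append(res)
    return sorted(results, key=lambda r: (r.p, r.drug))


def pgsea_score(zp: ZProfile, sig: SensitivitySignature) -> EnrichmentResult | None:
    """One-sample t-test on signed z-scores of the signature genes.

    v_i = sign_i * z_i over the m >= 2 signature genes present in the
    profile; t = mean(v) / (sd(v)/sqrt(m)) with a one-sided upper-tail p
    on m-1 degrees of freedom.  Returns None when fewer than 2 genes
    overlap.
    """
    v = np.array([s * zp.values[g] for g, s in sig.genes if g in zp.values.index])
    m = len(v)
    if m < 2:
        return None
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if sd == 0.0:
        t = math.inf if mean > 0 else (-math.inf if mean < 0 else 0.0)
        p = float(np.finfo(float).tiny) if mean > 0 else 1.0
        return EnrichmentResult(sig.drug, t, m - 1, p, mean, m, sd_zero=True)
    t = mean / (sd / math.sqrt(m))
    p = float(sps.t.sf(t, m - 1))
    return EnrichmentResult(sig.drug, float(t), m - 1, p, mean, m)


def run_sensitivity_method(zp: ZProfile, signatures: Sequence[SensitivitySignature],
                           alpha: float = 0.05) -> list[EnrichmentResult]:
    """PGSEA over the signature database; keep drugs with p < alpha."""
    if not signatures:
        raise ValueError("empty signature database")
    results = []
    for sig in signatures:
        res = pgsea_score(zp, sig)
        if res is not None and res.p < alpha:
            res.score = -math.log10(res.p)
            res.genes = [g for g, _ in sig.genes if g in zp.values.index]
            results.append(res)
    return sorted(results, key=lambda r: (r.p, r.drug))


def read_response_signatures(path) -> list[ResponseSignature]:
    """TSV columns (drug, rank, identifier), rank 1 = most up-regulated."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for drug, grp in df.groupby("drug", sort=True):
        ranking = tuple(grp.sort_values("rank")["identifier"])
        out.append(ResponseSignature(str(drug), ranking))
    return out


def write_response_signatures(sigs: Sequence[ResponseSignature], path) -> None:
    rows = [{"drug": s.drug, "rank": i + 1, "identifier": ident}
            for s in sigs for i, ident in enumerate(s.ranking)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sensitivity_signatures(path) -> list[SensitivitySignature]:
    df = pd.read_csv(path, sep="\t")
    return [SensitivitySignature(str(drug),
                                 tuple((str(r.gene), int(r.sign)) for r in grp.itertuples()))
            for drug, grp in df.groupby("drug", sort=True)]


def write_sensitivity_signatures(sigs: Sequence[SensitivitySignature], path) -> None:
    rows = [{"drug": s.drug, "gene": g, "sign": sign}
            for s in sigs for g, sign in s.genes]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
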