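"""All-vs-all pairwise genotype comparison, duplicate detection and
gene-pool consistency checking — the quality-control heart of SNP
fingerprinting.

For every sample pair, over markers called in both samples:

* identical states are matches;
* two different homozygous calls are *homozygous differences* — in inbred
  material this is strong evidence the samples are not the same line;
* every other difference (het vs hom) is a *heterozygous difference*;
* the allele-match similarity scores 1 for an identical genotype, 0.5 for
  one shared allele (hom vs het on that allele) and 0 for no shared allele,
  averaged over the shared markers.  This is the "correlation" used to sort
  fingerprinting similarity matrices.

Two samples are treated as the same germplasm when their homozygous
mismatch rate is below 1% (with a minimum overlap guard); duplicate groups
are the connected components of that identity relation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .model import HET, HOM_A, HOM_B, MISSING, GenotypeMatrix, SampleMeta

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairComparison:
    sample_a: str
    sample_b: str
    n_a: int            # markers genotyped in sample a
    n_b: int            # markers genotyped in sample b
    n_shared: int       # markers genotyped in both
    het_diffs: int
    hom_diffs: int
    total_diffs: int
    pct_het_diffs: float | None
    pct_hom_diffs: float | None
    pct_total_diffs: float | None
    similarity: float | None  # None when the pair is incomparable (n_shared == 0)

    @property
    def comparable(self) -> bool:
        return self.n_shared > 0


@dataclass
class IdentityRule:
    """Identity = pct_hom_diffs strictly below ``max_pct_hom_diffs`` with at
    least ``min_shared`` markers scored in both samples.  Pairs passing the
    homozygous-mismatch rule but falling below ``min_similarity`` are flagged
    borderline (sister-line signature)."""

    max_pct_hom_diffs: float = 0.01
    min_similarity: float = 0.99
    min_shared: int = 100

    def __post_init__(self):
        if not 0 <= self.max_pct_hom_diffs <= 1:
            raise ValueError("max_pct_hom_diffs must be in [0, 1]")
        if not 0 <= self.min_similarity <= 1:
            raise ValueError("min_similarity must be in [0, 1]")


@dataclass
class DuplicateGroups:
    groups: list[list[str]]                    # connected components (sorted)
    per_sample_duplicate_count: dict[str, int]  # identical partners per sample
    borderline_pairs: list[tuple[str, str]]    # identity rule met, similarity low


class SimilarityMatrix:
    """Symmetric grid of pairwise comparison statistics for one matrix.

    Backed by dense arrays; ``pair(a, b)`` materialises a
    :class:`PairComparison` and ``to_dataframe`` dumps one row per unordered
    pair (the fingerprinting pair table).
    """

    def __init__(self, matrix: GenotypeMatrix):
        if matrix.n_samples < 2:
            raise ValueError("similarity matrix needs >= 2 samples")
        self.names = matrix.sample_names
        C = matrix.codes
        called = (C != MISSING)
        a0 = (C == HOM_A).astype(np.float32)
        a1 = (C == HOM_B).astype(np.float32)
        a2 = (C == HET).astype(np.float32)
        m = called.astype(np.float32)
        self.n_per_sample = called.sum(axis=1).astype(np.int64)
        self.n_shared = np.rint(m @ m.T).astype(np.int64)
        self.matches = np.rint(a0 @ a0.T + a1 @ a1.T + a2 @ a2.T).astype(np.int64)
        self.hom_diffs = np.rint(a0 @ a1.T + a1 @ a0.T).astype(np.int64)
        self.het_diffs = self.n_shared - self.matches - self.hom_diffs
        with np.errstate(invalid="ignore", divide="ignore"):
            self.similarity = np.where(
                self.n_shared > 0,
                (self.matches + 0.5 * self.het_diffs) / np.maximum(self.n_shared, 1),
                np.nan,
            )
        self._index = {n: i for i, n in enumerate(self.names)}

    @property
    def n(self) -> int:
        return len(self.names)

    def pair(self, a: str, b: str) -> PairComparison:
        i, j = self._index[a], self._index[b]
        ns = int(self.n_shared[i, j])
        hd = int(self.het_diffs[i, j])
        od = int(self.hom_diffs[i, j])
        td = hd + od
        if ns:
            return PairComparison(a, b, int(self.n_per_sample[i]),
                                  int(self.n_per_sample[j]), ns, hd, od, td,
                                  hd / ns, od / ns, td / ns,
                                  float(self.similarity[i, j]))
        return PairComparison(a, b, int(self.n_per_sample[i]),
                              int(self.n_per_sample[j]), 0, 0, 0, 0,
                              None, None, None, None)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                rows.append(self.pair(self.names[i], self.names[j]))
        return pd.DataFrame([r.__dict__ for r in rows])

    def similarity_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.similarity, index=self.names, columns=self.names)


def compare_pair(matrix: GenotypeMatrix, a: str, b: str) -> PairComparison:
    """Compare two samples marker by marker (see module docstring for the
    match / hom-diff / het-diff / similarity definitions)."""
    i = matrix.sample_index(a)
    j = matrix.sample_index(b)
    ca, cb = matrix.codes[i], matrix.codes[j]
    called_a, called_b = ca != MISSING, cb != MISSING
    both = called_a & called_b
    n_a, n_b = int(called_a.sum()), int(called_b.sum())
    ns = int(both.sum())
    if ns == 0:
        logger.warning("pair (%s, %s) shares no genotyped markers; incomparable", a, b)
        return PairComparison(a, b, n_a, n_b, 0, 0, 0, 0, None, None, None, None)
    xa, xb = ca[both], cb[both]
    matches = int((xa == xb).sum())
    hom = int(((xa != xb) & (xa != HET) & (xb != HET)).sum())
    het = ns - matches - hom
    sim = (matches + 0.5 * het) / ns
    return PairComparison(a, b, n_a, n_b, ns, het, hom, het + hom,
                          het / ns, hom / ns, (het + hom) / ns, sim)


def similarity_matrix(matrix: GenotypeMatrix) -> SimilarityMatrix:
    """All-vs-all comparison of every unordered sample pair."""
    return SimilarityMatrix(matrix)


def dosage_correlation_matrix(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Pearson correlation on allele-dosage coding (0, 1, 2; missing skipped
    pairwise) — an alternative similarity metric for sensitivity analysis."""
    dose = np.where(matrix.codes == MISSING, np.nan,
                    np.where(matrix.codes == HET, 1.0,
                             np.where(matrix.codes == HOM_B, 2.0, 0.0)))
    df = pd.DataFrame(dose.T, columns=matrix.sample_names)
    return df.corr(method="pearson")


def rank_by_similarity(sim: SimilarityMatrix, query: str) -> list[tuple[str, float]]:
    """All other samples ordered by descending similarity to ``query``
    (ties broken by name; incomparable pairs last)."""
    if query not in sim._index:
        raise KeyError(f"unknown sample: {query!r}")
    qi = sim._index[query]
    comp, incomp = [], []
    for j, name in enumerate(sim.names):
        if j == qi:
            continue
        s = sim.similarity[qi, j]
        if np.isnan(s):
            incomp.append((name, float("nan")))
        else:
            comp.append((name, float(s)))
    comp.sort(key=lambda t: (-t[1], t[0]))
    incomp.sort(key=lambda t: t[0])
    return comp + incomp


def find_duplicates(sim: SimilarityMatrix,
                    rule: IdentityRule | None = None) -> DuplicateGroups:
    """Identify identical germplasm and group it.

    A pair is identical iff its homozygous-mismatch fraction is strictly
    below ``rule.max_pct_hom_diffs`` with ``n_shared >= rule.min_shared``.
    Groups are connected components of the identity relation (identity is
    not transitive, so intra-group pairs violating the rule are logged).
    Identical pairs whose allele-match similarity is below
    ``rule.min_similarity`` are flagged borderline.
    """
    rule = rule or IdentityRule()
    g = nx.Graph()
    g.add_nodes_from(sim.names)
    borderline = []
    n = sim.n
    with np.errstate(invalid="ignore"):
        frac = np.where(sim.n_shared > 0,
                        sim.hom_diffs / np.maximum(sim.n_shared, 1), np.inf)
    identical = (frac < rule.max_pct_hom_diffs) & (sim.n_shared >= rule.min_shared)
    for i in range(n):
        for j in range(i + 1, n):
            if identical[i, j]:
                a, b = sim.names[i], sim.names[j]
                g.add_edge(a, b)
                if sim.similarity[i, j] < rule.min_similarity:
                    borderline.append((a, b))
    groups = [sorted(c) for c in nx.connected_components(g)]
    groups.sort(key=lambda c: c[0])
    for comp in groups:
        if len(comp) > 2:
            idx = [sim._index[x] for x in comp]
            for ii, a in enumerate(idx):
                for b in idx[ii + 1:]:
                    if not identical[a, b]:
                        logger.warning(
                            "group members %s and %s do not themselves satisfy "
                            "the identity rule (non-transitive identity)",
                            sim.names[a], sim.names[b],
                        )
    counts = {name: int(d) for name, d in g.degree()}
    return DuplicateGroups(groups, counts, borderline)


def duplicate_statistics(groups: DuplicateGroups, n_samples: int | None = None
                         ) -> dict[str, float]:
    """Fraction of samples with no duplicate partner and with more than two
    duplicate partners."""
    counts = groups.per_sample_duplicate_count
    n = n_samples if n_samples is not None else len(counts)
    if n == 0:
        raise ValueError("no samples")
    none = sum(1 for c in counts.values() if c == 0)
    more2 = sum(1 for c in counts.values() if c > 2)
    return {"fraction_no_duplicates": none / n,
            "fraction_more_than_two": more2 / n}


def genepool_consistency_check(sim: SimilarityMatrix,
                               samples: list[SampleMeta],
                               references: dict[str, list[str]]) -> list[dict]:
    """Flag samples whose declared gene pool contradicts their genotype.

    Each sample is assigned to the pool of its most similar declared
    reference sample; samples with a declared pool that disagrees with the
    assignment are flagged.  Reference samples are never flagged.
    """
    if not references or not any(references.values()):
        raise ValueError("no reference samples designated")
    ref_names = {n for pool in references.values() for n in pool}
    for n in ref_names:
        if n not in sim._index:
            raise KeyError(f"reference sample not in matrix: {n!r}")
    flagged = []
    for s in samples:
        if s.name in ref_names or s.declared_genepool in (None, "unknown"):
            continue
        qi = sim._index[s.name]
        best_pool, best_ref, best_sim = None, None, -np.inf
        for pool, names in references.items():
            for rn in names:
                v = sim.similarity[qi, sim._index[rn]]
                if not np.isnan(v) and v > best_sim:
                    best_pool, best_ref, best_sim = pool, rn, float(v)
        if best_pool is not None and best_pool != s.declared_genepool:
            flagged.append({"sample": s.name, "declared": s.declared_genepool,
                            "assigned": best_pool, "nearest_reference": best_ref,
                            "similarity": best_sim})
    return flagged
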