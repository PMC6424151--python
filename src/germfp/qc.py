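"""Sample and marker quality filters plus marker redundancy binning.

The filters mirror routine fingerprinting QC for inbred germplasm:

* samples are dropped when too much of the assay failed (high missingness)
  or when they are unexpectedly heterozygous (inbred lines should be close
  to fully homozygous; a highly heterozygous sample is usually an accidental
  hybrid or a contaminated DNA well);
* markers are dropped when their assay failure rate is too high or they were
  scored in too few samples — except whitelisted trait-diagnostic markers,
  which are kept regardless because they are only run on relevant subsets;
* redundant markers carrying the same information (same genotyping pattern,
  optionally same position) are collapsed to one representative per bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import HET, MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

#: trait-diagnostic assays kept through marker filters by default
DEFAULT_DIAGNOSTIC_WHITELIST = frozenset({"bc3", "bc-3a", "Bc-3b", "IntRegAPA3"})


@dataclass
class QCThresholds:
    max_sample_missing: float = 0.50
    max_sample_het: float = 0.10
    max_marker_missing: float = 0.20
    min_marker_sample_coverage: float = 0.50
    diagnostic_whitelist: frozenset[str] = DEFAULT_DIAGNOSTIC_WHITELIST

    def __post_init__(self):
        for name in ("max_sample_missing", "max_sample_het",
                     "max_marker_missing", "min_marker_sample_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        self.diagnostic_whitelist = frozenset(self.diagnostic_whitelist)


@dataclass
class BinParams:
    min_shared_calls: int = 30
    min_concordance: float = 0.99
    same_position_window_bp: int = 0  # 0 => bin on genotyping pattern alone

    def __post_init__(self):
        if self.min_shared_calls < 1:
            raise ValueError("min_shared_calls must be >= 1")


def filter_samples(matrix: GenotypeMatrix,
                   thresholds: QCThresholds | None = None
                   ) -> tuple[GenotypeMatrix, list[dict]]:
    """Remove samples with missing fraction >= ``max_sample_missing`` or
    heterozygous fraction (over called markers) > ``max_sample_het``.

    Returns the filtered matrix and a report listing each removal with the
    offending statistic.
    """
    thresholds = thresholds or QCThresholds()
    miss = matrix.sample_missing_fraction()
    het = matrix.sample_het_fraction()
    report = []
    keep = []
    for i, s in enumerate(matrix.samples):
        reasons = []
        if miss[i] >= thresholds.max_sample_missing:
            reasons.append(f"missing={miss[i]:.2f}")
        if het[i] > thresholds.max_sample_het:
            reasons.append(f"het={het[i]:.2f}")
        if reasons:
            report.append({"sample": s.name, "reason": "; ".join(reasons),
                           "missing": float(miss[i]), "het": float(het[i])})
        else:
            keep.append(s.name)
    if not keep:
        raise ValueError("sample filter removed every sample")
    return matrix.subset_samples(keep), report


def _marker_error_fraction(matrix: GenotypeMatrix) -> np.ndarray:
    """Per-marker missing fraction computed within the genotyping sets where
    the marker was actually assayed (>= 1 call in the set).

    In a combined multi-batch matrix a marker absent from whole batches has a
    large combined missing fraction while being perfectly reliable within its
    own batch; restricting the denominator to assayed batches separates assay
    failure from panel composition.  Falls back to the whole-matrix fraction
    when no set information is present.
    """
    sets: dict[str | None, list[int]] = {}
    for i, s in enumerate(matrix.samples):
        sets.setdefault(s.set_id, []).append(i)
    if len(sets) <= 1:
        return matrix.marker_missing_fraction()
    out = np.zeros(matrix.n_markers)
    called = matrix.codes != MISSING
    for j in range(matrix.n_markers):
        n_tot = n_miss = 0
        for idx in sets.values():
            sub = called[idx, j]
            if sub.any():  # marker assayed in this batch
                n_tot += len(idx)
                n_miss += int((~sub).sum())
        out[j] = n_miss / n_tot if n_tot else 1.0
    return out


def filter_markers(matrix: GenotypeMatrix,
                   thresholds: QCThresholds | None = None
                   ) -> tuple[GenotypeMatrix, list[dict]]:
    """Keep markers with assay failure < ``max_marker_missing`` and overall
    call coverage >= ``min_marker_sample_coverage``, plus all whitelisted
    diagnostic markers regardless of the thresholds.
    """
    thresholds = thresholds or QCThresholds()
    err = _marker_error_fraction(matrix)
    cov = matrix.marker_call_fraction()
    keep, report = [], []
    for j, m in enumerate(matrix.markers):
        whitelisted = m.id in thresholds.diagnostic_whitelist or m.diagnostic
        ok = err[j] < thresholds.max_marker_missing and \
            cov[j] >= thresholds.min_marker_sample_coverage
        report.append({"marker": m.id, "error_fraction": float(err[j]),
                       "coverage": float(cov[j]), "kept": bool(ok or whitelisted),
                       "whitelisted": bool(whitelisted)})
        if ok or whitelisted:
            keep.append(m.id)
    if not keep:
        logger.warning("marker filter removed every marker")
    return matrix.subset_markers(keep), report


def bin_markers(matrix: GenotypeMatrix, params: BinParams | None = None
                ) -> tuple[list[str], list[list[str]]]:
    """Collapse markers with redundant information content into bins.

    Greedy single-linkage grouping scanning markers in map order: a marker
    joins an existing bin if its call-pattern concordance with any member
    (fraction of identical states over samples where both are called) is
    >= ``min_concordance`` with at least ``min_shared_calls`` shared calls —
    and, when ``same_position_window_bp`` > 0, it lies within that window of
    the member's position.  One representative per bin is kept: the marker
    with the highest call rate (ties broken by lower position, then id).

    Returns ``(kept_marker_ids, bins)`` where kept ids are the bin
    representatives plus any diagnostic markers, preserving matrix order.
    """
    params = params or BinParams()
    m = matrix.sorted_by_map()
    n_mk = m.n_markers
    codes = m.codes
    called = codes != MISSING
    bins: list[list[int]] = []
    for j in range(n_mk):
        placed = False
        for b in bins:
            for k in b:
                if params.same_position_window_bp > 0:
                    mj, mk = m.markers[j], m.markers[k]
                    if (mj.chromosome != mk.chromosome
                            or mj.position_bp is None or mk.position_bp is None
                            or abs(mj.position_bp - mk.position_bp)
                            > params.same_position_window_bp):
                        continue
                both = called[:, j] & called[:, k]
                n_shared = int(both.sum())
                if n_shared < params.min_shared_calls:
                    continue
                conc = float((codes[both, j] == codes[both, k]).mean())
                if conc >= params.min_concordance:
                    b.append(j)
                    placed = True
                    break
            if placed:
                break
        if not placed:
            bins.append([j])

    def call_rate(j: int) -> float:
        return float(called[:, j].mean())

    kept_ids = set()
    bin_ids: list[list[str]] = []
    for b in bins:
        rep = min(b, key=lambda j: (-call_rate(j),
                                    m.markers[j].position_bp or 0,
                                    m.markers[j].id))
        kept_ids.add(m.markers[rep].id)
        bin_ids.append([m.markers[j].id for j in b])
    for mk in m.markers:
        if mk.diagnostic or mk.id in DEFAULT_DIAGNOSTIC_WHITELIST:
            kept_ids.add(mk.id)
    kept = [mid for mid in matrix.marker_ids if mid in kept_ids]
    return kept, bin_ids
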