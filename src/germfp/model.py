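"""Core data model for KASP-style SNP fingerprinting data.

Every genotype call is reduced to one of four states relative to the two
declared alleles of its biallelic marker:

* ``HOM_A`` — homozygous for the marker's first allele (e.g. ``A:A``),
* ``HOM_B`` — homozygous for the second allele,
* ``HET``   — heterozygous (unordered: ``A:G`` is the same call as ``G:A``),
* ``MISSING`` — failed assay, conventionally printed as ``?``.

The :class:`GenotypeMatrix` stores a samples x markers grid of these states
as a compact ``int8`` array; the raw string form can be regenerated from the
marker's allele pair on demand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

# Call-state codes.  MISSING is negative so boolean masks are cheap.
MISSING: int = -1
HOM_A: int = 0
HOM_B: int = 1
HET: int = 2

STATE_NAMES = {MISSING: "MISSING", HOM_A: "HOM_A", HOM_B: "HOM_B", HET: "HET"}

#: tokens that encode a failed/absent call without any warning
MISSING_TOKENS = frozenset({"?", "-", "", "NA", "NaN", "nan", "."})

_NUCLEOTIDES = frozenset("ACGT")
_SET_RE = re.compile(r"_set(\w+?)(?:_r\d+)?$")
_REP_RE = re.compile(r"(_r\d+)$")


def split_allele_token(token: str):
    """Split a diploid call token into its two alleles.

    Accepts ``":"``-separated (``A:G``), ``"/"``-separated (``A/G``) and
    fused two-letter (``AG``) tokens.  Returns ``None`` for a recognised
    missing token, a 2-tuple of upper-case alleles for a well-formed call,
    and the string ``"bad"`` for anything else (including ``N`` alleles).
    """
    t = token.strip()
    if t in MISSING_TOKENS:
        return None
    for sep in (":", "/"):
        if sep in t:
            parts = t.split(sep)
            if len(parts) == 2 and all(len(p.strip()) == 1 for p in parts):
                a, b = (p.strip().upper() for p in parts)
                if a in _NUCLEOTIDES and b in _NUCLEOTIDES:
                    return (a, b)
            return "bad"
    if len(t) == 2:
        a, b = t[0].upper(), t[1].upper()
        if a in _NUCLEOTIDES and b in _NUCLEOTIDES:
            return (a, b)
    return "bad"


@dataclass(frozen=True)
class MarkerDef:
    """A biallelic SNP marker with an optional physical-map location.

    ``diagnostic`` marks trait-linked assays (e.g. the bc-3 virus-resistance
    SNPs) that are exempt from coverage-based marker filters.
    """

    id: str
    chromosome: str | None = None
    position_bp: int | None = None
    allele_a: str | None = None
    allele_b: str | None = None
    diagnostic: bool = False

    def __post_init__(self):
        if self.position_bp is not None and self.position_bp < 1:
            raise ValueError(f"marker {self.id}: position_bp must be >= 1")
        if (
            self.allele_a is not None
            and self.allele_b is not None
            and self.allele_a == self.allele_b
        ):
            raise ValueError(f"marker {self.id}: alleles must differ")

    def with_alleles(self, a: str | None, b: str | None) -> "MarkerDef":
        return replace(self, allele_a=a, allele_b=b)


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one genotyped sample.

    Names follow the breeding-program convention ``<line>_set<k>[_r<j>]``
    where ``set`` identifies the genotyping batch and ``_r1``/``_r2`` mark
    replicates submitted within one batch.
    """

    name: str
    set_id: str | None = None
    replicate_suffix: str | None = None
    species: str = "P_vulgaris"
    declared_genepool: str | None = None

    @classmethod
    def from_name(cls, name: str, species: str = "P_vulgaris",
                  declared_genepool: str | None = None) -> "SampleMeta":
        set_m = _SET_RE.search(name)
        rep_m = _REP_RE.search(name)
        return cls(
            name=name,
            set_id=f"set{set_m.group(1)}" if set_m else None,
            replicate_suffix=rep_m.group(1) if rep_m else None,
            species=species,
            declared_genepool=declared_genepool,
        )


class GenotypeMatrix:
    """Samples x markers grid of 4-state genotype calls.

    Parameters
    ----------
    samples : sequence of SampleMeta
    markers : sequence of MarkerDef
    codes : ndarray of int8, shape (n_samples, n_markers)
        Call states using the module-level codes.
    """

    def __init__(self, samples: Sequence[SampleMeta], markers: Sequence[MarkerDef],
                 codes: np.ndarray):
        codes = np.asarray(codes, dtype=np.int8)
        if codes.shape != (len(samples), len(markers)):
            raise ValueError(
                f"codes shape {codes.shape} does not match "
                f"{len(samples)} samples x {len(markers)} markers"
            )
        names = [s.name for s in samples]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(
                "duplicate sample names (add explicit _r1/_r2 replicate "
                f"suffixes): {sorted(dupes)}"
            )
        ids = [m.id for m in markers]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate marker ids: {dup}")
        bad = set(np.unique(codes)) - {MISSING, HOM_A, HOM_B, HET}
        if bad:
            raise ValueError(f"invalid call codes: {sorted(bad)}")
        self.samples = list(samples)
        self.markers = list(markers)
        self.codes = codes
        self._sample_index = {n: i for i, n in enumerate(names)}
        self._marker_index = {m: i for i, m in enumerate(ids)}

    # -- basic accessors ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def sample_names(self) -> list[str]:
        return [s.name for s in self.samples]

    @property
    def marker_ids(self) -> list[str]:
        return [m.id for m in self.markers]

    def sample_index(self, name: str) -> int:
        try:
            return self._sample_index[name]
        except KeyError:
            raise KeyError(f"unknown sample: {name!r}") from None

    def marker_index(self, marker_id: str) -> int:
        try:
            return self._marker_index[marker_id]
        except KeyError:
            raise KeyError(f"unknown marker: {marker_id!r}") from None

    # -- per-sample / per-marker statistics --------------------------------

    def sample_missing_fraction(self) -> np.ndarray:
        return (self.codes == MISSING).mean(axis=1)

    def sample_het_fraction(self) -> np.ndarray:
        """Heterozygous fraction over *called* markers; 0 for empty samples."""
        called = (self.codes != MISSING).sum(axis=1)
        het = (self.codes == HET).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(called > 0, het / np.maximum(called, 1), 0.0)
        return frac

    def marker_missing_fraction(self) -> np.ndarray:
        return (self.codes == MISSING).mean(axis=0)

    def marker_call_fraction(self) -> np.ndarray:
        return (self.codes != MISSING).mean(axis=0)

    # -- subsetting --------------------------------------------------------

    def subset_samples(self, names: Iterable[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(n) for n in names]
        return GenotypeMatrix(
            [self.samples[i] for i in idx], self.markers, self.codes[idx, :]
        )

    def subset_markers(self, marker_ids: Iterable[str]) -> "GenotypeMatrix":
        idx = [self.marker_index(m) for m in marker_ids]
        return GenotypeMatrix(
            self.samples, [self.markers[i] for i in idx], self.codes[:, idx]
        )

    def sorted_by_map(self) -> "GenotypeMatrix":
        """Markers reordered by (chromosome, position); unmapped markers last,
        in their original relative order (stable)."""
        def key(i):
            m = self.markers[i]
            mapped = m.chromosome is not None and m.position_bp is not None
            return (not mapped, m.chromosome or "", m.position_bp or 0, i)
        order = sorted(range(self.n_markers), key=key)
        return GenotypeMatrix(
            self.samples, [self.markers[i] for i in order], self.codes[:, order]
        )

    # -- formatting --------------------------------------------------------

    def call_str(self, sample: str | int, marker: str | int, sep: str = ":") -> str:
        i = sample if isinstance(sample, int) else self.sample_index(sample)
        j = marker if isinstance(marker, int) else self.marker_index(marker)
        code = self.codes[i, j]
        m = self.markers[j]
        a = m.allele_a or "N"
        b = m.allele_b or "N"
        if code == MISSING:
            return "?"
        if code == HOM_A:
            return f"{a}{sep}{a}"
        if code == HOM_B:
            return f"{b}{sep}{b}"
        lo, hi = sorted((a, b))
        return f"{lo}{sep}{hi}"

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_names == other.sample_names
            and self.marker_ids == other.marker_ids
            and np.array_equal(self.codes, other.codes)
        )

    def __repr__(self) -> str:
        return f"<GenotypeMatrix {self.n_samples} samples x {self.n_markers} markers>"
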