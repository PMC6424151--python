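"""Marker-assisted selection calls from diagnostic SNPs and F1 verification.

The default panel targets the recessive *bc-3* resistance gene to Bean
Common Mosaic (Necrotic) Virus: two KASP assays (bc3, bc-3a) query the same
SNP (C227A) and Bc-3b queries a second SNP (T194A) in the same *eIF4E*
gene.  Because *bc-3* resistance is recessive, only individuals homozygous
for the resistance allele are predicted resistant; heterozygotes carry the
allele but express the susceptible phenotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .introgression import ConsensusHaplotype
from .model import HET, HOM_A, HOM_B, MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

RESISTANT = "resistant"
SUSCEPTIBLE = "susceptible"
CARRIER_HET = "carrier_het"
NO_CALL = "no_call"
CONFLICT = "conflict"


@dataclass(frozen=True)
class DiagnosticMarker:
    id: str
    gene: str
    variant_label: str
    resistance_allele: str
    susceptible_allele: str
    inheritance: str        # "recessive" or "dominant"
    trait: str

    def __post_init__(self):
        if self.resistance_allele == self.susceptible_allele:
            raise ValueError(f"{self.id}: resistance and susceptible alleles equal")
        if self.inheritance not in ("recessive", "dominant"):
            raise ValueError(f"{self.id}: inheritance must be recessive|dominant")


def default_panel() -> list[DiagnosticMarker]:
    """The shipped diagnostic panel.

    bc3/bc-3a/Bc-3b carry the published C227A / T194A allele assignments.
    IntRegAPA3 tags the arcelin (APA) bruchid-resistance locus as a dominant
    marker; its KASP allele pair is assay-specific and the defaults here are
    placeholders that must be configured for a given assay design.
    """
    return [
        DiagnosticMarker("bc3", "eIF4E", "C227A", "A", "C", "recessive",
                         "BCMV/BCMNV resistance"),
        DiagnosticMarker("bc-3a", "eIF4E", "C227A", "A", "C", "recessive",
                         "BCMV/BCMNV resistance"),
        DiagnosticMarker("Bc-3b", "eIF4E", "T194A", "A", "T", "recessive",
                         "BCMV/BCMNV resistance"),
        DiagnosticMarker("IntRegAPA3", "APA", "arcelin", "A", "G", "dominant",
                         "bruchid resistance"),
    ]


@dataclass(frozen=True)
class MASCall:
    sample: str
    marker: str
    genotype: str           # raw-style call string
    prediction: str


def _predict_one(code: int, res_is_a: bool, inheritance: str) -> str:
    if code == MISSING:
        return NO_CALL
    res_hom = HOM_A if res_is_a else HOM_B
    sus_hom = HOM_B if res_is_a else HOM_A
    if code == res_hom:
        return RESISTANT
    if code == sus_hom:
        return SUSCEPTIBLE
    # heterozygote
    return RESISTANT if inheritance == "dominant" else CARRIER_HET


def mas_predict(matrix: GenotypeMatrix, panel: list[DiagnosticMarker] | None = None
                ) -> tuple[list[MASCall], dict[tuple[str, str], str]]:
    """Predict trait phenotypes from diagnostic-marker genotypes.

    Returns per-sample-per-marker calls plus a per-(sample, gene) consensus:
    markers of the same gene must agree; disagreement (e.g. between the two
    assays of the same SNP) yields a flagged ``conflict`` consensus with a
    logged warning.  A panel marker absent from the matrix raises, listing it.
    """
    panel = panel or default_panel()
    missing = [p.id for p in panel if p.id not in matrix.marker_ids]
    if missing:
        raise KeyError(f"panel markers absent from matrix: {missing}")
    calls: list[MASCall] = []
    per_gene: dict[tuple[str, str], list[str]] = {}
    for p in panel:
        j = matrix.marker_index(p.id)
        m = matrix.markers[j]
        # orient HOM_A/HOM_B to the panel's alleles; the marker may be
        # monomorphic in this dataset, so either allele alone is enough
        if m.allele_a == p.resistance_allele or m.allele_b == p.susceptible_allele:
            res_is_a = True
        elif m.allele_a == p.susceptible_allele or m.allele_b == p.resistance_allele:
            res_is_a = False
        elif m.allele_a is None and m.allele_b is None:
            res_is_a = True  # no observed calls at all; predictions are NO_CALL
        else:
            declared = sorted({m.allele_a, m.allele_b} - {None})
            raise ValueError(
                f"marker {p.id}: panel alleles {p.resistance_allele}/"
                f"{p.susceptible_allele} do not match observed alleles {declared}"
            )
        for i, s in enumerate(matrix.samples):
            pred = _predict_one(int(matrix.codes[i, j]), res_is_a, p.inheritance)
            calls.append(MASCall(s.name, p.id, matrix.call_str(i, j), pred))
            per_gene.setdefault((s.name, p.gene), []).append(pred)
    consensus: dict[tuple[str, str], str] = {}
    for key, preds in per_gene.items():
        informative = [p for p in preds if p != NO_CALL]
        if not informative:
            consensus[key] = NO_CALL
        elif len(set(informative)) == 1:
            consensus[key] = informative[0]
        else:
            logger.warning("conflicting diagnostic calls for sample %s, gene %s: %s",
                           key[0], key[1], informative)
            consensus[key] = CONFLICT
    return calls, consensus


def f1_verify(matrix: GenotypeMatrix, putative_f1: str,
              parent1: ConsensusHaplotype, parent2: ConsensusHaplotype,
              min_het_fraction: float = 0.9) -> str:
    """Classify a putative F1 as ``hybrid``, ``self`` or ``ambiguous``.

    A true hybrid of two inbred parents is heterozygous at every marker that
    is homozygous-polymorphic between them; a selfed seed matches the mother
    instead.  The verdict uses the het fraction over parent-polymorphic
    markers scored in the putative F1: >= ``min_het_fraction`` -> hybrid,
    <= 1 - ``min_het_fraction`` -> self, in between -> ambiguous.  Fewer
    than 10 scored polymorphic markers raise (insufficient markers).
    """
    if parent1.marker_ids != parent2.marker_ids:
        raise ValueError("parental consensuses were built on different marker sets")
    # polymorphism needs no map position here, only homozygous disagreement
    polymorphic = [
        mid for k, mid in enumerate(parent1.marker_ids)
        if mid not in parent1.dropped and mid not in parent2.dropped
        and int(parent1.codes[k]) in (HOM_A, HOM_B)
        and int(parent2.codes[k]) in (HOM_A, HOM_B)
        and parent1.codes[k] != parent2.codes[k]
    ]
    oi = matrix.sample_index(putative_f1)
    scored = [mid for mid in polymorphic
              if matrix.codes[oi, matrix.marker_index(mid)] != MISSING]
    if len(scored) < 10:
        raise ValueError(
            f"only {len(scored)} scored polymorphic markers for {putative_f1}; "
            "need >= 10 for F1 verification"
        )
    het = sum(1 for mid in scored
              if matrix.codes[oi, matrix.marker_index(mid)] == HET)
    frac = het / len(scored)
    if frac >= min_het_fraction:
        return "hybrid"
    if frac <= 1.0 - min_het_fraction:
        return "self"
    return "ambiguous"
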