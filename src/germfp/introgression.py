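"""Parental consensus haplotypes, offspring chromosome painting,
recombination counting, donor-fraction quantification and residual
heterozygosity detection.

The workflow mirrors introgression tracking in a backcross program:

1. reconcile replicate samples of each parent into a consensus haplotype,
2. keep only markers homozygous-polymorphic between the two consensuses
   (optionally also donor-missing "dominant" presence/absence markers, which
   matter for wide crosses where the donor's assays fail),
3. paint each offspring marker by parental origin (P1 / P2 / HET),
4. summarise: recombination counts per chromosome, donor-genome fractions
   and heterozygous blocks (residual heterozygosity vs isolated call errors).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import HET, HOM_A, HOM_B, MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

# painted-state codes
P1: int = 0
P2: int = 1
HET_STATE: int = 2
MISSING_STATE: int = -1
UNEXPECTED: int = 3

PAINT_NAMES = {P1: "P1", P2: "P2", HET_STATE: "HET",
               MISSING_STATE: "MISSING", UNEXPECTED: "UNEXPECTED"}


@dataclass
class ConsensusHaplotype:
    """Parental genotype vector reconciled from two replicate samples.

    Reconciliation rules per marker:
    1. one replicate missing -> take the other call;
    2. one heterozygous, one homozygous -> take the homozygous call;
    3. conflicting homozygous calls, or both missing -> drop the marker.
    Equal calls (including both-het) are kept as-is.
    """

    label: str
    marker_ids: list[str]
    codes: np.ndarray                    # int8 per marker; MISSING where dropped
    dropped: dict[str, str] = field(default_factory=dict)  # id -> reason

    def code_of(self, marker_id: str) -> int:
        return int(self.codes[self.marker_ids.index(marker_id)])


@dataclass
class PaintedGenome:
    """Per-marker parental-origin states of one offspring over the
    polymorphic marker set, ordered by (chromosome, position)."""

    offspring: str
    marker_ids: list[str]
    chromosomes: list[str]
    positions: np.ndarray               # int64 bp
    states: np.ndarray                  # int8 painted-state codes
    dominant: np.ndarray                # bool; donor-missing presence/absence markers

    def chromosome_order(self) -> list[str]:
        seen: list[str] = []
        for c in self.chromosomes:
            if c not in seen:
                seen.append(c)
        return seen


@dataclass
class IntrogressionSummary:
    offspring: str
    donor_fraction_dosage: float        # (2*donor_hom + het) / (2*scored)
    donor_fraction_simple: float        # donor_hom / scored
    n_scored: int
    recombinations_per_chromosome: dict[str, int]
    het_blocks: list[tuple[str, int, int, int]]  # (chrom, start_bp, end_bp, n_markers)


def consensus_call(code_a: int, code_b: int) -> tuple[int, str | None]:
    """Reconcile one ordered pair of call states.

    Returns ``(code, drop_reason)`` where ``drop_reason`` is None for a kept
    call; dropped markers report ``code == MISSING``.
    """
    if code_a == code_b:
        if code_a == MISSING:
            return MISSING, "both missing"
        return code_a, None
    if code_a == MISSING:
        return code_b, None
    if code_b == MISSING:
        return code_a, None
    if code_a == HET:
        return code_b, None            # hom wins over het
    if code_b == HET:
        return code_a, None
    return MISSING, "conflicting homozygotes"


def build_consensus(matrix: GenotypeMatrix, replicate_a: str, replicate_b: str,
                    label: str) -> ConsensusHaplotype:
    """Build a parental consensus haplotype from two replicate samples."""
    ia = matrix.sample_index(replicate_a)
    ib = matrix.sample_index(replicate_b)
    codes = np.full(matrix.n_markers, MISSING, dtype=np.int8)
    dropped: dict[str, str] = {}
    for j, m in enumerate(matrix.markers):
        c, reason = consensus_call(int(matrix.codes[ia, j]), int(matrix.codes[ib, j]))
        codes[j] = c
        if reason is not None:
            dropped[m.id] = reason
    return ConsensusHaplotype(label, matrix.marker_ids, codes, dropped)


def select_polymorphic(parent1: ConsensusHaplotype, parent2: ConsensusHaplotype,
                       markers, allow_missing_donor: bool = False
                       ) -> tuple[list[str], set[str]]:
    """Markers informative for painting offspring of parent1 x parent2.

    A marker is kept iff both parents are homozygous for different alleles.
    With ``allow_missing_donor``, markers where the donor (parent2) assay
    failed while parent1 is homozygous are also kept as dominant
    presence/absence markers.  Markers dropped by either consensus are
    excluded, as are markers without a map position.  The returned ids are
    ordered by (chromosome, position).

    Returns ``(ordered_marker_ids, dominant_marker_ids)``.
    """
    if parent1.marker_ids != parent2.marker_ids:
        raise ValueError("parental consensuses were built on different marker sets")
    by_id = {m.id: m for m in markers}
    kept: list[str] = []
    dominant: set[str] = set()
    for idx, mid in enumerate(parent1.marker_ids):
        if mid in parent1.dropped:
            continue
        # a donor consensus with both replicates missing is normally dropped,
        # but in donor-missing mode that assay-failure signature is exactly
        # what makes the marker a usable dominant presence/absence marker
        donor_dropped = parent2.dropped.get(mid)
        if donor_dropped is not None and not (
            allow_missing_donor and donor_dropped == "both missing"
        ):
            continue
        m = by_id.get(mid)
        if m is None or m.chromosome is None or m.position_bp is None:
            continue
        c1 = int(parent1.codes[idx])
        c2 = int(parent2.codes[idx])
        if c1 in (HOM_A, HOM_B) and c2 in (HOM_A, HOM_B) and c1 != c2:
            kept.append(mid)
        elif allow_missing_donor and c2 == MISSING and c1 in (HOM_A, HOM_B):
            kept.append(mid)
            dominant.add(mid)
    if not kept:
        logger.warning("no polymorphic markers between %s and %s",
                       parent1.label, parent2.label)
    kept.sort(key=lambda mid: (by_id[mid].chromosome, by_id[mid].position_bp))
    return kept, dominant


def paint_offspring(matrix: GenotypeMatrix, offspring: str,
                    parent1: ConsensusHaplotype, parent2: ConsensusHaplotype,
                    polymorphic: list[str], dominant: set[str] = frozenset(),
                    dominant_missing_as_donor: bool = True) -> PaintedGenome:
    """Assign each polymorphic marker of an offspring to a parental origin.

    At a regular (codominant) marker the offspring call equal to parent1's
    homozygote paints P1, equal to parent2's paints P2, the heterozygote of
    the two parental alleles paints HET, a failed call paints MISSING and
    anything else UNEXPECTED.  At a dominant marker (donor assay failed) a
    failed offspring call is painted P2 when ``dominant_missing_as_donor``
    (the shared assay-failure signature is evidence of the donor segment),
    otherwise MISSING.
    """
    oi = matrix.sample_index(offspring)
    p1_idx = {mid: k for k, mid in enumerate(parent1.marker_ids)}
    by_id = {m.id: m for m in matrix.markers}
    states = np.full(len(polymorphic), MISSING_STATE, dtype=np.int8)
    dom = np.zeros(len(polymorphic), dtype=bool)
    chroms, positions = [], []
    for k, mid in enumerate(polymorphic):
        m = by_id[mid]
        chroms.append(m.chromosome)
        positions.append(m.position_bp)
        off = int(matrix.codes[oi, matrix.marker_index(mid)])
        c1 = int(parent1.codes[p1_idx[mid]])
        c2 = int(parent2.codes[p1_idx[mid]])
        if mid in dominant:
            dom[k] = True
            if off == c1:
                states[k] = P1
            elif off == MISSING:
                states[k] = P2 if dominant_missing_as_donor else MISSING_STATE
            else:
                states[k] = UNEXPECTED
        else:
            if off == c1:
                states[k] = P1
            elif off == c2:
                states[k] = P2
            elif off == HET:
                states[k] = HET_STATE
            elif off == MISSING:
                states[k] = MISSING_STATE
            else:
                states[k] = UNEXPECTED
    return PaintedGenome(offspring, list(polymorphic), chroms,
                         np.asarray(positions, dtype=np.int64), states, dom)


def count_recombinations(painted: PaintedGenome) -> dict[str, int]:
    """Recombination events per chromosome: transitions between consecutive
    informative states (MISSING and UNEXPECTED are skipped).  A P1->HET->P2
    run counts two events (one per homolog)."""
    out: dict[str, int] = {}
    chrom_arr = np.asarray(painted.chromosomes)
    for chrom in painted.chromosome_order():
        s = painted.states[chrom_arr == chrom]
        s = s[(s != MISSING_STATE) & (s != UNEXPECTED)]
        out[chrom] = int((s[1:] != s[:-1]).sum()) if s.size > 1 else 0
    return out


def detect_het_blocks(painted: PaintedGenome, min_block: int = 3
                      ) -> tuple[list[tuple[str, int, int, int]],
                                 list[tuple[str, int]]]:
    """Find residual-heterozygosity blocks.

    A block is a maximal run of >= ``min_block`` HET markers on one
    chromosome; failed calls inside a run are ignored (they neither extend
    nor break it).  Shorter HET runs are returned separately as probable
    genotyping errors, as ``(chromosome, position)`` of each isolated het.
    """
    if min_block < 2:
        raise ValueError("min_block must be >= 2")
    blocks: list[tuple[str, int, int, int]] = []
    isolated: list[tuple[str, int]] = []
    chrom_arr = np.asarray(painted.chromosomes)
    for chrom in painted.chromosome_order():
        sel = chrom_arr == chrom
        states = painted.states[sel]
        pos = painted.positions[sel]
        run: list[int] = []  # indices of het markers in current run
        def flush():
            if not run:
                return
            if len(run) >= min_block:
                blocks.append((chrom, int(pos[run[0]]), int(pos[run[-1]]), len(run)))
            else:
                isolated.extend((chrom, int(pos[k])) for k in run)
            run.clear()
        for k, st in enumerate(states):
            if st == HET_STATE:
                run.append(k)
            elif st == MISSING_STATE:
                continue
            else:
                flush()
        flush()
    return blocks, isolated


def introgression_fraction(painted: PaintedGenome, donor: str = "P2",
                           min_het_block: int = 3) -> IntrogressionSummary:
    """Quantify the donor-genome share of a painted offspring.

    ``donor_fraction_dosage`` weights heterozygous markers as half a donor
    dose: (2 * donor_hom + het) / (2 * scored); ``donor_fraction_simple`` is
    the plain homozygous-donor fraction.  Scored markers are those painted
    P1, P2 or HET.
    """
    donor_code = {"P1": P1, "P2": P2}[donor]
    s = painted.states
    scored = (s == P1) | (s == P2) | (s == HET_STATE)
    n_scored = int(scored.sum())
    if n_scored == 0:
        raise ValueError(f"no scored markers for offspring {painted.offspring}")
    donor_hom = int((s == donor_code).sum())
    het = int((s == HET_STATE).sum())
    blocks, _ = detect_het_blocks(painted, min_block=min_het_block)
    return IntrogressionSummary(
        offspring=painted.offspring,
        donor_fraction_dosage=(2 * donor_hom + het) / (2 * n_scored),
        donor_fraction_simple=donor_hom / n_scored,
        n_scored=n_scored,
        recombinations_per_chromosome=count_recombinations(painted),
        het_blocks=blocks,
    )


DEFAULT_PAINT_COLORS = {
    P1: "#2166ac",        # recurrent parent: blue
    P2: "#ffd92f",        # donor parent: yellow
    HET_STATE: "#66c2a5",
    MISSING_STATE: "#d9d9d9",
    UNEXPECTED: "#e41a1c",
}


def plot_painting(painted_genomes: list[PaintedGenome], path,
                  chromosomes: list[str] | None = None,
                  colors: dict[int, str] | None = None,
                  chromosome_length_bp: int | None = None):
    """Draw per-chromosome painted bars, one track per offspring.

    Each chromosome gets a panel with a bp axis; markers are drawn as
    segments spanning the midpoints to their neighbours, coloured by painted
    state (donor yellow, recurrent blue by default).  Chromosomes with no
    polymorphic markers get a panel labelled "no markers".
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not painted_genomes:
        raise ValueError("nothing to plot")
    colors = {**DEFAULT_PAINT_COLORS, **(colors or {})}
    if chromosomes is None:
        chromosomes = []
        for p in painted_genomes:
            for c in p.chromosome_order():
                if c not in chromosomes:
                    chromosomes.append(c)
        chromosomes.sort()
    n_panels = len(chromosomes)
    fig, axes = plt.subplots(n_panels, 1, figsize=(10, 1 + 0.6 * n_panels
                                                   * max(1, len(painted_genomes))),
                             squeeze=False)
    for ax_row, chrom in zip(axes[:, 0], chromosomes):
        any_markers = False
        for t, p in enumerate(painted_genomes):
            sel = np.asarray(p.chromosomes) == chrom
            pos = p.positions[sel]
            states = p.states[sel]
            if pos.size == 0:
                continue
            any_markers = True
            edges = np.empty(pos.size + 1, dtype=float)
            edges[1:-1] = (pos[:-1] + pos[1:]) / 2.0
            edges[0] = pos[0] - (edges[1] - pos[0] if pos.size > 1 else 1.0)
            edges[-1] = pos[-1] + (pos[-1] - edges[-2] if pos.size > 1 else 1.0)
            for k in range(pos.size):
                ax_row.barh(t, edges[k + 1] - edges[k], left=edges[k], height=0.8,
                            color=colors[int(states[k])], edgecolor="none")
        if not any_markers:
            ax_row.text(0.5, 0.5, "no markers", ha="center", va="center",
                        transform=ax_row.transAxes)
        ax_row.set_ylabel(chrom, rotation=0, ha="right", va="center")
        ax_row.set_yticks(range(len(painted_genomes)))
        ax_row.set_yticklabels([p.offspring for p in painted_genomes], fontsize=7)
        if chromosome_length_bp:
            ax_row.set_xlim(0, chromosome_length_bp)
    axes[-1, 0].set_xlabel("position (bp)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
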