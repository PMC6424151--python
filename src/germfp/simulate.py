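"""Synthetic multi-origin breeding-program genotype datasets with truth tables.

The generator emulates the statistical structure a germplasm-fingerprinting
pipeline has to cope with:

* two diverged gene pools (Andean / Mesoamerican) of inbred founder lines,
  fully homozygous apart from optional residual-heterozygosity blocks;
* planted duplicate groups (the same line re-entered under related names,
  with independent call errors and assay failures per copy);
* mislabelled samples (an Andean name carrying a Mesoamerican genotype —
  the seed mix-up signature);
* sister-species samples whose KASP assays fail at elevated rates because
  the assay primers were designed within the focal species;
* biparental crosses (F1 / F2 / BC1 / RIL) with per-chromosome crossover
  counts drawn from a Poisson distribution, so painted-genome, recombination
  and donor-fraction analyses can be checked against known truth.

All randomness flows from one ``numpy`` Generator seeded by
``SimConfig.seed``; a fixed seed fixes the whole bundle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .io import write_genotype_table, write_marker_map, write_vcf
from .model import HET, HOM_A, HOM_B, MISSING, GenotypeMatrix, MarkerDef, SampleMeta

logger = logging.getLogger(__name__)

_NUC = "ACGT"


@dataclass
class DuplicateSpec:
    group_size: int = 2
    call_error_rate: float = 0.002


@dataclass
class CrossDesign:
    kind: str                      # F1 | F2 | BC1 | RIL
    parent1: str                   # recurrent parent for BC1
    parent2: str                   # donor parent
    n_offspring: int
    crossover_mean: float = 1.5    # Poisson mean per chromosome per meiosis
    name_prefix: str | None = None
    selfing_generations: int = 6   # RIL only
    call_error_rate: float = 0.0
    missing_rate: float = 0.0


@dataclass
class SimConfig:
    n_chromosomes: int = 11
    markers_per_chromosome: int = 69       # 11 x 69 = 759, a panel-sized map
    chromosome_length_bp: int = 50_000_000
    # per-marker allele-a frequency in pool A ~ U(low, high); pool B mirrors it
    pool_freq_low: float = 0.05
    pool_freq_high: float = 0.30
    n_lines_per_pool: int = 50
    duplicate_groups: list[DuplicateSpec] = field(
        default_factory=lambda: [DuplicateSpec(2, 0.002) for _ in range(5)])
    mislabel_count: int = 2
    residual_het_rate: float = 0.10        # fraction of lines with one het block
    het_block_markers: tuple[int, int] = (5, 15)
    missing_rate_normal: float = 0.02
    missing_rate_sister_species: tuple[float, float] = (0.23, 0.41)
    n_sister_species: int = 2
    sister_divergence: float = 0.15        # fraction of markers privately shifted
    crosses: list[CrossDesign] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        rates = [self.pool_freq_low, self.pool_freq_high, self.residual_het_rate,
                 self.missing_rate_normal, self.sister_divergence,
                 *self.missing_rate_sister_species]
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("all rates must be in [0, 1]")
        if self.pool_freq_low > self.pool_freq_high:
            raise ValueError("pool_freq_low > pool_freq_high")
        if self.n_chromosomes < 1 or self.markers_per_chromosome < 1:
            raise ValueError("need >= 1 chromosome and >= 1 marker per chromosome")
        if self.n_lines_per_pool < 1:
            raise ValueError("need >= 1 line per pool")


@dataclass
class SyntheticTruth:
    """Ground truth for every planted structure, aligned to the emitted matrix."""

    marker_ids: list[str] = field(default_factory=list)
    duplicate_groups: list[list[str]] = field(default_factory=list)
    mislabels: dict[str, str] = field(default_factory=dict)
    # offspring -> chromosome -> breakpoint positions of the diploid origin
    # mosaic (midpoints between the flanking markers where the state changes)
    crossovers: dict[str, dict[str, list[int]]] = field(default_factory=dict)
    # offspring -> per-marker true origin state (0=P1, 1=P2, 2=het)
    origin_states: dict[str, list[int]] = field(default_factory=dict)
    donor_segments: dict[str, list[list]] = field(default_factory=dict)
    het_blocks: dict[str, list[list]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


def validate_truth(truth_dict: dict) -> None:
    """Structural validation of a truth JSON document (see
    docs/truth_schema.json for the schema it enforces)."""
    required = {"marker_ids": list, "duplicate_groups": list, "mislabels": dict,
                "crossovers": dict, "origin_states": dict,
                "donor_segments": dict, "het_blocks": dict}
    for key, typ in required.items():
        if key not in truth_dict:
            raise ValueError(f"truth document missing key: {key}")
        if not isinstance(truth_dict[key], typ):
            raise ValueError(f"truth key {key} must be {typ.__name__}")
    for g in truth_dict["duplicate_groups"]:
        if not (isinstance(g, list) and all(isinstance(x, str) for x in g)):
            raise ValueError("duplicate_groups must be lists of sample names")
    for name, per_chrom in truth_dict["crossovers"].items():
        if not isinstance(per_chrom, dict):
            raise ValueError(f"crossovers[{name}] must map chromosome -> positions")
        for pos_list in per_chrom.values():
            if not all(isinstance(p, int) for p in pos_list):
                raise ValueError("crossover positions must be integers")
    n_mk = len(truth_dict["marker_ids"])
    for name, states in truth_dict["origin_states"].items():
        if len(states) != n_mk:
            raise ValueError(f"origin_states[{name}] length != number of markers")
        if not set(states) <= {0, 1, 2}:
            raise ValueError(f"origin_states[{name}] has invalid codes")


# ---------------------------------------------------------------------------
# founders
# ---------------------------------------------------------------------------

def _make_markers(config: SimConfig, rng: np.random.Generator) -> list[MarkerDef]:
    markers = []
    for c in range(config.n_chromosomes):
        chrom = f"Pv{c + 1:02d}"
        pos: np.ndarray = np.array([], dtype=np.int64)
        while pos.size < config.markers_per_chromosome:
            extra = rng.integers(1, config.chromosome_length_bp + 1,
                                 size=2 * config.markers_per_chromosome)
            pos = np.unique(np.concatenate([pos, extra]))
        pos = np.sort(rng.choice(pos, size=config.markers_per_chromosome,
                                 replace=False))
        for p in pos:
            i, j = rng.choice(4, size=2, replace=False)
            a, b = sorted((_NUC[i], _NUC[j]))
            markers.append(MarkerDef(f"{chrom}_{int(p)}", chromosome=chrom,
                                     position_bp=int(p), allele_a=a, allele_b=b))
    return markers


def simulate_founders(config: SimConfig,
                      rng: np.random.Generator | None = None
                      ) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Simulate the inbred founder panel of both gene pools plus sister-species
    samples; returns the matrix and a truth table with the planted het blocks."""
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    markers = _make_markers(config, rng)
    m = len(markers)
    chrom_of = np.array([mk.chromosome for mk in markers])
    freq_a_poolA = rng.uniform(config.pool_freq_low, config.pool_freq_high, size=m)
    freq_a_poolB = 1.0 - freq_a_poolA

    samples: list[SampleMeta] = []
    rows: list[np.ndarray] = []
    truth = SyntheticTruth(marker_ids=[mk.id for mk in markers])

    def add_line(name, pool_freq, genepool, species="P_vulgaris"):
        codes = np.where(rng.random(m) < pool_freq, HOM_A, HOM_B).astype(np.int8)
        meta = SampleMeta(name=name, set_id="set1", species=species,
                          declared_genepool=genepool)
        samples.append(meta)
        rows.append(codes)
        return codes

    for i in range(config.n_lines_per_pool):
        add_line(f"AND{i:03d}", freq_a_poolA, "Andean")
    for i in range(config.n_lines_per_pool):
        add_line(f"MES{i:03d}", freq_a_poolB, "Mesoamerican")

    # residual heterozygosity: some lines keep one still-segregating block
    for i, meta in enumerate(samples):
        if rng.random() < config.residual_het_rate:
            chrom = f"Pv{int(rng.integers(config.n_chromosomes)) + 1:02d}"
            in_chrom = np.flatnonzero(chrom_of == chrom)
            lo, hi = config.het_block_markers
            nb = min(int(rng.integers(lo, hi + 1)), in_chrom.size)
            start = int(rng.integers(0, in_chrom.size - nb + 1))
            block = in_chrom[start:start + nb]
            rows[i][block] = HET
            truth.het_blocks[meta.name] = [[
                chrom, int(markers[block[0]].position_bp),
                int(markers[block[-1]].position_bp)]]

    # sister-species samples: elevated assay failure plus private divergence
    sister_species = ["P_acutifolius", "P_coccineus"]
    for k in range(config.n_sister_species):
        sp = sister_species[k % 2]
        name = f"{'PACU' if sp == 'P_acutifolius' else 'PCOC'}{k:02d}"
        codes = add_line(name, freq_a_poolB, None, species=sp)
        shift = rng.random(m) < config.sister_divergence
        codes[shift] = np.where(codes[shift] == HOM_A, HOM_B, HOM_A)
        lo, hi = config.missing_rate_sister_species
        miss_rate = rng.uniform(lo, hi)
        codes[rng.random(m) < miss_rate] = MISSING

    # routine assay failure for the P. vulgaris founders
    for i, meta in enumerate(samples):
        if meta.species == "P_vulgaris":
            rows[i][rng.random(m) < config.missing_rate_normal] = MISSING

    matrix = GenotypeMatrix(samples, markers, np.vstack(rows))
    return matrix, truth


# ---------------------------------------------------------------------------
# duplicates and mislabels
# ---------------------------------------------------------------------------

def _inject_errors(codes: np.ndarray, error_rate: float, missing_rate: float,
                   rng: np.random.Generator) -> np.ndarray:
    out = codes.copy()
    if error_rate > 0:
        called = np.flatnonzero(out != MISSING)
        hit = called[rng.random(called.size) < error_rate]
        for j in hit:
            choices = [s for s in (HOM_A, HOM_B, HET) if s != out[j]]
            out[j] = choices[int(rng.integers(len(choices)))]
    if missing_rate > 0:
        out[rng.random(out.size) < missing_rate] = MISSING
    return out


def plant_duplicates_and_mislabels(matrix: GenotypeMatrix, truth: SyntheticTruth,
                                   config: SimConfig,
                                   rng: np.random.Generator
                                   ) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Append duplicate copies (independent call errors and assay failures)
    and mislabelled samples (another pool's genotype under a conflicting
    name); the truth table records the planted partition and identities."""
    pool_lines = [s.name for s in matrix.samples
                  if s.declared_genepool in ("Andean", "Mesoamerican")]
    n_sources = len(config.duplicate_groups) + config.mislabel_count
    if any(spec.group_size < 2 for spec in config.duplicate_groups):
        raise ValueError("duplicate group size must be >= 2")
    if n_sources > len(pool_lines):
        raise ValueError(
            f"{n_sources} duplicate/mislabel sources requested but only "
            f"{len(pool_lines)} founder lines available"
        )
    sources = list(rng.choice(pool_lines, size=n_sources, replace=False))
    samples = list(matrix.samples)
    rows = [matrix.codes]
    k = 0
    for spec, src in zip(config.duplicate_groups, sources):
        si = matrix.sample_index(src)
        group = [src]
        for copy_no in range(2, spec.group_size + 1):
            name = f"{src}_set{copy_no}"
            codes = _inject_errors(matrix.codes[si], spec.call_error_rate,
                                   config.missing_rate_normal, rng)
            samples.append(SampleMeta(
                name=name, set_id=f"set{copy_no}",
                declared_genepool=matrix.samples[si].declared_genepool))
            rows.append(codes[None, :])
            group.append(name)
        truth.duplicate_groups.append(group)
        k += 1
    andean = [s for s in sources[k:] if s.startswith("AND")]
    # ensure enough Andean names to mislabel; top up deterministically
    extra = [s.name for s in matrix.samples
             if s.declared_genepool == "Andean" and s.name not in sources]
    while len(andean) < config.mislabel_count and extra:
        andean.append(extra.pop(0))
    # keep mislabel identities disjoint from duplicate-group sources (and
    # from each other) so each planted structure stays its own component
    meso = [s.name for s in matrix.samples
            if s.declared_genepool == "Mesoamerican" and s.name not in sources]
    if config.mislabel_count > len(meso):
        raise ValueError("not enough Mesoamerican lines to source mislabels")
    true_lines = list(rng.choice(meso, size=config.mislabel_count, replace=False))
    for j in range(config.mislabel_count):
        label_line = andean[j]
        true_line = true_lines[j]
        name = f"{label_line}_set9"
        codes = _inject_errors(matrix.codes[matrix.sample_index(true_line)],
                               0.0, config.missing_rate_normal, rng)
        samples.append(SampleMeta(name=name, set_id="set9",
                                  declared_genepool="Andean"))
        rows.append(codes[None, :])
        truth.mislabels[name] = true_line
    out = GenotypeMatrix(samples, matrix.markers, np.vstack(rows))
    return out, truth


# ---------------------------------------------------------------------------
# crosses
# ---------------------------------------------------------------------------

class _Individual:
    """Two haplotypes tracked as allele codes (0/1, -1 unknown) and origin
    labels (0 = derived from parent1, 1 = from parent2)."""

    __slots__ = ("alleles", "origins")

    def __init__(self, alleles: np.ndarray, origins: np.ndarray):
        self.alleles = alleles      # (2, m) int8
        self.origins = origins      # (2, m) int8


def _founder_individual(matrix: GenotypeMatrix, name: str, origin_label: int
                        ) -> _Individual:
    codes = matrix.codes[matrix.sample_index(name)]
    a1 = np.where(codes == HOM_B, 1, np.where(codes == MISSING, -1, 0))
    a2 = np.where(codes == HOM_A, 0, np.where(codes == MISSING, -1, 1))
    alleles = np.stack([a1, a2]).astype(np.int8)
    origins = np.full_like(alleles, origin_label)
    return _Individual(alleles, origins)


def _meiosis(ind: _Individual, chrom_idx: np.ndarray, positions: np.ndarray,
             n_chrom: int, length_bp: int, crossover_mean: float,
             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    hap = np.empty(positions.size, dtype=np.int8)
    for c in range(n_chrom):
        sel = chrom_idx == c
        k = int(rng.poisson(crossover_mean))
        xpos = np.sort(rng.integers(1, length_bp, size=k))
        start = int(rng.integers(2))
        hap[sel] = (start + np.searchsorted(xpos, positions[sel])) % 2
    cols = np.arange(positions.size)
    return ind.alleles[hap, cols].copy(), ind.origins[hap, cols].copy()


def _offspring_of(mother: _Individual, father: _Individual, chrom_idx, positions,
                  n_chrom, length_bp, crossover_mean, rng) -> _Individual:
    a1, o1 = _meiosis(mother, chrom_idx, positions, n_chrom, length_bp,
                      crossover_mean, rng)
    a2, o2 = _meiosis(father, chrom_idx, positions, n_chrom, length_bp,
                      crossover_mean, rng)
    return _Individual(np.stack([a1, a2]), np.stack([o1, o2]))


def _genotype_codes(ind: _Individual) -> np.ndarray:
    a1, a2 = ind.alleles
    codes = np.where((a1 == -1) | (a2 == -1), MISSING,
                     np.where(a1 == a2,
                              np.where(a1 == 0, HOM_A, HOM_B), HET))
    return codes.astype(np.int8)


def _origin_states(ind: _Individual) -> np.ndarray:
    o1, o2 = ind.origins
    return np.where(o1 == o2, o1, 2).astype(np.int8)


def _mosaic_breakpoints(states: np.ndarray, chrom_names: np.ndarray,
                        positions: np.ndarray) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for chrom in dict.fromkeys(chrom_names):
        sel = chrom_names == chrom
        s = states[sel]
        p = positions[sel]
        change = np.flatnonzero(s[1:] != s[:-1])
        out[str(chrom)] = [int((p[i] + p[i + 1]) // 2) for i in change]
    return out


def _donor_segments(states: np.ndarray, chrom_names: np.ndarray,
                    positions: np.ndarray) -> list[list]:
    """Maximal runs of markers carrying donor material (origin state 1 or 2)."""
    segs: list[list] = []
    for chrom in dict.fromkeys(chrom_names):
        sel = chrom_names == chrom
        s = states[sel]
        p = positions[sel]
        carrying = s != 0
        start = None
        for k in range(s.size + 1):
            if k < s.size and carrying[k]:
                if start is None:
                    start = k
            elif start is not None:
                segs.append([str(chrom), int(p[start]), int(p[k - 1])])
                start = None
    return segs


def simulate_cross(matrix: GenotypeMatrix, truth: SyntheticTruth,
                   design: CrossDesign, config: SimConfig,
                   rng: np.random.Generator
                   ) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Append offspring of a biparental cross and record full truth.

    F1: one gamete from each parent.  F2: self of a shared F1.  BC1: F1
    gamete x recurrent-parent (parent1) gamete.  RIL: recurrent selfing from
    the F1 for ``selfing_generations`` generations.
    """
    if design.kind not in ("F1", "F2", "BC1", "RIL"):
        raise ValueError(f"unknown cross design: {design.kind!r}")
    chrom_names = np.array([mk.chromosome for mk in matrix.markers])
    chrom_labels = list(dict.fromkeys(chrom_names))
    chrom_idx = np.array([chrom_labels.index(c) for c in chrom_names])
    positions = np.array([mk.position_bp for mk in matrix.markers], dtype=np.int64)
    n_chrom = len(chrom_labels)
    L = config.chromosome_length_bp
    xmean = design.crossover_mean

    p1 = _founder_individual(matrix, design.parent1, 0)
    p2 = _founder_individual(matrix, design.parent2, 1)
    prefix = design.name_prefix or design.kind
    shared_f1 = _offspring_of(p1, p2, chrom_idx, positions, n_chrom, L, xmean, rng)

    samples = list(matrix.samples)
    rows = [matrix.codes]
    for i in range(design.n_offspring):
        if design.kind == "F1":
            ind = _offspring_of(p1, p2, chrom_idx, positions, n_chrom, L, xmean, rng)
        elif design.kind == "F2":
            ind = _offspring_of(shared_f1, shared_f1, chrom_idx, positions,
                                n_chrom, L, xmean, rng)
        elif design.kind == "BC1":
            ind = _offspring_of(shared_f1, p1, chrom_idx, positions,
                                n_chrom, L, xmean, rng)
        else:  # RIL
            ind = _offspring_of(shared_f1, shared_f1, chrom_idx, positions,
                                n_chrom, L, xmean, rng)
            for _ in range(design.selfing_generations - 1):
                ind = _offspring_of(ind, ind, chrom_idx, positions,
                                    n_chrom, L, xmean, rng)
        name = f"{prefix}{i + 1:03d}"
        codes = _genotype_codes(ind)
        codes = _inject_errors(codes, design.call_error_rate,
                               design.missing_rate, rng)
        samples.append(SampleMeta(name=name))
        rows.append(codes[None, :])
        states = _origin_states(ind)
        truth.origin_states[name] = [int(s) for s in states]
        truth.crossovers[name] = _mosaic_breakpoints(states, chrom_names, positions)
        truth.donor_segments[name] = _donor_segments(states, chrom_names, positions)
    out = GenotypeMatrix(samples, matrix.markers, np.vstack(rows))
    return out, truth


# ---------------------------------------------------------------------------
# end-to-end convenience + bundle
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Run the whole generator (founders, duplicates/mislabels, crosses)
    deterministically from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    matrix, truth = simulate_founders(config, rng)
    matrix, truth = plant_duplicates_and_mislabels(matrix, truth, config, rng)
    for design in config.crosses:
        matrix, truth = simulate_cross(matrix, truth, design, config, rng)
    return matrix, truth


def write_bundle(matrix: GenotypeMatrix, truth: SyntheticTruth, out_dir
                 ) -> dict[str, Path]:
    """Emit calls CSV, marker map TSV, VCF and truth JSON into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "calls": out_dir / "calls.csv",
        "map": out_dir / "map.tsv",
        "vcf": out_dir / "genotypes.vcf",
        "truth": out_dir / "truth.json",
    }
    write_genotype_table(matrix, paths["calls"])
    write_marker_map(matrix.markers, paths["map"])
    write_vcf(matrix, paths["vcf"])
    truth.to_json(paths["truth"])
    return paths
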