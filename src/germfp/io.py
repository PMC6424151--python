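"""Readers and writers for genotype tables, marker maps, Flapjack files and VCF.

Supported dialects:

* ``calls_csv`` — samples in rows, markers in columns, cells are diploid call
  tokens (``A:A``, ``A/G``, ``AG``; ``?``/``-``/empty for missing).
* ``flapjack`` — the tab-delimited ``.genotype`` / ``.map`` pair used by the
  Flapjack visualisation tool (calls as ``A/G``).
* VCF 4.2 — biallelic SNP records; GT ``0/0``, ``1/1``, ``0/1``, ``./.`` map
  bijectively onto HOM_A, HOM_B, HET, MISSING.  Parsing goes through pysam.

Heterozygous calls are normalised so the allele pair is lexicographically
sorted (``A:G`` and ``G:A`` are the same call).  Unknown tokens never become
genotypes silently: they load as MISSING with a logged warning.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .model import (
    HET,
    HOM_A,
    HOM_B,
    MISSING,
    GenotypeMatrix,
    MarkerDef,
    SampleMeta,
    split_allele_token,
)

logger = logging.getLogger(__name__)

_FJ_GENOTYPE_HEADER = "# fjFile = GENOTYPE"
_FJ_MAP_HEADER = "# fjFile = MAP"


# ---------------------------------------------------------------------------
# genotype tables
# ---------------------------------------------------------------------------

def _read_grid(path, delimiter: str) -> tuple[list[str], list[str], list[list[str]]]:
    """Read a header row of marker names plus sample rows; strict on raggedness."""
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter=delimiter)
                if r and not (len(r) == 1 and not r[0].strip())
                and not r[0].startswith("#")]
    if not rows:
        raise ValueError(f"{path}: empty genotype table")
    header = rows[0]
    marker_ids = [h.strip() for h in header[1:]]
    sample_names, cells = [], []
    for ridx, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise ValueError(
                f"{path}: ragged row {ridx} ({len(row)} fields, expected {len(header)})"
            )
        sample_names.append(row[0].strip())
        cells.append([c.strip() for c in row[1:]])
    dupes = sorted({n for n in sample_names if sample_names.count(n) > 1})
    if dupes:
        raise ValueError(
            "duplicate sample names without replicate suffixes: " + ", ".join(dupes)
        )
    return sample_names, marker_ids, cells


def _classify_grid(sample_names, marker_ids, cells, source: str) -> GenotypeMatrix:
    n, m = len(sample_names), len(marker_ids)
    split = [[split_allele_token(cells[i][j]) for j in range(m)] for i in range(n)]
    # declare each marker's allele pair from the observed calls
    markers = []
    codes = np.full((n, m), MISSING, dtype=np.int8)
    for j, mid in enumerate(marker_ids):
        counts: Counter[str] = Counter()
        for i in range(n):
            s = split[i][j]
            if isinstance(s, tuple):
                counts.update(s)
        ordered = sorted(counts, key=lambda a: (-counts[a], a))
        if len(ordered) > 2:
            logger.warning(
                "%s: marker %s shows %d alleles; keeping the two most frequent %s",
                source, mid, len(ordered), ordered[:2],
            )
        declared = sorted(ordered[:2])
        allele_a = declared[0] if declared else None
        allele_b = declared[1] if len(declared) > 1 else None
        markers.append(MarkerDef(mid, allele_a=allele_a, allele_b=allele_b))
        for i in range(n):
            s = split[i][j]
            if s is None:
                continue
            if s == "bad":
                logger.warning(
                    "%s: unrecognised call token %r for sample %s, marker %s; "
                    "treated as missing", source, cells[i][j], sample_names[i], mid,
                )
                continue
            a, b = s
            if a not in declared or b not in declared:
                logger.warning(
                    "%s: call %r at sample %s, marker %s uses undeclared allele; "
                    "treated as missing", source, cells[i][j], sample_names[i], mid,
                )
                continue
            if a == b:
                codes[i, j] = HOM_A if a == allele_a else HOM_B
            else:
                codes[i, j] = HET
    samples = [SampleMeta.from_name(nm) for nm in sample_names]
    return GenotypeMatrix(samples, markers, codes)


def read_genotype_table(path, dialect: str = "calls_csv") -> GenotypeMatrix:
    """Read a samples x markers call table.

    ``dialect="calls_csv"`` expects comma separation, ``"flapjack"`` the
    tab-separated Flapjack ``.genotype`` layout.  All tokens are classified
    into the four call states; non-conforming tokens load as MISSING with a
    logged warning.
    """
    path = Path(path)
    if dialect == "calls_csv":
        delim = ","
    elif dialect == "flapjack":
        delim = "\t"
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    names, marker_ids, cells = _read_grid(path, delim)
    return _classify_grid(names, marker_ids, cells, str(path))


def write_genotype_table(matrix: GenotypeMatrix, path, sep: str = ":") -> None:
    """Write a calls CSV (missing as ``?``, calls as ``A:A`` style)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample"] + matrix.marker_ids)
        for i, s in enumerate(matrix.samples):
            w.writerow([s.name] + [matrix.call_str(i, j, sep=sep)
                                   for j in range(matrix.n_markers)])


# ---------------------------------------------------------------------------
# marker maps
# ---------------------------------------------------------------------------

def read_marker_map(path, diagnostic_ids: Sequence[str] = ()) -> list[MarkerDef]:
    """Read a marker map (TSV/CSV with marker id, chromosome, position columns).

    Markers are returned sorted within chromosome by ascending position
    (stable for ties).  Duplicate marker ids are rejected.
    """
    path = Path(path)
    text = path.read_text().splitlines()
    rows = []
    for line in text:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split(",")
        rows.append([p.strip() for p in parts])
    if not rows:
        logger.warning("%s: empty marker map", path)
        return []
    # optional header row
    first = [c.lower() for c in rows[0]]
    if any(k in first[0] for k in ("marker", "id", "snp")):
        rows = rows[1:]
    diag = set(diagnostic_ids)
    defs = []
    seen = set()
    for r in rows:
        if len(r) < 3:
            raise ValueError(f"{path}: map row needs 3 columns, got {r}")
        mid, chrom, pos = r[0], r[1], int(float(r[2]))
        if mid in seen:
            raise ValueError(f"{path}: duplicate marker id {mid!r}")
        seen.add(mid)
        defs.append(MarkerDef(mid, chromosome=chrom, position_bp=pos,
                              diagnostic=mid in diag))
    defs.sort(key=lambda m: (m.chromosome, m.position_bp))
    return defs


def write_marker_map(markers: Sequence[MarkerDef], path) -> None:
    with open(path, "w") as fh:
        fh.write("marker\tchromosome\tposition\n")
        for m in markers:
            if m.chromosome is None or m.position_bp is None:
                logger.warning("marker %s has no map position; skipped", m.id)
                continue
            fh.write(f"{m.id}\t{m.chromosome}\t{m.position_bp}\n")


def attach_map(matrix: GenotypeMatrix, mapped: Sequence[MarkerDef]) -> GenotypeMatrix:
    """Attach chromosome/position (and diagnostic flags) from a map to a matrix.

    Markers absent from the map stay in the matrix but carry no position and
    are excluded from position-dependent analyses; a warning is logged.
    """
    by_id = {m.id: m for m in mapped}
    new_markers = []
    for m in matrix.markers:
        if m.id in by_id:
            src = by_id[m.id]
            new_markers.append(MarkerDef(
                m.id, chromosome=src.chromosome, position_bp=src.position_bp,
                allele_a=m.allele_a, allele_b=m.allele_b,
                diagnostic=m.diagnostic or src.diagnostic,
            ))
        else:
            logger.warning(
                "marker %s absent from map; excluded from position-dependent "
                "analyses", m.id,
            )
            new_markers.append(m)
    return GenotypeMatrix(matrix.samples, new_markers, matrix.codes)


# ---------------------------------------------------------------------------
# Flapjack
# ---------------------------------------------------------------------------

def write_flapjack(matrix: GenotypeMatrix, markers: Sequence[MarkerDef] | None,
                   out_prefix) -> tuple[Path, Path]:
    """Write a Flapjack ``.genotype``/``.map`` pair.

    Calls are written ``A/G`` style with ``-`` for missing.  Markers without
    map entries are excluded from the ``.map`` file with a warning.
    """
    if matrix.n_samples == 0 or matrix.n_markers == 0:
        raise ValueError("cannot write an empty matrix to Flapjack")
    out_prefix = Path(out_prefix)
    if markers is None:
        markers = matrix.markers
    geno_path = out_prefix.with_suffix(".genotype")
    map_path = out_prefix.with_suffix(".map")
    with open(geno_path, "w") as fh:
        fh.write(_FJ_GENOTYPE_HEADER + "\n")
        fh.write("\t" + "\t".join(matrix.marker_ids) + "\n")
        for i, s in enumerate(matrix.samples):
            cells = []
            for j in range(matrix.n_markers):
                c = matrix.call_str(i, j, sep="/")
                cells.append("-" if c == "?" else c)
            fh.write(s.name + "\t" + "\t".join(cells) + "\n")
    by_id = {m.id: m for m in markers}
    with open(map_path, "w") as fh:
        fh.write(_FJ_MAP_HEADER + "\n")
        for mid in matrix.marker_ids:
            m = by_id.get(mid)
            if m is None or m.chromosome is None or m.position_bp is None:
                logger.warning("marker %s missing map entry; excluded from .map", mid)
                continue
            fh.write(f"{mid}\t{m.chromosome}\t{m.position_bp}\n")
    return geno_path, map_path


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write the matrix as an uncompressed VCF 4.2 text file.

    REF/ALT are the marker's declared allele pair (``N`` if an allele was
    never observed).  Markers without map positions are excluded with a
    warning; records are ordered by (contig first-appearance, position).
    """
    mapped = [m for m in matrix.markers
              if m.chromosome is not None and m.position_bp is not None]
    skipped = matrix.n_markers - len(mapped)
    if skipped:
        logger.warning("%d markers without map positions excluded from VCF", skipped)
    contigs: list[str] = []
    for m in mapped:
        if m.chromosome not in contigs:
            contigs.append(m.chromosome)
    order = {c: k for k, c in enumerate(contigs)}
    mapped.sort(key=lambda m: (order[m.chromosome], m.position_bp))
    jidx = {m.id: matrix.marker_index(m.id) for m in mapped}
    gt_str = {HOM_A: "0/0", HOM_B: "1/1", HET: "0/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=germfp\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.sample_names) + "\n")
        for m in mapped:
            j = jidx[m.id]
            ref = m.allele_a or "N"
            alt = m.allele_b or "N"
            gts = "\t".join(gt_str[int(c)] for c in matrix.codes[:, j])
            fh.write(f"{m.chromosome}\t{m.position_bp}\t{m.id}\t{ref}\t{alt}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF of biallelic SNPs into a GenotypeMatrix (via pysam).

    Multi-allelic records are skipped with a warning; contig order is
    preserved as encountered.
    """
    vf = pysam.VariantFile(str(path))
    sample_names = list(vf.header.samples)
    markers: list[MarkerDef] = []
    rows: list[np.ndarray] = []
    for rec in vf:
        alts = rec.alts or ()
        if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
            logger.warning("skipping non-biallelic-SNP record %s:%s", rec.chrom, rec.pos)
            continue
        alt = alts[0]
        mid = rec.id or f"{rec.chrom}_{rec.pos}"
        markers.append(MarkerDef(mid, chromosome=rec.chrom, position_bp=rec.pos,
                                 allele_a=rec.ref, allele_b=alt if alt != "N" else None))
        col = np.full(len(sample_names), MISSING, dtype=np.int8)
        for i, name in enumerate(sample_names):
            gt = rec.samples[name].get("GT")
            if gt is None or any(a is None for a in gt):
                continue
            if gt == (0, 0):
                col[i] = HOM_A
            elif gt == (1, 1):
                col[i] = HOM_B
            else:
                col[i] = HET
        rows.append(col)
    vf.close()
    codes = (np.stack(rows, axis=1) if rows
             else np.empty((len(sample_names), 0), dtype=np.int8))
    samples = [SampleMeta.from_name(n) for n in sample_names]
    return GenotypeMatrix(samples, markers, codes)
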