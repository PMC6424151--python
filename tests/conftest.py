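import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from germfp.io import _classify_grid  # noqa: E402
from germfp.model import (  # noqa: E402
    HET,
    HOM_A,
    HOM_B,
    MISSING,
    GenotypeMatrix,
    MarkerDef,
    SampleMeta,
)


def matrix_from_calls(rows, sample_names=None, marker_ids=None, loci=None):
    """Build a GenotypeMatrix from raw call-token strings (e.g. "A:A", "?").

    ``loci`` is an optional list of (chromosome, position_bp) per marker.
    """
    n, m = len(rows), len(rows[0])
    sample_names = sample_names or [f"s{i + 1}" for i in range(n)]
    marker_ids = marker_ids or [f"m{j + 1}" for j in range(m)]
    mat = _classify_grid(sample_names, marker_ids, [list(r) for r in rows], "test")
    if loci is not None:
        markers = [
            MarkerDef(mk.id, chromosome=c, position_bp=p,
                      allele_a=mk.allele_a, allele_b=mk.allele_b,
                      diagnostic=mk.diagnostic)
            for mk, (c, p) in zip(mat.markers, loci)
        ]
        mat = GenotypeMatrix(mat.samples, markers, mat.codes)
    return mat


def random_matrix(rng, n, m, probs=(0.1, 0.35, 0.35, 0.2)):
    """Random 4-state matrix with generic single-chromosome A/G markers."""
    codes = rng.choice(
        np.array([MISSING, HOM_A, HOM_B, HET], dtype=np.int8),
        size=(n, m), p=probs,
    )
    markers = [MarkerDef(f"m{j + 1}", chromosome="Pv01",
                         position_bp=1000 * (j + 1), allele_a="A", allele_b="G")
               for j in range(m)]
    samples = [SampleMeta(name=f"s{i + 1}") for i in range(n)]
    return GenotypeMatrix(samples, markers, codes)


def oracle_compare(ca, cb):
    """Independent per-marker enumeration of all pairwise-comparison fields."""
    n_a = sum(1 for c in ca if c != MISSING)
    n_b = sum(1 for c in cb if c != MISSING)
    n_shared = matches = hom = het = 0
    score = 0.0
    for x, y in zip(ca, cb):
        if x == MISSING or y == MISSING:
            continue
        n_shared += 1
        if x == y:
            matches += 1
            score += 1.0
        elif x != HET and y != HET:
            hom += 1
        else:
            het += 1
            score += 0.5
    out = {"n_a": n_a, "n_b": n_b, "n_shared": n_shared, "het_diffs": het,
           "hom_diffs": hom, "total_diffs": het + hom}
    if n_shared:
        out.update(pct_het_diffs=het / n_shared, pct_hom_diffs=hom / n_shared,
                   pct_total_diffs=(het + hom) / n_shared,
                   similarity=(matches + 0.5 * het) / n_shared)
    else:
        out.update(pct_het_diffs=None, pct_hom_diffs=None,
                   pct_total_diffs=None, similarity=None)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
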