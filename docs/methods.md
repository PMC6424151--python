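# Methods

## The problem

Breeding programs exchange inbred germplasm across many institutes over
decades.  Names drift, seed lots get mixed, popular varieties are re-released
under new names, and replicate submissions of "the same" line sometimes are
not.  A few hundred well-behaved biallelic SNP assays (KASP-style) are enough
to fingerprint a collection, confirm or refute identity claims, place lines
into the two domesticated gene pools of common bean (Andean and
Mesoamerican), track donor introgressions in backcross material and run
marker-assisted selection (MAS) on trait-diagnostic SNPs.  `germfp`
implements that whole chain as a tested library plus a thin CLI.

## Data model

Every call is one of four states relative to the marker's declared allele
pair: `HOM_A`, `HOM_B`, `HET` (unordered, so `A:G` ≡ `G:A`) and `MISSING`
(`?` in KASP exports).  Token parsing accepts `:`-separated, `/`-separated
and fused two-letter forms; anything unrecognisable loads as `MISSING` with
a logged warning, never silently as a genotype.  Allele pairs are taken from
the data (the two most frequent observed alleles, ties broken
lexicographically) unless a VCF supplies REF/ALT.  Coordinates are 1-based
physical bp, as in VCF.

## Quality control

*Samples* are dropped at ≥ 50% missing calls or > 10% heterozygous calls
(over called markers).  The heterozygosity cap is the one genuinely open
threshold here: inbred lines should be nearly homozygous, and 10% keeps
lines with a residual-heterozygosity block while rejecting accidental
hybrids (a true F1 sits near 50% het over polymorphic markers).  It is
configurable and recorded in the QC report.

*Markers* are kept when their assay-failure rate is < 20% **and** they were
scored in ≥ 50% of samples.  The two criteria are evaluated on different
denominators: failure rate within the genotyping batches where the marker
was actually assayed (a marker absent from whole batches is a panel-design
fact, not an assay failure), coverage over the combined matrix.  Four
trait-diagnostic assays (`bc3`, `bc-3a`, `Bc-3b`, `IntRegAPA3`) are
whitelisted through any threshold because they are deliberately run on
subsets.

*Binning* collapses markers with redundant information content: greedy
single-linkage in map order, joining markers whose call-pattern concordance
is ≥ 0.99 over ≥ 30 shared calls (optionally restricted to a bp window;
window 0 = pattern-only).  Defaults were chosen so that two independent
biallelic markers essentially never bin together (at typical allele
frequencies the expected concordance of unlinked markers is far below 0.9,
so 30 shared calls give a ≥ 0.99 observed concordance only for genuinely
redundant assays).  One representative per bin is kept: highest call rate,
ties to the lower position.

## Pairwise identity

For each sample pair, over markers called in both: identical states are
matches; differing homozygous states are *homozygous mismatches* — the
decisive signal in inbred material, since a single true homozygous
difference cannot arise from residual heterozygosity; every other
difference is a heterozygous difference.  The allele-match similarity
scores 1 / 0.5 / 0 per marker (identical / one shared allele / none) and is
the "correlation" breeders sort similarity matrices by; a Pearson
correlation on 0/1/2 dosages is available as a sensitivity check.

Two samples are *identical germplasm* when their homozygous-mismatch
fraction is strictly below 1% with at least 100 markers shared (the floor
guards against spurious identity via diagnostic-only overlap; pairs sharing
no markers are reported as incomparable, not as dissimilar).  Identity is
not transitive, so duplicate groups are connected components of the
relation, with intra-group rule violations logged and pairs that pass the
mismatch rule but fall below 0.99 similarity flagged *borderline* — the
sister-line signature, where residual heterozygosity at line coding left
many het differences but no homozygous ones.

Gene-pool consistency assigns each sample to the pool of its most similar
declared reference line and flags contradictions with the declared pool —
the seed mix-up detector.

## Dendrogram

Distance is `1 − similarity` (or the total-difference fraction).  Trees are
built by neighbor joining — the standard distance dendrogram for SNP
fingerprints — with the Saitou–Nei Q-criterion, ties broken at the lowest
active index pair for reproducibility, negative branch lengths clamped to 0
with a warning, and the unrooted result represented with a trifurcating
root (n leaves, n−2 internal nodes, 2n−3 branches).  On additive matrices
NJ provably recovers the generating tree; the suite checks exact recovery
(lengths to 1e−9) on random 6–10 taxon trees, and agreement with
scikit-bio's independent NJ implementation on generic matrices.  Export is
Newick (labels with spaces quoted) or a minimal NEXUS loadable by
SplitsTree4.

## Introgression tracking

Parental consensus haplotypes reconcile replicate samples per marker:
(1) a missing call is filled from the called replicate, (2) a homozygote
wins over a heterozygote (in inbred parents the het is the likelier error
or residual segregation), (3) conflicting homozygotes — or two missing
calls — drop the marker.  Painting uses markers where both consensuses are
homozygous for different alleles; in *donor-missing mode*, markers where
the donor assay failed while the recurrent parent is called are kept as
dominant presence/absence markers (relevant in wide crosses, where sister
species fail 23–41% of assays).  At a dominant marker an offspring's failed
call is painted as donor by default — the shared assay-failure signature is
the evidence — with a conservative mode that paints it missing instead.

Offspring states are `P1`/`P2`/`HET`/`MISSING`/`UNEXPECTED` (the latter
when a call matches neither parent; these are skipped, like missing, in
downstream counts).  Recombinations per chromosome are transitions between
consecutive informative states; `P1→HET→P2` counts two events, one per
homolog.  Donor fraction is reported two ways: dosage-weighted
`(2·donor_hom + het) / (2·scored)` (primary, the expected-value scale on
which a BC1 averages 25%) and the plain homozygous-donor fraction.
Residual-heterozygosity blocks are maximal runs of ≥ 3 `HET` markers
(missing calls inside a run neither break nor extend it); shorter runs are
flagged as probable call errors — three consecutive erroneous het calls at
realistic 0.5–2% per-call error rates are improbable by chance, which is
why 3 is the default.

## MAS and F1 verification

The shipped panel carries the two *eIF4E* SNPs of the recessive *bc-3*
BCMV/BCMNV-resistance gene (C227A queried by both `bc3` and `bc-3a`; T194A
by `Bc-3b`): homozygous resistance allele → resistant, heterozygote →
carrier with susceptible phenotype, homozygous susceptible → susceptible.
Markers of one gene must agree per sample; disagreement (including between
the two assays of the same SNP) yields a flagged conflict, not a call.
`IntRegAPA3` (arcelin locus, bruchid resistance) is configured dominant;
its assay allele pair is not published, so the shipped alleles are
placeholders to be set per assay design.  F1 verification classifies a
putative hybrid by its het fraction over parent-polymorphic markers
(≥ 0.9 hybrid, ≤ 0.1 self, otherwise ambiguous, ≥ 10 scored markers
required).

## Synthetic data

The generator emulates a multi-origin fingerprinting collection: 11
chromosomes of 50 Mb with uniformly placed markers (default 69 per
chromosome, a panel-sized map); per-marker pool-A allele frequencies drawn
uniform on (0.05, 0.30) with pool B mirrored at 1−p, giving strongly
diverged pools like the two bean gene pools; inbred founders drawn per pool
(fully homozygous except an optional single residual-het block of 5–15
markers in 10% of lines); 2% routine missingness; two sister-species
samples with 23–41% assay failure plus a 15% private-allele shift (full
interspecific divergence is deliberately not modelled — a vulgaris-designed
SNP panel cannot see it, which is exactly the limitation being emulated);
five planted duplicate pairs at 0.2% call error; two cross-pool mislabels.
Crosses (F1/F2/BC1/RIL) form gametes with Poisson crossover counts
(default mean 1.5 per chromosome per meiosis, which yields mostly 0–4
visible recombinations per chromosome; no interference, uniform crossover
placement — adequate since only physical marker order is used downstream).
RILs self for 6 generations from a shared F1.

Truth tables record the planted partition, mislabel identities, per-marker
true origin states, donor segments, and crossovers — the latter reported
uniformly as the realized breakpoints of the offspring's diploid origin
mosaic (midpoint bp between the flanking markers where the true state
changes), because after generations of RIL selfing only mosaic breakpoints
remain observable, and they are by construction consistent with the
emitted matrix.  The truth JSON schema ships in `docs/truth_schema.json`
and is enforced by a structural validator in the package.

What passing tests on synthetic data do **not** show: real KASP clusters
can fail asymmetrically per plate, missingness is not independent across
markers, and real pool divergence varies per marker class; recovery rates
on real data will be somewhat worse than the clean-room numbers here.

## Numerical and degenerate-input choices

Pair statistics are computed by one-hot matrix products (float32 matmuls,
exact for counts below 2^24, verified against per-marker enumeration);
similarity of a pair with no shared markers is reported as missing — never
0.  Sorting is stable everywhere ties can occur (marker maps, bin
representatives, similarity ranking by name).  Empty marker filters warn
rather than fail; an empty sample filter is an error.  Problem sizes in the
test and acceptance runs (20 seeds × 110 samples × 754 markers for
duplicate recovery; 200 BC1 offspring × 440 markers; 50 RILs × 1650
markers; 100 NJ trees of 6–10 taxa) were chosen as the smallest sizes at
which the Monte-Carlo tolerances (3 standard errors; ≥ 99% per-chromosome
agreement) are meaningful.

## Known limitations

No HMM smoothing of painted states (single-marker miscalls paint as
single-marker segments); no genetic-map (cM) inference, kinship/IBD, or
imputation; binning is greedy single-linkage and therefore order-dependent
in principle (map order makes it deterministic); the gene-pool check is
nearest-reference assignment, not admixture estimation.
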