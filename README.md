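# germfp

SNP fingerprinting for germplasm collections: quality control, duplicate
detection, population dendrograms, introgression tracking and
marker-assisted selection — built for breeding programs that genotype
inbred lines (common bean and similar selfers) with a few hundred biallelic
KASP-style SNP assays.

## What it does, and for whom

Germplasm exchanged between breeding programs accumulates renamed
varieties, mixed seed lots and mislabelled samples.  `germfp` takes a
samples × markers table of diploid calls (`A:A`, `C:T`, `?` for failed
assays) plus a physical marker map and answers the questions a breeder or
genebank curator actually asks:

* **Are these two samples the same line?**  For each pair, over the `n`
  markers called in both, it counts heterozygous and homozygous
  differences and an allele-match similarity
  `s = (matches + ½·het_diffs) / n`.  Two inbred samples are *identical
  germplasm* when their homozygous-mismatch fraction is `< 1%` (with
  ≥ 100 shared markers); duplicate groups are connected components of that
  relation, and pairs that pass the mismatch rule with `s < 0.99` are
  flagged as probable sister lines.
* **Does the collection structure make sense?**  A neighbor-joining
  dendrogram on `d = 1 − s` (Newick/NEXUS export, SplitsTree4-compatible),
  plus a gene-pool consistency check that flags, say, an Andean-named
  sample whose genotype sits among the Mesoamerican references.
* **Where is the donor genome in my backcross lines?**  Parental consensus
  haplotypes from replicate samples, chromosome painting of offspring,
  recombination counts, donor fractions (`(2·donor_hom + het)/(2·scored)`)
  and residual-heterozygosity blocks — including dominant presence/absence
  handling for wide crosses where the donor's assays fail.
* **Which lines carry the resistance allele?**  MAS calls from diagnostic
  SNP panels (shipped: the recessive *bc-3* BCMV/BCMNV-resistance SNPs
  C227A and T194A in *eIF4E*), and F1-hybrid verification from
  heterozygosity at parent-polymorphic markers.

A seeded synthetic-data generator (`germfp.simulate`) produces whole
collections with known truth — diverged gene pools, planted duplicates and
mislabels, sister-species missingness, F1/F2/BC1/RIL crosses with recorded
crossovers — so every stage is testable without any external data.

## Worked example

```python
import germfp as g

cfg = g.SimConfig(seed=42, crosses=[g.CrossDesign("BC1", "AND000", "MES000",
                                                  4, name_prefix="ALB")])
matrix, truth = g.simulate_dataset(cfg)

filtered, removed = g.filter_samples(matrix)     # missing/heterozygosity screen
filtered, _ = g.filter_markers(filtered)         # assay failure + coverage

sim = g.similarity_matrix(filtered)
groups = g.find_duplicates(sim, g.IdentityRule())
for grp in groups.groups:
    if len(grp) > 1:
        print("identical germplasm:", ", ".join(grp))

c1 = g.build_consensus(matrix, "AND000", "AND000", "recurrent")
c2 = g.build_consensus(matrix, "MES000", "MES000", "donor")
poly, dom = g.select_polymorphic(c1, c2, matrix.markers)
for name in ("ALB001", "ALB002", "ALB003", "ALB004"):
    s = g.introgression_fraction(
        g.paint_offspring(matrix, name, c1, c2, poly, dom))
    rec = s.recombinations_per_chromosome
    print(f"{name}: donor dosage {s.donor_fraction_dosage:.1%}, "
          f"recombinations/chromosome {min(rec.values())}-{max(rec.values())}")
```

prints

```
identical germplasm: AND000_set9, MES009
identical germplasm: AND007, AND007_set2
identical germplasm: AND022, AND022_set2
identical germplasm: AND048_set9, MES007
identical germplasm: MES026, MES026_set2
identical germplasm: MES032, MES032_set2
identical germplasm: MES040, MES040_set2
ALB001: donor dosage 28.9%, recombinations/chromosome 0-3
ALB002: donor dosage 11.9%, recombinations/chromosome 0-4
ALB003: donor dosage 29.2%, recombinations/chromosome 0-2
ALB004: donor dosage 20.8%, recombinations/chromosome 0-6
```

Reading the output: the `_set2` pairs are the planted replicate
submissions, recovered by the homozygous-mismatch rule; `AND000_set9` and
`AND048_set9` are planted seed mix-ups — Andean names carrying
Mesoamerican genotypes — which the duplicate scan ties to their true
source lines and the gene-pool check flags independently.  The QC step had
already removed the four BC1 offspring from the identity analysis: at
~25% heterozygosity they fail the inbred-line screen, which is exactly
what that screen is for.  Their painted donor dosages scatter around the
Mendelian 25% expectation for a first backcross, with 0–6 crossovers per
chromosome.

The same workflow is available from a shell:

```bash
germfp simulate --seed 42 --out-dir sim/
germfp qc --in sim/calls.csv --map sim/map.tsv --out filtered.csv
germfp compare --in filtered.csv --out pairs.tsv
germfp tree --in filtered.csv --out tree.nwk --format nexus
germfp paint --in sim/calls.csv --map sim/map.tsv --p1 AND000 --p2 MES000 \
       --offspring ALB001,ALB002,ALB003,ALB004 --out-prefix alb
germfp mas --in filtered.csv
```

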