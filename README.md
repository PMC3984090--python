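# haploclust

Region-based SNP haplotype clustering, haplogroup partitioning,
causative-SNP allele calling and pictorial rendering for
reference-aligned resequencing panels.

## What it does, and for whom

Crop geneticists mining resequencing panels for allelic variation around
candidate genes need three things done reproducibly: (1) cluster the
samples' haplotypes over a gene window, (2) split them into haplogroups
relative to the reference genome, and (3) read off each sample's allele
at the known causative polymorphisms.  `haploclust` does exactly that
for tab-delimited SNP matrices (one chromosome per file, first sample
column = reference), with soybean's maturity loci (*E1*–*E4*) and the
stem-growth gene *Dt1* shipped as the built-in allele registry — and
every piece reusable for any organism.

## The method

For samples *i*, *j* over the SNP positions of a window, the distance is

    d(i, j) = mismatches / compared

where `compared` counts positions at which neither sample is missing
(`-`/`N` excluded pair-wise).  A UPGMA tree is built on these distances
(merge height = d/2, size-weighted average linkage), with deterministic
tie-breaking and child ordering so identical inputs give identical
trees, Newick files and images.  Cutting the tree at the first branching
point yields the two tier-1 haplogroups: **reference-like** (containing
the reference sample) and **non-reference**; deeper tiers refine the
partition.  Allele calls compare each sample's base at a causative SNP
with the registry's ref/alt symbols (IUPAC ambiguity code covering
exactly {ref, alt} ⇒ heterozygous); genes whose variants are structural
rather than SNPs are covered by a deletion-*candidate* scan over runs of
missing data.  Codon helpers: `affected_codon(p) = ⌈p/3⌉` on CDS
coordinates, frameshift-intact length `⌈p/3⌉ − 1`.

See `docs/methods.md` for assumptions, parameter defaults and
limitations.

## Worked example

Simulate a small panel with two planted haplotype clusters, cluster it,
and render the pictorial:

```sh
haploclust simulate --seed 7 --n-samples 12 --n-sites 80 \
    --out-snp panel.txt --out-header panel.xml --out-truth truth.tsv
haploclust cluster --snp panel.txt --samples panel.xml --out-dir run
haploclust render --snp panel.txt --samples panel.xml --mode three --out pic.png
```

`run/haplogroups.tsv` then contains the tier-1 partition:

```
sample	group	reference_like
Ref	1	yes
S01	1	yes
S03	1	yes
...
S02	2	no
S08	2	no
```

Group 1 is the reference-like haplogroup (10 samples clustered with
`Ref`), group 2 the divergent one — matching `truth.tsv`'s planted
founder labels exactly.  `run/distances.tsv` holds the pairwise identity
distances (e.g. `Ref` vs `S02` = 0.092105, i.e. 9.2% of their jointly
called sites differ), `run/tree.nwk` the ultrametric UPGMA tree, and
`pic.png` the position × sample grid colored white/black/gray for
identical/different/missing relative to the reference.

Allele calling against the built-in registry (here on a real-coordinate
E1-window matrix) writes one row per sample:

```sh
haploclust call --snp e1_panel.txt --samples e1_panel.xml --out genotypes.tsv
```

with each cell the allele name at the causative SNP (`E1` / `e1-as` /
`no_data` / `heterozygous` / `unknown_variant`), plus an optional
deletion-candidate column when `--scan-start/--scan-end` are given.
Datasets sharing a reference can be combined with `haploclust merge`
(positions become the sorted union; samples of a dataset lacking a
position receive the reference base there).

The same functionality is available as a library:

```python
from haploclust import (distance_matrix, upgma, partition_haplogroups,
                        haplotype_window, Region)
window = haplotype_window(Region("Gm06", 20006928, 20007814))  # ±3.5 kb
# -> Region(chromosome='Gm06', start=20003428, end=20011314)
```

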