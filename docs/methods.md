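# Methods

## The problem

Given whole-genome resequencing panels expressed as reference-aligned SNP
matrices, a recurring question in crop genetics is: over the window
around a candidate gene, how many distinct haplotypes does a panel carry,
which samples share the reference genome's haplotype, and how do those
haplogroups line up with the known functional and variant alleles of the
gene?  The motivating use case is the soybean maturity loci (*E1*–*E4*)
and the stem-growth-habit gene *Dt1*, analysed against the Williams 82
reference, but nothing in the machinery is soybean-specific.

## Data model

A `SNPMatrix` holds one chromosome's variant positions (strictly
increasing, 1-based) by ordered samples; the first sample is the
reference genome.  Cells are single IUPAC symbols: heterozygous
genotypes entered as two-letter tokens collapse to the ambiguity code of
the pair at parse time (`AG` → `R`, order- and case-insensitive; `TT` →
`T`).  Missing data is exactly `-` or `N`; `.` is rejected rather than
silently treated as missing, so corrupt files fail loudly.  Ambiguity
codes are carried as first-class symbols through distance computation
and rendering — they are interpreted (as potential heterozygotes) only
at the allele-calling step, where the interpretation is well defined.

All coordinates are 1-based with both interval ends inclusive.  There is
no half-open convention anywhere in the public API; the single deliberate
exception is `interval_length`, which returns `end − start` because
deletion sizes in the allele literature are quoted under the
coordinate-difference convention (the 2,633 bp intron-3 deletion at
Gm19:47516697–47519330 fixes this empirically).

Chromosome labels compare as exact trimmed strings (`Gm06` ≠ `6`);
no alias normalization is attempted, because silent relabelling is the
classic way to corrupt a multi-dataset merge.

## Distance and clustering

The genetic distance between two samples over a window is the number of
mismatched symbols divided by the number of positions where **both**
samples have data; missing positions are excluded pair by pair.  No
evolutionary correction is applied — for near-identical haplotypes over
a few-kb window the mismatch proportion is the right resolution, and it
is the definition the downstream tree is meant to reflect.  A pair with
zero informative overlap is assigned distance 1.0 and a
`ZeroOverlapWarning`: a conservative maximal separation beats an
undefined value, and the warning keeps the decision auditable.

Trees are built with textbook UPGMA: repeatedly merge the two clusters
at minimal average distance, place the merge node at half that distance,
and maintain cluster–cluster distances as size-weighted averages over
member pairs (the incremental update `(nᵢdᵢₖ + nⱼdⱼₖ)/(nᵢ+nⱼ)` is
algebraically the unweighted mean over all member pairs; the test suite
enforces equality against a brute-force oracle that recomputes every
mean from scratch, and against SciPy's average linkage).  Two
deterministic conventions make output byte-stable across runs:

* **tie-break** — among tied minimal pairs, merge the pair whose sorted
  pair of smallest original sample indices is lexicographically least;
* **child order** — within a merge node, the child containing the
  lexicographically smallest leaf name comes first.

Both are arbitrary but fixed; haplogroup *contents* do not depend on
them, only the drawing order does.

A **haplogroup partition at tier *t*** cuts the tree at depth *t* (root
= depth 0): the groups are the leaf sets of the maximal subtrees rooted
at depth *t*, with any leaf shallower than *t* forming its own group.
Tier 1 therefore gives the two root-child clades — the reference-like
haplogroup (the one containing the reference sample) and its
complement — and higher tiers refine the partition monotonically.

## Dataset integration

Datasets called against the same reference can be merged position-wise:
the merged position list is the sorted union, and a position absent from
one dataset is filled in with the **reference symbol** for that
dataset's samples.  In a variant-only matrix "no row" means "no variant
reported", so reference fill-in is the faithful interpretation — but it
biases sparsely-assayed samples toward reference-likeness, which in turn
shrinks their distances to the reference.  Users comparing panels with
very different site densities should keep this in mind; it is the main
caveat of the merge.

Reference symbols must agree at shared positions; a conflict is a hard
error by default (overridable to prefer-first with a logged warning),
because a silently wrong reference column corrupts every haplogroup
downstream.  Later datasets' reference columns are dropped when they
duplicate the merged reference's name and kept as ordinary samples
otherwise; cross-dataset sample-name collisions are suffixed
`@<dataset>`.  More than three datasets triggers an advisory warning
only — nothing in the algorithm needs a hard cap.

## Allele calling

The registry maps genes to causative SNPs (`AlleleDef`: site, reference
symbol + allele name, alternative symbol + allele name).  The built-in
registry covers the soybean loci with SNP-defined alleles: *E1/e1-as*
(Gm06:20007173 C↔G — Williams 82 carries *e1-as*, so the reference
symbol C names *e1-as* and G names functional *E1*), *E2/e2*
(Gm10:44732850 A↔T) and the four missense *dt1* alleles of *Dt1*
(R62S, P113L, R130K, R166W).  R130K is included for completeness even
though it is rarely observed in resequencing panels.

Per sample and site: reference symbol → reference allele name; alt
symbol → alt name; missing → `no_data`; the ambiguity code expanding to
exactly {ref, alt} → `heterozygous`; anything else →
`unknown_variant`.  A site absent from the matrix produces
assumed-reference calls with an explicit flag: in a variant-only matrix
absence is evidence of the reference state, but weaker than an observed
base, and the flag preserves that distinction.

For a gene with several registry sites, the per-gene label in the
genotype table is combined as: any observed alt wins (multiple alts join
with `+`); else heterozygous; else unknown; `no_data` only when *every*
site is missing; otherwise the reference allele name.  The asymmetry is
intentional — only an observed alternative base positively renames the
allele, while missing data at one of several sites does not overturn
reference observations at the others.  A per-sample note: a sample
missing data at exactly the one site that would distinguish an alt
cannot be positively classified; it surfaces as the reference name, and
the per-site `call_allele` output (which reports `no_data` at that
site) is the place to check when that distinction matters.

Structural alleles (large deletions, retrotransposon insertions) have no
causative SNP.  The deletion-signature scan counts missing symbols for
one sample over the SNP positions inside a scan region and flags the
sample as a deletion **candidate** when the missing fraction reaches a
threshold (default 0.9) over at least a minimum number of sites
(default 3, so a single missing call can never flag).  The flag is
heuristic by design — a long no-data run is *consistent with* a genomic
deletion but confirming one needs an orthogonal assay (e.g. PCR across
the breakpoints), which is outside this package's scope.

Codon arithmetic operates on 1-based CDS positions only:
`affected_codon(p) = ⌈p/3⌉`, and a frameshift at CDS position *p* leaves
`⌈p/3⌉ − 1` N-terminal residues intact.  One documented ambiguity: a
nonsense mutation in codon *k* is conventionally described as truncating
the protein "to *k* amino acids" although only *k − 1* residues are
actually translated before the stop; the package reports the affected
codon index (*k*) and leaves the off-by-one of the prose convention to
the caller.

## Rendering

Positions are rows (ascending, with the position and the reference
nucleotide always printed on the left), samples are columns in the
tree's leaf order, with the dendrogram drawn above.  `three_color` mode
encodes identity to the reference (white = identical, black =
different, gray = no data); `multi_color` encodes the base (A red,
G blue, C green, T yellow, missing gray) with a fixed ten-entry
auxiliary palette for the ambiguity codes, every entry distinct from the
base colors.  Optional per-cell letters, one-cell inter-column spacing,
and a right-hand sidebar marking gene span (light bar), exon (black
bar), exon index and strand for each SNP row.

Rendering draws directly with Pillow primitives and a fixed bitmap
font; image dimensions are an exact affine function of
`(n_positions, n_samples, show_space, cell_size)` given the documented
layout constants, and PNG output is byte-identical across runs on the
same inputs.  JPEG is supported for convenience but carries no
byte-determinism guarantee (encoders differ).  A pixel-area guard
(default 5·10⁷ px) refuses absurd renders; the text report has no such
cap.  All pixel metrics and the palette are this package's own
documented defaults.

## Synthetic panels

`simulate.generate_matrix` emulates the structure of a low-coverage
resequencing panel without modelling its population genetics: a
reference haplotype drawn uniformly over {A,C,G,T}; *k* founders, each
non-reference founder differing from the reference at a seeded
`divergence` fraction of sites; samples copy an assigned founder, then
receive per-cell noise mutations (rate `noise`), per-cell missing calls
(rate `missing`, symbol `N`), and finally contiguous `-` runs over
requested (samples × sub-region) blocks, mimicking deletions.  The
reference column stays pristine.

Defaults are sized like a real gene-window panel: 32 samples (reference
plus 31), 300 variant sites over a ~8 kb window, two founders at 10%
divergence, 1% noise and 5% missing data — the noise and missing rates
being what ~5× short-read coverage plausibly produces.  The generator
deliberately omits recombination and linkage disequilibrium: the planted
two-cluster model is sufficient to exercise every downstream operation
with known truth, and passing tests demonstrate correct *algorithmic*
behaviour, not robustness to admixed or recombinant real panels (where
the first-tier bipartition may genuinely be ambiguous).

Reproducibility contract: one global seed drives a named PRNG stream per
stage, in the fixed order `positions`, `reference`, `founders`,
`assignment`, `noise`, `missing` — so changing the missing rate never
perturbs the founder draws.  Stream order is part of the public
contract.

## Numerical and edge-case choices

* Distances live exactly in [0, 1]; the `DistanceMatrix` constructor
  enforces symmetry and a zero diagonal.
* Ultrametricity holds to 1e-9 (exact arithmetic up to float rounding);
  merge heights are non-decreasing by the UPGMA reducibility property.
* An empty region slice is legal (0-position matrix), but clustering an
  empty region is a data error at the CLI level.
* Duplicate positions in an input file are an error, not last-wins:
  silent overwrite hides upstream merge bugs.
* The reference column may itself contain ambiguity codes; nothing
  forbids it, and interpretation is left to the caller.
* Test problem sizes (≤ 32 samples, ≤ 300 sites, 20-seed recovery
  battery, 200 oracle matrices at n ≤ 8) were chosen as the smallest
  panels that exercise every code path with planted truth.

## Known limitations

* No diploid phasing and no multi-allelic representation beyond one
  symbol per cell.
* No genomic↔CDS coordinate mapping: codon arithmetic requires CDS
  positions from the caller.
* Deletion candidates are not allele calls; single-base deletions and
  insertions are invisible to a SNP matrix altogether.
* Reference fill-in during merging biases sparse datasets toward the
  reference-like haplogroup (see above).
* Haplogroup definitions depend on the window: the same panel cut at a
  different region can partition differently, which is a property of
  the method, not a defect.
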