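# Methods

`cladepan` reconstructs the population structure of a closely related set of
bacterial genomes in two independent ways and then asks what gene content
distinguishes the groups it finds.  All stages run on plain-text inputs
(FASTA, GFF3, TSV) and a synthetic-genome generator provides ground-truthed
inputs so every inference can be scored against the process that produced
the data.

## The synthetic population

The generator builds an ancestral genome of `n_ancestral_families` (default
300) protein-coding genes — codons sampled uniformly from the 61 non-stop
codons, lengths uniform on 300–1500 bp rounded to codons — laid end-to-end
on a single contig with fixed 50-bp intergenic spacers.  The genome evolves
down a star-of-clades tree: `n_clades` (default 4) clade ancestors at
`inter_clade_divergence` = 0.02 substitutions/site from the root, each with
`strains_per_clade` (default 5) tips at `intra_clade_divergence` = 0.002,
plus an optional outgroup genome on a 0.15 stem.  Substitutions follow a
Kimura-2-parameter process: each site is hit with probability equal to the
branch length, and a hit is a transition with probability κ/(κ+2) (κ =
`transition_bias` = 4).  Multiple hits per branch are not modeled, so
per-branch divergence understates a true Markov process by O(rate²); at the
default rates this bias is under 1% and the K2P estimator downstream is the
matching correction.

At each ingroup tip, every ancestral family is independently lost with
probability 0.03 or pseudogenized with probability 0.02.  Pseudogenization
replaces the intact CDS annotation with either a 5′ truncation (≥30% of the
gene, codon-aligned) or two fragments separated by a skipped stretch; the
underlying DNA stays in place, mirroring how annotation pipelines call
fCDS/pseudogenes.  Each clade additionally receives one planted 10-CDS
block of novel families, inserted at the same ancestral gene boundary in
every member of the clade and nowhere else; these blocks are the ground
truth for clade-specific content and variable-region detection and are
exempt from loss/pseudogenization so they remain diagnostic.

What the simulation deliberately omits: multi-contig draft structure
(except via an explicit `split_contigs` flag), recombination and HGT beyond
the planted blocks, rearrangements, realistic intergenic composition, rRNA
operons and plasmids.  Intergenic spacers do not mutate, which dilutes
whole-genome divergence by the spacer fraction (~5%); the divergence
recovery test budgets for this.  Passing tests therefore demonstrate that
the inference machinery recovers planted structure under an idealized
neutral model — not that it is robust to assembly noise, annotation error
or recombination in real data.

Internal stop codons can arise in a protein when mutation creates one; they
are translated as `X` so the protein alphabet stays 20 amino acids + X.

## Average nucleotide identity

Two self-contained estimators stand in for the BLAST- and MUMmer-based ANI
tools:

* **ANIb-style** — the query is cut into non-overlapping 1020-bp fragments
  (a trailing remainder is kept only if ≥510 bp).  Each fragment is placed
  on the subject by 15-mer diagonal voting and aligned to the best window
  with edlib; fragments with identity < 0.30 or aligned coverage < 0.70 are
  discarded (the classical ANIb retention rule).  ANI is the mean identity
  of retained fragments; identity counts gap columns against the fragment.
* **ANIm-style** — unique 20-mer exact matches are chained collinearly
  (longest increasing subsequence on subject positions), same-diagonal
  seeds are merged into maximal exact blocks, and inter-block gaps up to
  5 kb are closed by global alignment.  Identity is matches over matched
  columns; gap columns are excluded from the denominator, so indel-only
  differences do not depress ANIm.

A pair with no seed or chain yields a *missing* value (never 0).  The
directed values of a pair are averaged into a symmetric matrix with unit
diagonal.  The hybrid distance matrix uses 1 − ANIm within a species label
and 1 − ANIb across labels, which is how a species-complex study balances
ANIm's resolution at high identity against ANIb's robustness at low
identity; missing cells are a hard error there because the tree needs a
complete matrix.

## Gene families and the ternary matrix

Proteins are clustered into families by thresholded single linkage: an edge
joins two proteins iff amino-acid identity > 0.80 **and** both alignment
coverages > 0.80 (strict inequalities), computed from a global BLOSUM62
alignment (gap open 11, extend 1); identity is identical residues over
aligned columns with terminal gaps trimmed, coverage is each protein's
residues inside the trimmed core over its length.  Families are the
connected components.  Candidate pairs are pre-filtered by a shared 5-mer
(identity > 0.8 over the core forces a gapless run of ≥5 identical
residues, so no qualifying edge is lost), then by an edlib edit-distance
bound that any qualifying pair provably satisfies; pairs already in the
same component are skipped, which cannot change the components.

The genome × family matrix is ternary: intact (2) when the genome has ≥1
intact member, fragment-only (1), absent (0).  Core families are present
(state ≥1) in every genome; singletons have exactly one member gene;
variable is the rest.  Fragment-only presence counts as present for
core/pan membership (existence question); pathway and PTS profiling default
to intact-only (function question).

Rarefaction draws, per rep, one random strain permutation and reports
pan/core sizes along its prefixes, so each step size sees `reps` (default
10) random strain combinations and every rep's pan curve is non-decreasing
and core curve non-increasing by construction.  Group statistics resample
`sample_n` = 5 strains per group (without replacement by default; a
with-replacement mode is available), 10,000 reps, reporting mean ± sd of
unique and total variable-family and singleton counts.

## Core-SNP supermatrix

Tree-building families must be intact in every genome, contain no fragment
member anywhere, and have exactly one member per genome (the single-copy
rule makes a one-row-per-genome alignment well defined).  Each family is
aligned center-star: the center minimizes total pairwise edit distance
(ties to the smallest genome label), others are aligned to it globally
(match 1 / mismatch −1 / open −4 / extend −1) and merged under
"once a gap, always a gap" — adequate for near-identical core genes and
fully deterministic.  A column enters the supermatrix iff it has ≥2
distinct symbols from {A,C,G,T,-} and no N in any row; every gap column is
its own character.  Columns are concatenated in family-id order with
per-column provenance.

## Trees

K2P distance: d = −½·ln(1−2P−Q) − ¼·ln(1−2Q) with P, Q the transition and
transversion proportions over sites where both rows are in {A,C,G,T}
(pairwise deletion of gaps and N).  Arguments ≤0 raise a saturation error
naming the pair.  Note that on a variant-columns-only supermatrix these
distances are on the per-variant-column scale, far larger than genome-wide
divergence; topology and supports are the meaningful output.

Neighbor joining is the canonical Q-criterion algorithm; ties are broken by
the lexicographically smallest pair of cluster labels (a cluster is labeled
by its smallest descendant leaf) and negative branch lengths are clamped to
zero.  Rooting places the root at the midpoint of the outgroup's pendant
edge.  Bootstrap resamples supermatrix columns with replacement (default
100 reps) over a canonical lexicographic column order — making supports
exactly invariant to input column order under a fixed seed — rebuilds
K2P + NJ per rep, and attaches to each internal edge of the point-estimate
tree the percentage of replicates containing its bipartition; replicates
that saturate are skipped with a warning, and ≥20% skips abort.  Fitch
parsimony scores a fixed tree by per-column set operations (rooting
invariant).  Complete-linkage dendrograms of matrix rows (euclidean metric,
ternary states as 0/1/2) use scipy's agglomerative implementation and also
return the leaf order used for matrix export.

Newick output sorts children by smallest descendant leaf label and formats
branch lengths at 6 significant digits, so serialization is byte-stable;
integer bootstrap supports become internal node labels.

## Clade profiling

A family is clade-specific when present in ≥90% of the clade's genomes and
≤5% of the rest (thresholds and the presence mode are exposed).  Variable
regions of a target genome against a comparison group are maximal runs of
≥`min_run` (default 5) consecutive CDS whose families are absent from every
comparison genome, allowing `gap_tolerance` (default 0) unmarked interior
CDS; the region span is last CDS end − first CDS start + 1.  This is an
operational, annotation-driven replacement for composition-based
genomic-plasticity detectors: the quantities reported (region count, bp,
CDS) are exactly the ones such a study tabulates.  Pathway completion is
the fraction of a pathway's roles whose family is intact in the strain; PTS
profiling counts intact components (0–4) per system.  Unresolvable family
labels count as absent with a warning.

## Numerical and design choices

* Probabilities/thresholds are compared with strict `>` where the family
  rule says "more than 80%"; a pair at exactly 0.80 does not join.
* Coverage is enforced on both proteins (min of the two) — the conservative
  reading when "alignment coverage" is not attributed to a side.
* Missing ANI propagates as NaN, never as 0.
* The pangenome and core-SNP stages run on the ingroup only; the outgroup
  appears only in the ANI/hybrid tree, where it roots the topology.
* Family ids (`FAM_<smallest member gene>`), NJ tie-breaks, center choice
  and Newick ordering are all deterministic, so every pipeline product is
  reproducible bit-for-bit under a fixed seed.
* Problem sizes used by the test-suite and the acceptance script — 4 clades
  × 5 strains + outgroup, 300 ancestral families (~280 kb genomes), 100
  bootstrap reps, 10,000 group-bootstrap reps, 200 NJ-oracle matrices, 100
  Fitch-oracle instances — were chosen so the full run completes on a
  single CPU in a few minutes while leaving every statistical check
  comfortably powered.

## Known limitations

* The ANI estimators are calibrated surrogates, not bit-compatible
  re-implementations of BLAST/MUMmer pipelines; absolute values can differ
  from pyani by ~0.5% on real drafts (fragment-edge and repeat handling).
* Center-star alignment is exact enough for >80%-identity core genes but
  not a general MSA; highly gapped families would need a profile aligner.
* Fragment proteins shorter than 80% of their family's length legitimately
  fail the coverage rule and form their own (often singleton) families;
  family-recovery guarantees therefore apply to intact genes.
* Variable-region detection sees only annotated CDS; intergenic insertions
  are invisible to it.
* The with-replacement group-bootstrap mode exists but the default follows
  the without-replacement reading, the only one well defined for a group
  with exactly `sample_n` strains.
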