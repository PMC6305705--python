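# Methods

## The measurement

`darkmeter` treats "how well is this community represented by sequenced
genomes?" as a nearest-neighbor identity problem on a reference
phylogeny. The reference database couples, for each completely
sequenced genome: its full-length 16S rRNA gene, its position as a tip
of a rooted tree, and its 16S gene copy number. A query read's **map
ratio** is the fraction of identical positions in an optimal semi-global
alignment against its nearest reference gene. The read is then placed on
a tree *edge* — its nearest tip's edge when the nearest reference is
unique, or the edge above the most recent common ancestor of all
co-optimal references when identity ties (ambiguity is represented
structurally, never broken arbitrarily). There is one edge above every
node, tips and root included: a rooted bifurcating tree over n genomes
has 2n − 1 edges.

This deliberately replaces likelihood-based phylogenetic placement with
the simplest rule preserving the two quantities the analysis consumes:
a nearest sequenced genome (for the identity statistic) and a tree
position (for copy-number lookup). It likewise replaces covariance-model
domain scanning with a best-alignment-score decision against per-domain
sequence panels: the decision *rule* (best model wins, ties and weak
scores unassigned) is the modeled behavior, not the scoring engine.

## Alignment and the map-ratio convention

Alignment is global over the read with free terminal gaps on the
reference (a short amplicon aligns within a full-length gene), scored
match +1, mismatch −1, gap open −2, gap extension −1, via Biopython's
`PairwiseAligner`; counts are taken from its first, deterministically
ordered traceback. The identity denominator is the **read length**:
every query base counts, whether aligned, inserted relative to the
reference, or end-clipped, while reference overhang columns do not.
`N` positions never count as matches. This convention is fixed and
recorded in output metadata because identity definitions that include
or exclude gap columns differ by up to a few percent on indel-rich
alignments.

Two numerical properties of this convention matter when interpreting
low map ratios:

- For substitution-only divergence d at distinct sites, identity to the
  source is exactly 1 − d as long as the score-optimal alignment stays
  gapless — which it does for d ≤ ~0.25 under the default scores, since
  converting a mismatch to a match through gaps costs at least 3 for a
  gain of 2.
- For *unrelated* sequences, optimal gapped identity does not fall to
  the ~0.25 random-match level: chaining matches through cheap gaps
  against a 6× longer reference puts a floor near 0.60–0.67 for 250 nt
  reads. Map ratios of highly divergent reads therefore bottom out
  around 0.6 rather than declining linearly; the dark-read rule's
  log-abundance threshold must clear that floor before such reads can
  be flagged.

## Nearest-reference search

Candidates are ranked by shared 8-mer count and only those within 90%
of the best count are aligned. The prefilter is bypassed — every
reference aligned — whenever the best shared count falls below 20: for
a 250 nt read against 1,500 nt genes, chance sharing averages ~5.5
8-mers, so counts in that range carry no ranking information, whereas
reads within 20% of a true relative share ~40+. With this rule the
prefiltered search returns exactly the exhaustive-scan co-optimal set
(asserted against a brute-force scan in the test suite), while skipping
most alignments for reads that do have a nearby reference. All
co-optimal references are kept as a set.

## Copy-number normalization

Reads placed on an edge are divided by the 16S copy number expected at
that tree position: the genome's own copy number at a tip edge, the
unweighted arithmetic mean over subtended tips at an internal edge.
The mean rule keeps every estimate inside the min–max envelope of the
observed copy numbers below the edge and makes the transform exactly
invertible (Σ normalized × copy = Σ raw, enforced to 1e−9 relative);
branch-length-weighted ancestral estimation is a possible refinement,
not implemented. Polytomies are accepted anywhere below the root; a
root with more than two children is rejected as an unrooted tree.

## Survey statistics

- **Sample summaries.** Mean map ratio per sample and domain is
  weighted by read counts (a unique read seen 3,000 times contributes
  3,000 draws). Only samples with *more than* 1,000 domain-assigned
  reads enter the flagging distribution; those below the floor are
  summarized but never flagged. The flag threshold is mean ratio < 0.8.
- **Dark-read rule.** A unique read is flagged when
  `map_ratio < 0.075 · log10(abundance) + 0.4`. Abundance enters on a
  log10 scale: on a raw-count scale the threshold would exceed 1 for
  any abundance above 8 and flag everything. At abundance 1 the
  threshold is exactly the intercept. Abundance is tallied within each
  consensus environment by default (a unique read may be flagged in one
  environment and not another); a config switch tallies globally.
- **Dark edges.** Flagged uniques aggregate by edge; the top 10 per
  domain by summed abundance are reported with abundance-weighted mean
  map ratio, the nearest-taxon label, and the environment contributing
  the most flagged reads. Ties order by edge id.
- **Rarefaction** uses the closed-form hypergeometric expectation
  E[S(n)] = Σᵢ (1 − C(N−Nᵢ, n)/C(N, n)), evaluated with log-gamma for
  stability; Monte Carlo subsampling is retained only as a test oracle.
  Roundoff at large N is ~1e−11, so exact endpoint identities are
  asserted to that resolution.
- **Richness vs effort.** Ordinary least squares of unique-read count
  on sample count, one point per environment; Pearson r², two-sided
  t-distribution p-value, and residuals (to list environments more
  diverse than effort predicts). No multiple-testing correction is
  applied. The standalone operation requires ≥3 points and nonzero
  variance; the pipeline simply omits the regression output when its
  synthetic environments do not satisfy this.

## The synthetic survey generator

The generator exists so that every downstream stage has ground truth.
It emulates the *structure* of a polar amplicon survey, not its
biology:

- **Reference tree**: pure-birth topology (uniform leaf splits) with
  exponential branch lengths, mean 0.02 substitutions/site per branch;
  the two root children found the Bacteria and Archaea clades and carry
  an extra 0.15 divergence each so the domains are well separated.
  Sequences evolve from a random 1,500 nt root gene by
  `round(length × gene_len)` substitutions per branch, no indels.
  Copy numbers are uniform integers in [1, 15].
- **Reads**: 250 nt windows of source genes. Dark-lineage templates
  receive *exactly* `round(d × 250)` substitutions at distinct sites
  (d cycling through {0.05, 0.10, 0.20} by default), so constructed
  identity is exact rather than binomial — parameter-recovery tests can
  assert equality within ±0.02 instead of a statistical band.
  In-database templates use d = 0. Per-sample abundances are Poisson;
  sequencing errors are i.i.d. per base (default 0.1%); a configurable
  fraction of reads carries a sub-Q20 base late (exercising trimming)
  or early (exercising rejection). Samples are allocated to consensus
  environments triangularly (1, 2, 3, … runs) so sampling effort varies
  across environments as it does in real surveys.
- **Determinism**: one seed drives everything; internal streams are
  derived with distinct nonzero tags (NumPy `SeedSequence` zero-pads
  entropy, so a zero tag would alias a plain `default_rng(seed)`
  stream). Fixed seed ⇒ byte-identical outputs, asserted file-by-file.

What the generator does **not** emulate: 16S secondary structure and
conserved/variable region layout, chimeras, PCR and primer bias,
paired-end structure, realistic quality-score decay, or realistic
phylogenetic depth. Passing tests therefore demonstrate that the
*measurement machinery* is correct and calibrated on data with known
truth — not that any particular real environment is well or poorly
represented by genomes.

## Default problem sizes

Tests and the acceptance script run surveys of ~20 reference genomes
and a few thousand reads across 3–6 samples — large enough that every
code path (trimming, rejection, collapse, ties, MRCA placement, both
domains, all divergence levels) is exercised, small enough to rerun
freely. The statistics are scale-free roll-ups, so nothing in the
implementation depends on these sizes.

## Known limitations

- Nearest-neighbor identity ignores branch lengths; two references
  equidistant in identity but very different in age place identically.
- The domain panels are full reference sets; for large databases a
  curated subset per domain would be the right panel choice.
- The identity floor (~0.6) under gapped alignment compresses the
  dynamic range of the map ratio below ~0.7; comparisons between very
  low map ratios should not be over-interpreted.
- Edge copy numbers use the unweighted subtended-tip mean; no
  uncertainty is propagated into normalized abundances.
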