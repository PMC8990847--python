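# Methods

## Scope and model

`panpav` implements a map-to-pan PAV workflow for a resequenced diversity
panel. The object at its centre is the binary genes × accessions presence
matrix; everything upstream (novel-sequence construction, coverage-based
calling) produces it and everything downstream (frequency classes, growth
curves, selection scans, PAV-GWAS, family profiles) consumes it. The package
does not run assemblers, aligners or domain-detection pipelines: it consumes
their outputs (contig FASTA, alignment records, coverage fractions, family
annotation tables), which keeps every stage deterministic and testable.

Coordinates are 0-based half-open everywhere internally; GFF3 input/output
converts at the boundary.

## Novel-sequence construction (contigclass)

Rules and defaults:

* contigs shorter than `min_contig_len` = 500 bp are removed; exactly
  500 bp is kept (the threshold is a minimum length);
* reliable alignment: identity strictly greater than `min_identity` = 90
  (a "higher than" rule, so identity exactly 90.0 is dropped) and
  contig-side span at least `min_aln_len` = 300 bp. The length threshold is
  applied per record and on the contig side; under indels the reference-side
  span differs, and chaining of adjacent records is deliberately not done —
  one record, one decision;
* classification: no reliable alignment → fully unaligned; otherwise the
  complement of the union of aligned intervals is computed within
  `[0, contig_len)` and segments of at least `min_unaligned` = 500 bp are
  novel; none → the contig is fully explained by the reference.

Redundancy removal is a single greedy pass in place of the multi-round
cd-hit/all-vs-all procedure used in large production runs: sequences are
visited longest first (ties by id, so the pass is order-stable), and a
sequence joins the first cluster whose representative shares enough
canonical k-mers. Identity between sequences is *estimated*, not aligned:
with independent substitutions at rate p, a fraction (1−p)^k of k-mers
survive, so containment C of the shorter sequence's canonical k-mer set
(k = 15 by default; canonical = min of k-mer and reverse complement, making
the estimator strand-blind) implies identity C^(1/k). The join rule is
C ≥ 0.8 · (cluster_identity/100)^k — the 0.8 factor encodes the requirement
that the match cover at least 80% of the shorter sequence. Random unrelated
sequences share essentially no 15-mers (expected collisions ≈ L/4^15), so
the rule cleanly separates them; an exact edit-distance oracle bounds the
estimator's error in the tests (within a few identity points for lightly
diverged pairs). Clustering representatives a second time returns them
unchanged (idempotence, asserted in tests). Representatives can optionally
be re-screened against the reference with the same criterion, standing in
for the final re-alignment round of production pipelines.

Taxonomy screening keeps sequences labelled within Eukaryota/Viridiplantae
and keeps unlabelled sequences — absence of a database hit is not evidence
of contamination.

## PAV calling and classification (pavcall)

Coverage of a gene is the fraction of its interval overlapped by depth ≥ 1
regions. The presence rule is `covered_fraction ≥ 0.8`; the usual statement
of the rule (above 80% present, below 80% absent) leaves exactly 80%
undefined, so the boundary is fixed inclusive here and the threshold is
configurable. Calling requires an explicit coverage value for
every gene × accession pair — a missing pair is an error, not an implicit
absence, because silent absence is the classic source of inflated PAV
counts.

Class boundaries: core means present in all accessions (takes precedence
over the softcore band, which nominally includes 100%); softcore is
frequency in [0.99, 1); shell is [0.01, 0.99), so a frequency of exactly 1%
is shell; cloud is below 1%. Genes present in no accession are flagged
`absent_everywhere` and dropped from class tables by default.

Growth curves use full random permutations per replicate rather than
independent subsets per sample size k, so every replicate path is monotone
by construction (pan non-decreasing, core non-increasing); per-k means and
standard deviations are reported across replicates.

## Selection scan (selscan)

Only variable (shell + cloud) genes are tested; core and softcore genes
cannot differ between groups. The WT, ND and Putative_Feral groups are
excluded from comparisons by default (too few accessions). Per gene the 2×2
presence table is tested with a two-sided Fisher exact test implemented by
hypergeometric enumeration: all tables with the observed margins are
enumerated and the probabilities of those no more probable than the observed
table are summed (log-pmf via `gammaln`, with a 1e−7 relative guard on the
point-probability comparison against floating-point ties). Any zero margin
returns p = 1 (degenerate). BH FDR is computed per comparison — the four
comparisons are corrected as separate families, a documented and
configurable choice.

Fold change is defined on frequencies, orientation-free:
max(f₁,f₂)/min(f₁,f₂). When exactly one frequency is zero the fold change is
+∞ — it passes the > 2 filter and the decision rests on the FDR; genes
absent from both groups are excluded from testing. Direction labels follow
the comparison semantics: improvement comparisons (IMP vs LDR) yield
favorable/unfavorable, subspecies comparisons (\_M vs \_A) yield
highly/lowly in melo, and any other pair yields generic `higher_in_<group>`
labels.

Term enrichment is one-sided over-representation (upper hypergeometric
tail), the standard convention for GO-style annotation tests, with BH FDR
across terms and an enrichment flag at FDR < 0.05.

## PAV-GWAS (pavgwas)

The scan is a deliberately simple, fully specified single-marker model:
trait ~ intercept + presence + top-k principal components of the
column-centered PAV matrix, ordinary least squares, two-sided t-test on the
presence coefficient, Bonferroni threshold α/m over the m genes actually
tested. Iterative multi-locus engines (FarmCPU and kin) are out of scope by
design; this model preserves the genotype definition and threshold rule
while being exactly testable — its per-gene estimates match a reference OLS
implementation to 1e−9 in the tests. Internally the fit uses the
Frisch–Waugh–Lovell decomposition (trait and genotypes residualized on the
shared covariates once), which is algebraically identical and lets the whole
scan vectorize.

Genes with fewer than `min_carriers` = 5 accessions in either presence
class are excluded and logged (degenerate designs). Missing trait values
drop the accession for that trait only; no imputation. PCA signs are fixed
by making each component's largest-magnitude gene loading positive, so runs
are deterministic. All phenotyped accessions enter the scan regardless of
group label.

## Synthetic cohorts (simulate)

The generator emulates what the analysis assumes, with planted truth for
recovery testing:

* **Cohort**: the default group composition is the melon panel — IMP_A 109,
  IMP_M 54, LDR_A 50, LDR_M 41, WT 14, ND 27, Putative_Feral 2 (297
  accessions).
* **Gene universe**: defaults of 2,000 core / 200 softcore / 680 shell /
  120 cloud genes (~3,000 total) keep the published class proportions at a
  size every test and the acceptance run can afford; the published
  34,305-gene scale is an empirical outcome, not a simulation condition.
  Core genes are present everywhere. Softcore presence counts are drawn
  uniformly from the [0.99N, N−1] band, cloud counts from [1, 0.01N) — a
  gene absent from every accession is never emitted. Shell presence is an
  independent Bernoulli per accession at a per-gene frequency drawn from
  Uniform(0.05, 0.95); the true frequency spectrum of shell genes is
  unknown, so this flat prior is a modelling choice exposed in `SimConfig`.
  Realized classes are enforced exactly by resampling a gene's vector until
  it lands in the intended band (the planted-truth contract is that the
  classifier applied to true presence reproduces the true classes), with a
  configuration error after bounded retries.
* **Planted selection**: `n_selected_genes` shell genes get group-specific
  frequencies (default 0.9/0.1 between IMP_M and LDR_M, alternating
  direction); other groups sit at the midpoint.
* **Planted trait effects**: `n_trait_genes` shell genes at carrier
  frequency 0.5 each add `trait_effect_size` (default 2.0) per presence
  allele to a baseline, plus Gaussian noise (default sd 1.0).
* **Coverage**: present genes draw covered fractions from [0.95, 1.0],
  absent from [0.0, 0.3] by default — separated across the 0.8 threshold so
  calling is exact; overlapping ranges (e.g. present [0.7, 1.0], which
  misses one third of present genes) exercise the noisy regime.
* **Contigs**: reference-derived windows with full-length high-identity
  records; novel contigs with no records; partial contigs = reference window
  plus a ≥ 500 bp novel insert at one end, the record covering only the
  reference part; contaminants labelled `Bacteria`. Alignment records are
  emitted directly instead of being recomputed by an aligner, so the
  classification logic is tested in isolation.
* **Determinism**: one global seed fans out to fixed per-stage substreams
  (content / coverage / reference / contigs / traits), so stages can be
  regenerated independently and runs are byte-identical given the seed.

What the generator does **not** emulate: linkage between genes (presence is
independent per gene, matching the scan's per-gene treatment but unlike real
chromosomes), read-level noise and mapping bias (coverage fractions are
drawn, not computed from reads), assembly artefacts, gene-length-dependent
coverage effects, and relatedness structure within groups. Passing recovery
tests therefore demonstrate correctness of the statistical machinery under
its own assumptions, not robustness to real-data violations of them.

## Family profiling (famprof)

Family summaries use the `total (variable, core)` convention with variable =
cloud ∪ shell and core = core ∪ softcore; these definitions fix the table
semantics and are not configurable. Both core% and variable% are exposed per
family and interpretation is left to the caller. Chromosome densities are
genes/Mb over pseudomolecule lengths from a .fai-style index; pan-genome
additional contigs are excluded from density denominators. The published
melon RGA and TPS per-family count tables ship in `panpav.datasets` as
inputs; inflating them to placeholder genes and re-aggregating reproduces
every cell, which is how the summary path is validated.

## Numerical and scale choices

* Fisher p-values are exact sums of hypergeometric point probabilities;
  agreement with integer-arithmetic enumeration is better than 1e−13
  relative over all 2×2 tables with margins ≤ 30.
* BH FDR is delegated to `statsmodels` behind the `bh_fdr` surface and
  checked against a direct implementation of the step-up formula (max
  absolute difference < 1e−12 on random vectors).
* The acceptance run uses 250 accessions × 3,000 genes, 50 seeds for GWAS
  power and 5,000 null genes for the p-value uniformity check — sizes chosen
  so the whole script completes in well under a minute on one CPU while
  keeping Monte-Carlo error far from every decision boundary.

## Known limitations

* The k-mer containment estimator loses accuracy above ~5% divergence
  (containment decays as (1−p)^k); the 90% clustering criterion sits within
  its usable range but the estimator should not be used as a general
  identity calculator.
* The single-marker GWAS does not control for cryptic relatedness beyond
  the PAV principal components; with strong family structure a mixed model
  would be required.
* Per-comparison FDR families mean a gene tested in four comparisons is not
  jointly corrected across them.
* The simulator's independence assumptions (above) make it unsuitable for
  studying linkage-driven artefacts.
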