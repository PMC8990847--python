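# panpav

Map-to-pan analysis of gene **presence/absence variation (PAV)** in crop
resequencing panels, built around the melon (*Cucumis melo*) pan-genome
workflow: construct the non-reference ("novel") sequence set from
contig-vs-reference alignments, call per-gene presence from read coverage,
classify genes by occurrence frequency, model pan/core-genome growth, scan
for genes whose frequency shifted between breeding groups, run PAV-based
GWAS on quantitative traits, and profile gene families (resistance-gene
analogs, terpene synthases) by their PAV classes.

It is aimed at plant population-genomics groups who have short-read
resequencing of a diversity panel plus per-accession de-novo assemblies, and
want a tested, scriptable implementation of the PAV pipeline rather than a
collection of one-off scripts. A synthetic-cohort generator with planted
ground truth (`panpav.simulate`) makes every stage testable end to end.

## The method

**Novel sequence construction.** Assembled contigs shorter than 500 bp are
discarded. A contig-vs-reference alignment is *reliable* if its identity
exceeds 90% and it spans ≥ 300 bp of the contig. Contigs with no reliable
alignment are *fully unaligned* and contribute their whole sequence; contigs
whose reliable alignments leave a continuous unaligned stretch ≥ 500 bp are
*partially unaligned* and contribute those stretches. Extracted sequences
are de-duplicated by greedy clustering at 90% identity (canonical k-mer
containment), re-screened against the reference, contaminants are removed by
taxonomy label, and the survivors are appended to the reference to form the
pan-genome.

**PAV calling and classes.** A gene is *present* in an accession when the
fraction of its gene region covered by that accession's reads is ≥ 0.8.
With N accessions and a gene present in n of them (f = n/N):

| class    | rule              |
|----------|-------------------|
| core     | n = N             |
| softcore | 0.99 ≤ f, n < N   |
| shell    | 0.01 ≤ f < 0.99   |
| cloud    | f < 0.01          |

Pan/core growth curves come from iterative random sampling: each replicate
is a random accession permutation, pan(k) = genes in ≥ 1 of the first k
accessions, core(k) = genes in all of them.

**Selection scan.** For each group comparison (e.g. improved vs landrace
*ssp. melo*), per-gene presence counts give a 2×2 table tested with a
two-sided Fisher exact test; Benjamini–Hochberg FDR is computed across the
tested (variable) genes. A gene is *selected* when frequency fold change
max(f₁,f₂)/min(f₁,f₂) > 2 and FDR < 0.001; it is *favorable* when more
frequent in the improved group, *unfavorable* otherwise.

**PAV-GWAS.** Shell-gene presence is the genotype. Each trait is fitted per
gene by least squares, trait ~ intercept + presence + top PAV principal
components, and the presence coefficient is t-tested; genome-wide
significance is Bonferroni, α/m over the m genes tested (0.05/7789 ≈ 6.4e−6
at the melon shell-gene scale).

## Worked example

A small synthetic cohort with 10 planted selected genes and 3 planted trait
genes:

```python
from panpav.simulate import SimConfig, simulate_all
from panpav import pavcall, selscan, pavgwas

cfg = SimConfig(
    group_sizes={"IMP_A": 40, "IMP_M": 30, "LDR_A": 30, "LDR_M": 25, "WT": 5},
    n_core_genes=60, n_softcore_genes=0, n_shell_genes=60, n_cloud_genes=5,
    n_selected_genes=10, n_trait_genes=3, seed=11,
)
bundle = simulate_all(cfg, with_sequences=False)

pav = pavcall.build_pav_matrix(bundle.coverage, threshold=0.8)
classes = pavcall.classify_matrix(pav)
print(classes["gene_class"].value_counts().to_dict())
# {'core': 60, 'shell': 60, 'cloud': 5}

scan = selscan.selection_scan(pav, bundle.truth.groups, classes,
                              comparisons=[("IMP_M", "LDR_M")])["IMP_M_vs_LDR_M"]
print((scan["call"] != "ns").sum(), "selected genes of", len(scan), "tested")
# 10 selected genes of 61 tested
```

The ten planted genes (group frequencies 0.9 vs 0.1) are exactly the ten
calls; e.g. `MELO_sim_00062` comes out with observed frequencies 0.87 vs
0.04, fold change 21.7, FDR 3.2e−9, call `favorable`. The GWAS stage on the
shell genes recovers the three planted trait genes (true effect 2.0 trait
units per presence allele, noise sd 1.0):

```python
shell = classes.index[classes["gene_class"] == "shell"]
pcs = pavgwas.pav_pcs(pav.loc[shell], 3)
gwas = pavgwas.association_scan(pav.loc[shell], bundle.traits["fruit_length"], pcs)
print(gwas.results[gwas.results["significant"]][["effect", "se", "p_value"]])
#                   effect        se       p_value
# gene_id
# MELO_sim_00070  1.798510  0.361809  2.146370e-06
# MELO_sim_00071  1.792124  0.335707  4.264037e-07
# MELO_sim_00072  2.657027  0.262788  6.305044e-18
```

All three are significant at the Bonferroni threshold 0.05/60 ≈ 8.3e−4, with
effect estimates bracketing the planted 2.0.

The same pipeline is available from the shell: `panpav simulate`,
`panpav contigclass`, `panpav pav`, `panpav curves`, `panpav selscan`,
`panpav gwas`, `panpav famprof` (see `panpav --help`).

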