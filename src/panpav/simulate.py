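"""Synthetic pan-genome cohorts with planted ground truth.

The generator emulates the statistical structure the PAV analysis assumes: a
gene universe partitioned into core / softcore / shell / cloud occurrence
classes, shell genes with group-dependent frequencies planted for the
selection scan, shell genes with additive trait effects planted for the
PAV-GWAS, read-coverage fractions with configurable noise around true
presence, and assembled contigs (reference-derived, fully novel, partially
novel and contaminant) with their alignment records emitted directly so the
novel-sequence construction is testable without running an aligner.

The default cohort is the melon resequencing panel composition: 109 IMP_A,
54 IMP_M, 50 LDR_A, 41 LDR_M, 14 WT, 27 ND and 2 Putative_Feral accessions
(297 total). Gene-class counts default to ~3,000 genes at the observed class
proportions (roughly 73% core+softcore, 23% shell, 4% cloud).

A single global seed fans out into independent per-stage streams (gene
content, coverage, contigs, traits), so each stage is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contigclass import AlignmentRecord
from .pavcall import CLOUD, CORE, SHELL, SOFTCORE, classify_gene_frequency
from .selscan import _direction_labels

__all__ = ["SimConfig", "TruthSet", "SimBundle", "ConfigurationError",
           "simulate_gene_content", "simulate_coverage", "simulate_reference",
           "simulate_contigs", "simulate_traits", "simulate_all", "write_bundle"]


class ConfigurationError(ValueError):
    """An infeasible or inconsistent simulation configuration."""


_DEFAULT_GROUPS = {
    "IMP_A": 109,
    "IMP_M": 54,
    "LDR_A": 50,
    "LDR_M": 41,
    "WT": 14,
    "ND": 27,
    "Putative_Feral": 2,
}

_STAGE_KEYS = {"content": 1, "coverage": 2, "reference": 3, "contigs": 4, "traits": 5}


@dataclass(frozen=True)
class SimConfig:
    group_sizes: dict = field(default_factory=lambda: dict(_DEFAULT_GROUPS))
    n_core_genes: int = 2000
    n_softcore_genes: int = 200
    n_shell_genes: int = 680
    n_cloud_genes: int = 120
    n_selected_genes: int = 40
    selected_comparison: tuple[str, str] = ("IMP_M", "LDR_M")
    selected_freq_pair: tuple[float, float] = (0.9, 0.1)
    n_trait_genes: int = 5
    trait_effect_size: float = 2.0
    trait_noise_sd: float = 1.0
    trait_baseline: float = 10.0
    trait_name: str = "fruit_length"
    coverage_present_range: tuple[float, float] = (0.95, 1.0)
    coverage_absent_range: tuple[float, float] = (0.0, 0.3)
    shell_freq_range: tuple[float, float] = (0.05, 0.95)
    additional_gene_fraction: float = 0.15
    n_reference_contigs: int = 20
    n_novel_contigs: int = 20
    n_partial_contigs: int = 10
    n_contaminant_contigs: int = 5
    gene_length_range: tuple[int, int] = (900, 3000)
    n_chromosomes: int = 12
    seed: int = 0

    @property
    def n_accessions(self) -> int:
        return sum(self.group_sizes.values())

    @property
    def n_genes(self) -> int:
        return (
            self.n_core_genes + self.n_softcore_genes + self.n_shell_genes + self.n_cloud_genes
        )

    def validate(self) -> None:
        n = self.n_accessions
        counts = (
            self.n_core_genes, self.n_softcore_genes, self.n_shell_genes,
            self.n_cloud_genes, self.n_selected_genes, self.n_trait_genes,
            self.n_reference_contigs, self.n_novel_contigs,
            self.n_partial_contigs, self.n_contaminant_contigs,
        )
        if any(c < 0 for c in counts):
            raise ConfigurationError("all counts must be >= 0")
        if n < 2:
            raise ConfigurationError("need at least 2 accessions")
        for name in ("coverage_present_range", "coverage_absent_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ConfigurationError(f"{name} must be an interval within [0, 1]")
        if self.n_selected_genes + self.n_trait_genes > self.n_shell_genes:
            raise ConfigurationError(
                "n_selected_genes + n_trait_genes must not exceed n_shell_genes"
            )
        if self.n_softcore_genes > 0 and int(np.ceil(0.99 * n)) > n - 1:
            raise ConfigurationError(
                f"softcore genes need a frequency in [0.99, 1): infeasible for {n} accessions"
            )
        if self.n_cloud_genes > 0 and int(np.ceil(0.01 * n)) - 1 < 1:
            raise ConfigurationError(
                f"cloud genes need a presence count in [1, 0.01*N): infeasible for {n} accessions"
            )
        if self.n_selected_genes > 0:
            for g in self.selected_comparison:
                if g not in self.group_sizes:
                    raise ConfigurationError(f"selected_comparison group {g!r} not in group_sizes")


@dataclass(frozen=True)
class TruthSet:
    """Planted ground truth of a simulated cohort."""

    true_presence: pd.DataFrame  # genes x accessions, 0/1
    true_class: pd.Series  # gene -> core/softcore/shell/cloud
    selected_genes: pd.DataFrame  # gene_id, comparison, direction, freq_a, freq_b
    trait_genes: pd.DataFrame  # gene_id, effect
    gene_provenance: pd.Series  # gene -> reference/additional
    groups: pd.Series  # accession -> group label


def _rng(config: SimConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), _STAGE_KEYS[stage]]))


def _sample_with_class(rng, n, p_per_acc, target_class, max_tries=1000):
    """Bernoulli presence vector resampled until its realized class matches."""
    for _ in range(max_tries):
        vec = (rng.random(n) < p_per_acc).astype(np.int8)
        k = int(vec.sum())
        if classify_gene_frequency(k, n) == target_class and k > 0:
            return vec
    raise ConfigurationError(
        f"could not realize a {target_class} gene in {max_tries} draws; "
        "check frequency settings against the cohort size"
    )


def simulate_gene_content(config: SimConfig) -> tuple[TruthSet, pd.DataFrame]:
    """Draw the true presence matrix and its planted structure.

    Core genes are present everywhere; softcore genes are absent in at least
    one accession but present in >=99%; shell genes get an independent
    Bernoulli presence per accession at a per-gene frequency (group-specific
    for planted selected genes, 0.5 for planted trait genes); cloud genes are
    present in at least one accession but <1%. Realized classes are enforced
    exactly. Returns ``(TruthSet, true_presence)``.
    """
    config.validate()
    rng = _rng(config, "content")
    n = config.n_accessions

    accessions, labels = [], []
    for g, size in config.group_sizes.items():
        for i in range(size):
            accessions.append(f"{g}_{i:03d}")
            labels.append(g)
    groups = pd.Series(labels, index=pd.Index(accessions, name="accession_id"), name="group")
    group_masks = {g: (groups == g).to_numpy() for g in config.group_sizes}

    vectors, classes, gene_ids = [], [], []
    selected_rows, trait_rows = [], []

    for i in range(config.n_core_genes):
        vectors.append(np.ones(n, dtype=np.int8))
        classes.append(CORE)

    softcore_lo = int(np.ceil(0.99 * n))
    for i in range(config.n_softcore_genes):
        k = int(rng.integers(softcore_lo, n))  # [0.99N, N-1]
        vec = np.zeros(n, dtype=np.int8)
        vec[rng.choice(n, size=k, replace=False)] = 1
        vectors.append(vec)
        classes.append(SOFTCORE)

    fa, fb = config.selected_freq_pair
    ga, gb = config.selected_comparison if config.n_selected_genes else (None, None)
    label_hi_a, label_hi_b = (
        _direction_labels(ga, gb) if config.n_selected_genes else ("", "")
    )
    n_planted = config.n_selected_genes + config.n_trait_genes
    for i in range(config.n_shell_genes):
        idx = len(vectors)
        if i < config.n_selected_genes:
            high_in_a = i % 2 == 0
            p = np.full(n, (fa + fb) / 2.0)
            p[group_masks[ga]] = fa if high_in_a else fb
            p[group_masks[gb]] = fb if high_in_a else fa
            vec = _sample_with_class(rng, n, p, SHELL)
            selected_rows.append(
                {
                    "gene_id": idx,  # resolved to id below
                    "comparison": f"{ga}_vs_{gb}",
                    "direction": label_hi_a if high_in_a else label_hi_b,
                    "freq_a": fa if high_in_a else fb,
                    "freq_b": fb if high_in_a else fa,
                }
            )
        elif i < n_planted:
            vec = _sample_with_class(rng, n, 0.5, SHELL)
            trait_rows.append({"gene_id": idx, "effect": config.trait_effect_size})
        else:
            freq = rng.uniform(*config.shell_freq_range)
            vec = _sample_with_class(rng, n, freq, SHELL)
        vectors.append(vec)
        classes.append(SHELL)

    cloud_hi = int(np.ceil(0.01 * n)) - 1  # largest count with freq < 1%
    for i in range(config.n_cloud_genes):
        k = int(rng.integers(1, cloud_hi + 1))
        vec = np.zeros(n, dtype=np.int8)
        vec[rng.choice(n, size=k, replace=False)] = 1
        vectors.append(vec)
        classes.append(CLOUD)

    # provenance: core/softcore genes sit on the reference; a configured
    # fraction of shell+cloud genes live on pan-genome additional contigs
    n_genes = len(vectors)
    provenance = np.array(["reference"] * n_genes, dtype=object)
    var_idx = np.arange(config.n_core_genes + config.n_softcore_genes, n_genes)
    n_add = int(round(config.additional_gene_fraction * len(var_idx)))
    if n_add:
        add_idx = rng.choice(var_idx, size=n_add, replace=False)
        provenance[add_idx] = "additional"
    ref_counter = add_counter = 0
    for i in range(n_genes):
        if provenance[i] == "reference":
            gene_ids.append(f"MELO_sim_{ref_counter:05d}")
            ref_counter += 1
        else:
            gene_ids.append(f"NOVEL_sim_{add_counter:05d}")
            add_counter += 1

    presence = pd.DataFrame(
        np.vstack(vectors), index=pd.Index(gene_ids, name="gene_id"), columns=groups.index
    )
    for row in selected_rows:
        row["gene_id"] = gene_ids[row["gene_id"]]
    for row in trait_rows:
        row["gene_id"] = gene_ids[row["gene_id"]]
    truth = TruthSet(
        true_presence=presence,
        true_class=pd.Series(classes, index=presence.index, name="gene_class"),
        selected_genes=pd.DataFrame(
            selected_rows, columns=["gene_id", "comparison", "direction", "freq_a", "freq_b"]
        ),
        trait_genes=pd.DataFrame(trait_rows, columns=["gene_id", "effect"]),
        gene_provenance=pd.Series(provenance, index=presence.index, name="source"),
        groups=groups,
    )
    return truth, presence


def simulate_coverage(true_presence: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Covered fractions around the true presence states (long format).

    Present genes draw uniformly from ``coverage_present_range``, absent genes
    from ``coverage_absent_range``; the ranges may overlap to emulate noisy
    calling.
    """
    rng = _rng(config, "coverage")
    if true_presence.size == 0:
        return pd.DataFrame(columns=["gene_id", "accession_id", "covered_fraction"])
    present = true_presence.to_numpy(dtype=bool)
    lo_p, hi_p = config.coverage_present_range
    lo_a, hi_a = config.coverage_absent_range
    frac = np.where(
        present,
        rng.uniform(lo_p, hi_p, size=present.shape),
        rng.uniform(lo_a, hi_a, size=present.shape),
    )
    long = (
        pd.DataFrame(frac, index=true_presence.index, columns=true_presence.columns)
        .stack()
        .rename("covered_fraction")
        .reset_index()
    )
    long.columns = ["gene_id", "accession_id", "covered_fraction"]
    return long


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, int(length))].tobytes().decode()


def simulate_reference(
    config: SimConfig, gene_ids=None
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random reference chromosomes with gene models placed along them.

    Reference-provenance genes are laid out round-robin over
    ``n_chromosomes`` pseudomolecules with 200 bp spacers; lengths are drawn
    from ``gene_length_range``. Returns ``(chromosome sequences, gene models)``
    with gene models carrying 0-based half-open coordinates.
    """
    rng = _rng(config, "reference")
    if gene_ids is None:
        gene_ids = [f"MELO_sim_{i:05d}" for i in range(config.n_genes)]
    lo, hi = config.gene_length_range
    chrom_names = [f"chr{c:02d}" for c in range(1, config.n_chromosomes + 1)]
    cursors = {c: 200 for c in chrom_names}
    rows = []
    for i, gid in enumerate(gene_ids):
        chrom = chrom_names[i % config.n_chromosomes]
        length = int(rng.integers(lo, hi + 1))
        start = cursors[chrom]
        rows.append(
            {
                "gene_id": gid,
                "chrom": chrom,
                "start": start,
                "end": start + length,
                "strand": "+" if rng.random() < 0.5 else "-",
            }
        )
        cursors[chrom] = start + length + 200
    chroms = {c: _random_seq(rng, cursors[c] + 200) for c in chrom_names}
    return chroms, pd.DataFrame(rows)


def simulate_contigs(
    config: SimConfig, reference: dict[str, str]
) -> tuple[dict[str, str], list[AlignmentRecord], dict[str, str], pd.DataFrame]:
    """Assembled-contig inputs for novel-sequence construction, with truth.

    Emits reference-derived contigs (full-length high-identity alignments),
    fully novel contigs (no alignments), partial contigs (a reference window
    plus a novel insert of >=500 bp at one end, with an alignment record
    covering only the reference part) and contaminant contigs (novel sequence
    tagged with a bacterial taxonomy label). Returns
    ``(contigs, alignment records, taxonomy labels, contig truth table)``.
    """
    rng = _rng(config, "contigs")
    chrom_names = sorted(reference)
    contigs: dict[str, str] = {}
    records: list[AlignmentRecord] = []
    taxonomy: dict[str, str] = {}
    truth_rows = []

    def ref_window(length):
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        seq = reference[chrom]
        length = min(length, len(seq) - 1)
        start = int(rng.integers(0, len(seq) - length))
        return chrom, start, seq[start : start + length]

    for i in range(config.n_reference_contigs):
        cid = f"refctg_{i:04d}"
        length = int(rng.integers(1000, 3001))
        chrom, start, seq = ref_window(length)
        contigs[cid] = seq
        records.append(
            AlignmentRecord(cid, 0, len(seq), chrom, start, start + len(seq),
                            float(rng.uniform(92.0, 99.9)))
        )
        truth_rows.append({"contig_id": cid, "category": "reference", "novel_start": -1, "novel_end": -1})

    for i in range(config.n_novel_contigs):
        cid = f"novctg_{i:04d}"
        contigs[cid] = _random_seq(rng, int(rng.integers(1000, 3001)))
        taxonomy[cid] = "Viridiplantae" if rng.random() < 0.5 else "unlabelled"
        truth_rows.append({"contig_id": cid, "category": "novel", "novel_start": 0,
                           "novel_end": len(contigs[cid])})

    for i in range(config.n_partial_contigs):
        cid = f"parctg_{i:04d}"
        ref_len = int(rng.integers(1000, 2001))
        novel_len = int(rng.integers(500, 1501))
        chrom, start, ref_part = ref_window(ref_len)
        novel_part = _random_seq(rng, novel_len)
        insert_at_end = bool(rng.random() < 0.5)
        if insert_at_end:
            contigs[cid] = ref_part + novel_part
            aln = (0, len(ref_part))
            novel_iv = (len(ref_part), len(ref_part) + novel_len)
        else:
            contigs[cid] = novel_part + ref_part
            aln = (novel_len, novel_len + len(ref_part))
            novel_iv = (0, novel_len)
        records.append(
            AlignmentRecord(cid, aln[0], aln[1], chrom, start, start + len(ref_part),
                            float(rng.uniform(92.0, 99.9)))
        )
        truth_rows.append({"contig_id": cid, "category": "partial",
                           "novel_start": novel_iv[0], "novel_end": novel_iv[1]})

    for i in range(config.n_contaminant_contigs):
        cid = f"conctg_{i:04d}"
        contigs[cid] = _random_seq(rng, int(rng.integers(1000, 3001)))
        taxonomy[cid] = "Bacteria"
        truth_rows.append({"contig_id": cid, "category": "contaminant", "novel_start": -1,
                           "novel_end": -1})

    return contigs, records, taxonomy, pd.DataFrame(truth_rows)


def simulate_traits(
    true_presence: pd.DataFrame, trait_genes: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Quantitative trait per accession: baseline + sum of planted per-gene
    effects times presence + Gaussian noise (sd = ``trait_noise_sd``)."""
    rng = _rng(config, "traits")
    acc = true_presence.columns
    value = np.full(len(acc), float(config.trait_baseline))
    for _, row in trait_genes.iterrows():
        value += float(row["effect"]) * true_presence.loc[row["gene_id"]].to_numpy(float)
    value += rng.normal(0.0, config.trait_noise_sd, size=len(acc))
    return pd.DataFrame({config.trait_name: value}, index=pd.Index(acc, name="accession_id"))


@dataclass(frozen=True)
class SimBundle:
    """Everything one simulated cohort produces."""

    config: SimConfig
    truth: TruthSet
    coverage: pd.DataFrame
    traits: pd.DataFrame
    reference: dict
    gene_models: pd.DataFrame
    contigs: dict
    alignments: list
    taxonomy: dict
    contig_truth: pd.DataFrame


def simulate_all(config: SimConfig, with_sequences: bool = True) -> SimBundle:
    """Run every stage of the generator under one seed."""
    truth, presence = simulate_gene_content(config)
    coverage = simulate_coverage(presence, config)
    traits = simulate_traits(presence, truth.trait_genes, config)
    if with_sequences:
        ref_genes = truth.gene_provenance.index[truth.gene_provenance == "reference"]
        reference, gene_models = simulate_reference(config, list(ref_genes))
        contigs, alignments, taxonomy, contig_truth = simulate_contigs(config, reference)
    else:
        reference, gene_models = {}, pd.DataFrame()
        contigs, alignments, taxonomy, contig_truth = {}, [], {}, pd.DataFrame()
    return SimBundle(config, truth, coverage, traits, reference, gene_models,
                     contigs, alignments, taxonomy, contig_truth)


def write_bundle(bundle: SimBundle, outdir) -> None:
    """Write a simulated cohort to disk in the pipeline's file formats."""
    from pathlib import Path

    from . import io as pio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if bundle.reference:
        pio.write_fasta(bundle.reference, out / "reference.fa")
        pio.write_gff3(bundle.gene_models, out / "genes.gff3")
        pio.write_fasta(bundle.contigs, out / "contigs.fa")
        pio.write_alignments(bundle.alignments, out / "alignments.tsv")
        pd.Series(bundle.taxonomy, name="taxonomy").rename_axis("seq_id").to_csv(
            out / "taxonomy.tsv", sep="\t"
        )
        bundle.contig_truth.to_csv(out / "contig_truth.tsv", sep="\t", index=False)
    bundle.coverage.to_csv(out / "coverage.tsv", sep="\t", index=False)
    bundle.truth.groups.rename_axis("accession_id").to_csv(out / "groups.tsv", sep="\t")
    bundle.traits.to_csv(out / "traits.tsv", sep="\t")
    bundle.truth.true_presence.to_csv(out / "true_presence.tsv", sep="\t")
    bundle.truth.true_class.rename_axis("gene_id").to_csv(out / "true_class.tsv", sep="\t")
    bundle.truth.selected_genes.to_csv(out / "true_selected.tsv", sep="\t", index=False)
    bundle.truth.trait_genes.to_csv(out / "true_trait_genes.tsv", sep="\t", index=False)
    bundle.truth.gene_provenance.rename_axis("gene_id").to_csv(
        out / "gene_provenance.tsv", sep="\t"
    )
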