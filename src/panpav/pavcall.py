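"""Gene presence/absence calling and occurrence-frequency classification.

Presence of a gene in an accession is decided from the fraction of the gene
region covered by that accession's reads: covered fraction >= 0.8 means the
gene is present (the threshold is configurable; exactly 80% counts as
present). The resulting genes x accessions binary matrix is the input to every
downstream stage.

Occurrence-frequency classes follow the standard pan-genome nomenclature:

* **core** — present in all accessions;
* **softcore** — present in at least 99% of accessions, but not all;
* **shell** — present in 1%–99% of accessions (the 1% boundary is shell);
* **cloud** — present in fewer than 1% of accessions.

Genes present in no accession are degenerate cloud genes, flagged and excluded
from matrices by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._intervals import covered_length

__all__ = [
    "CORE",
    "SOFTCORE",
    "SHELL",
    "CLOUD",
    "gene_coverage_from_depth",
    "call_presence",
    "build_pav_matrix",
    "classify_gene_frequency",
    "classify_matrix",
    "pan_core_curves",
    "GrowthCurve",
]

CORE = "core"
SOFTCORE = "softcore"
SHELL = "shell"
CLOUD = "cloud"
VARIABLE_CLASSES = (SHELL, CLOUD)
CORE_CLASSES = (CORE, SOFTCORE)


def gene_coverage_from_depth(depth_intervals, gene_interval) -> float:
    """Fraction of a gene interval overlapped by >=1 depth interval.

    ``depth_intervals`` are 0-based half-open regions with read depth >= 1
    (BED-like); ``gene_interval`` is ``(start, end)`` on the same coordinate
    system. A zero-length gene interval is an error.
    """
    start, end = int(gene_interval[0]), int(gene_interval[1])
    if end <= start:
        raise ValueError(f"gene interval [{start}, {end}) has non-positive length")
    return covered_length(depth_intervals, start, end) / (end - start)


def call_presence(covered_fraction: float, threshold: float = 0.8) -> bool:
    """True (present) iff ``covered_fraction >= threshold``."""
    if not 0.0 <= covered_fraction <= 1.0:
        raise ValueError(f"covered fraction {covered_fraction} outside [0, 1]")
    return covered_fraction >= threshold


def build_pav_matrix(
    coverage: pd.DataFrame, threshold: float = 0.8
) -> pd.DataFrame:
    """Apply the presence rule to a long-format coverage table.

    ``coverage`` needs columns ``gene_id``, ``accession_id``,
    ``covered_fraction``; every gene x accession pair must appear exactly once
    (absence must be an explicit 0.0, not a missing row). Returns a genes x
    accessions DataFrame of 0/1 ints.
    """
    required = {"gene_id", "accession_id", "covered_fraction"}
    missing = required - set(coverage.columns)
    if missing:
        raise ValueError(f"coverage table lacks columns: {sorted(missing)}")
    frac = coverage["covered_fraction"].to_numpy(dtype=float)
    if ((frac < 0) | (frac > 1)).any():
        raise ValueError("covered fractions outside [0, 1]")
    dup = coverage.duplicated(subset=["gene_id", "accession_id"])
    if dup.any():
        pair = coverage.loc[dup, ["gene_id", "accession_id"]].iloc[0]
        raise ValueError(f"duplicate coverage row for {pair.gene_id} x {pair.accession_id}")
    wide = coverage.pivot(index="gene_id", columns="accession_id", values="covered_fraction")
    if wide.isna().any().any():
        n = int(wide.isna().to_numpy().sum())
        raise ValueError(f"{n} gene x accession pairs missing from coverage table")
    pav = (wide.to_numpy() >= threshold).astype(np.int8)
    out = pd.DataFrame(pav, index=wide.index, columns=wide.columns)
    out.index.name = "gene_id"
    out.columns.name = "accession_id"
    return out


def classify_gene_frequency(n_present: int, n_accessions: int) -> str:
    """Occurrence-frequency class from a presence count.

    Boundaries: core is exactly all accessions; softcore is frequency in
    [0.99, 1); shell is [0.01, 0.99); cloud is below 0.01 (including zero).
    """
    if n_accessions <= 0:
        raise ValueError("n_accessions must be positive")
    if not 0 <= n_present <= n_accessions:
        raise ValueError(f"n_present {n_present} outside [0, {n_accessions}]")
    if n_present == n_accessions:
        return CORE
    freq = n_present / n_accessions
    if freq >= 0.99:
        return SOFTCORE
    if freq >= 0.01:
        return SHELL
    return CLOUD


def classify_matrix(pav: pd.DataFrame, drop_absent: bool = True) -> pd.DataFrame:
    """Per-gene presence count, frequency and class for a PAV matrix.

    Genes absent from every accession are flagged ``absent_everywhere`` and,
    with ``drop_absent`` (default), removed from the table.
    """
    n_acc = pav.shape[1]
    n_present = pav.to_numpy().sum(axis=1).astype(int)
    table = pd.DataFrame(
        {
            "gene_id": pav.index,
            "n_present": n_present,
            "frequency": n_present / n_acc,
            "gene_class": [classify_gene_frequency(n, n_acc) for n in n_present],
            "absent_everywhere": n_present == 0,
        }
    ).set_index("gene_id")
    if drop_absent:
        table = table[~table["absent_everywhere"]].drop(columns="absent_everywhere")
    return table


@dataclass(frozen=True)
class GrowthCurve:
    """Pan/core gene counts under iterative random accession sampling.

    ``per_replicate`` has one row per (replicate, k) with the pan and core
    gene counts after sampling the replicate's first k accessions;
    ``summary`` holds the per-k mean and standard deviation across replicates.
    """

    per_replicate: pd.DataFrame
    summary: pd.DataFrame
    n_replicates: int
    seed: int


def pan_core_curves(pav: pd.DataFrame, n_replicates: int = 100, seed: int = 0) -> GrowthCurve:
    """Pan- and core-genome growth curves by iterative random sampling.

    Each replicate draws one random permutation of the accessions and walks it:
    pan(k) counts genes present in at least one of the first k accessions,
    core(k) counts genes present in all of them, so every replicate path is
    monotone by construction (pan non-decreasing, core non-increasing).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    mat = pav.to_numpy().astype(bool)
    n_genes, n_acc = mat.shape
    rows = []
    for rep in range(n_replicates):
        perm = rng.permutation(n_acc)
        sampled = mat[:, perm]
        pan_k = np.logical_or.accumulate(sampled, axis=1).sum(axis=0)
        core_k = np.logical_and.accumulate(sampled, axis=1).sum(axis=0)
        rows.append(
            pd.DataFrame(
                {
                    "replicate": rep,
                    "k": np.arange(1, n_acc + 1),
                    "pan": pan_k.astype(int),
                    "core": core_k.astype(int),
                }
            )
        )
    per_rep = pd.concat(rows, ignore_index=True)
    summary = (
        per_rep.groupby("k")[["pan", "core"]]
        .agg(["mean", "std"])
        .pipe(lambda d: d.set_axis(["_".join(c) for c in d.columns], axis=1))
        .reset_index()
    )
    return GrowthCurve(per_rep, summary, n_replicates, seed)
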