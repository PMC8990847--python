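"""Gene-family PAV profiling: join external family annotations with PAV classes.

Resistance-gene analogs (RGA: NBS-LRR subfamilies, RLK, RLP, TM-CC) and
terpene synthases (TPS) are annotated by external domain-detection pipelines;
this module consumes their gene -> family tables and integrates them with the
occurrence-frequency classes to produce family summaries in the
``total (variable, core)`` convention, per-family core/variable percentages,
per-chromosome gene densities, and group-sorted presence matrices for
heatmap rendering.

"Variable" means cloud + shell; "core" means core + softcore. These
definitions fix the summary-table semantics and are not configurable.
"""

from __future__ import annotations

import pandas as pd

from .pavcall import CORE_CLASSES, VARIABLE_CLASSES

__all__ = [
    "join_family_pav",
    "family_summary",
    "family_percentages",
    "chromosome_density",
    "presence_matrix_export",
]


def join_family_pav(
    annotation: pd.DataFrame, gene_classes: pd.DataFrame
) -> pd.DataFrame:
    """Attach the PAV class to each annotated gene.

    ``annotation`` needs columns ``gene_id``, ``family``, ``source``
    (reference/additional); ``gene_classes`` is the classify_matrix table.
    Every annotated gene must be classified.
    """
    ann = annotation.set_index("gene_id") if "gene_id" in annotation.columns else annotation
    missing = [g for g in ann.index if g not in gene_classes.index]
    if missing:
        raise KeyError(f"annotated genes missing from class table: {missing[:10]}")
    joined = ann.copy()
    joined["gene_class"] = gene_classes.loc[joined.index, "gene_class"]
    joined["variable"] = joined["gene_class"].isin(VARIABLE_CLASSES)
    joined["core"] = joined["gene_class"].isin(CORE_CLASSES)
    return joined


def _counts(sub: pd.DataFrame) -> tuple[int, int, int]:
    total = len(sub)
    n_var = int(sub["variable"].sum())
    return total, n_var, total - n_var


def family_summary(joined: pd.DataFrame) -> pd.DataFrame:
    """Per-family counts by source, in the ``total (variable, core)`` layout.

    One row per family plus a ``Total`` row; per source (reference,
    additional) and for their pan-genome sum, columns ``<src>_total``,
    ``<src>_variable``, ``<src>_core``. The identity
    total = variable + core holds in every cell.
    """
    rows = {}
    families = sorted(joined["family"].unique())
    for fam in families + ["Total"]:
        sub = joined if fam == "Total" else joined[joined["family"] == fam]
        row = {}
        for src in ("reference", "additional"):
            t, v, c = _counts(sub[sub["source"] == src])
            row.update({f"{src}_total": t, f"{src}_variable": v, f"{src}_core": c})
        t, v, c = _counts(sub)
        row.update({"pangenome_total": t, "pangenome_variable": v, "pangenome_core": c})
        rows[fam] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "family"
    return out


def family_percentages(summary: pd.DataFrame) -> pd.DataFrame:
    """Pan-genome core% and variable% per family, one decimal place.

    Families with zero total are reported as missing (NA).
    """
    total = summary["pangenome_total"]
    core_pct = (100.0 * summary["pangenome_core"] / total).where(total > 0).round(1)
    var_pct = (100.0 * summary["pangenome_variable"] / total).where(total > 0).round(1)
    return pd.DataFrame({"core_pct": core_pct, "variable_pct": var_pct})


def chromosome_density(
    gene_models: pd.DataFrame,
    annotation: pd.DataFrame,
    chrom_lengths: pd.Series | dict,
) -> pd.DataFrame:
    """Per-chromosome, per-family gene density in genes/Mb (two decimals).

    ``gene_models`` maps ``gene_id`` -> ``chrom``; ``chrom_lengths`` gives
    pseudomolecule lengths in bp (e.g. from a .fai index). Only genes located
    on listed chromosomes enter; a gene on an unlisted chromosome is an error.
    The ``all`` row gives the genome-wide density over the pseudomolecules.
    """
    lengths = pd.Series(chrom_lengths, dtype=float)
    gm = gene_models.set_index("gene_id") if "gene_id" in gene_models.columns else gene_models
    ann = annotation.set_index("gene_id") if "gene_id" in annotation.columns else annotation
    located = ann.join(gm["chrom"], how="inner")
    bad = sorted(set(located["chrom"]) - set(lengths.index))
    if bad:
        raise KeyError(f"chromosomes absent from length table: {bad}")
    families = sorted(ann["family"].unique())
    counts = (
        located.groupby(["chrom", "family"]).size().unstack(fill_value=0)
        .reindex(index=lengths.index, columns=families, fill_value=0)
    )
    dens = counts.div(lengths / 1e6, axis=0)
    dens["total"] = counts.sum(axis=1) / (lengths / 1e6)
    all_row = counts.sum(axis=0) / (lengths.sum() / 1e6)
    all_row["total"] = counts.to_numpy().sum() / (lengths.sum() / 1e6)
    dens.loc["all"] = all_row
    return dens.round(2)


def presence_matrix_export(
    pav: pd.DataFrame,
    gene_subset: pd.DataFrame,
    groups: pd.Series | pd.DataFrame,
    gene_classes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Ordered 0/1 matrix of variable genes for heatmap rendering.

    ``gene_subset`` carries ``gene_id`` and ``family`` for the genes to
    export; rows come out family-sorted and columns group-sorted (stable
    within group). When ``gene_classes`` is given, non-variable genes in the
    subset are dropped with a warning rather than exported.
    """
    import warnings

    sub = gene_subset.set_index("gene_id") if "gene_id" in gene_subset.columns else gene_subset
    genes = list(sub.index)
    if gene_classes is not None:
        non_var = [
            g
            for g in genes
            if g in gene_classes.index
            and gene_classes.loc[g, "gene_class"] not in VARIABLE_CLASSES
        ]
        if non_var:
            warnings.warn(
                f"excluding {len(non_var)} non-variable genes from presence export",
                stacklevel=2,
            )
            genes = [g for g in genes if g not in set(non_var)]
    if isinstance(groups, pd.DataFrame):
        groups = groups.set_index("accession_id")["group"]
    gene_order = sub.loc[genes].sort_values("family").index
    acc_order = sorted(pav.columns, key=lambda a: (str(groups.get(a, "zzz")), str(a)))
    return pav.loc[gene_order, acc_order]
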