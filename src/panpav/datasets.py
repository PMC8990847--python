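"""Published per-family count tables usable as inputs.

The melon pan-genome RGA and TPS family counts are printed in the
``total (variable, core)`` convention per family and per source (reference
pseudomolecules vs pan-genome additional contigs). They are shipped here as
data so the family-profiling summaries can be exercised and checked without
the underlying 297-accession read data. :func:`expand_counts_to_genes`
inflates a count table into synthetic per-gene annotation and class tables
(one placeholder gene per counted unit: variable genes as shell, core genes
as core), which aggregate back to the original counts exactly.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["melon_rga_counts", "melon_tps_counts", "expand_counts_to_genes"]

# family: (reference (variable, core), additional (variable, core))
_RGA_COUNTS = {
    "CN": ((1, 2), (4, 0)),
    "CNL": ((3, 12), (5, 0)),
    "NBS": ((6, 2), (5, 0)),
    "NL": ((8, 13), (8, 0)),
    "RLK": ((13, 387), (11, 0)),
    "RLP": ((8, 38), (10, 0)),
    "TM-CC": ((5, 130), (6, 0)),
    "TN": ((0, 1), (0, 0)),
    "TNL": ((5, 12), (3, 0)),
    "TX": ((1, 4), (2, 0)),
    "OTHER": ((1, 2), (1, 0)),
}

_TPS_COUNTS = {"TPS": ((8, 18), (1, 0))}


def _counts_frame(table: dict) -> pd.DataFrame:
    rows = []
    for fam, ((rv, rc), (av, ac)) in table.items():
        rows.append(
            {
                "family": fam,
                "reference_variable": rv,
                "reference_core": rc,
                "additional_variable": av,
                "additional_core": ac,
            }
        )
    return pd.DataFrame(rows).set_index("family")


def melon_rga_counts() -> pd.DataFrame:
    """Resistance-gene-analog candidate counts in the melon pan-genome,
    per subfamily and source, split into variable and core genes."""
    return _counts_frame(_RGA_COUNTS)


def melon_tps_counts() -> pd.DataFrame:
    """Terpene-synthase counts in the melon pan-genome by source."""
    return _counts_frame(_TPS_COUNTS)


def expand_counts_to_genes(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inflate a per-family count table into per-gene annotation + class tables.

    Synthetic placeholder genes (``<family>_<source>_<class>_<i>``) are
    generated so that ``family_summary(join_family_pav(...))`` reproduces the
    counts. Variable genes are labelled shell, core genes core.
    """
    ann_rows, cls_rows = [], []
    for fam, row in counts.iterrows():
        for src in ("reference", "additional"):
            for cls_label, gene_class, n in (
                ("variable", "shell", row[f"{src}_variable"]),
                ("core", "core", row[f"{src}_core"]),
            ):
                for i in range(int(n)):
                    gid = f"{fam}_{src}_{cls_label}_{i}"
                    ann_rows.append({"gene_id": gid, "family": fam, "source": src})
                    cls_rows.append({"gene_id": gid, "gene_class": gene_class})
    annotation = pd.DataFrame(ann_rows)
    classes = pd.DataFrame(cls_rows).set_index("gene_id")
    return annotation, classes
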