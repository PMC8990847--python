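"""Group-frequency selection scan over variable genes.

For each comparison of accession groups (improved vs landrace within a
subspecies, or *ssp. melo* vs *ssp. agrestis* within a breeding stage) the scan
computes per-gene presence frequencies, a two-sided Fisher exact p-value on
the presence counts, Benjamini–Hochberg FDR across the tested genes, and a
frequency fold change. A gene is *selected* when fold change > 2 and
FDR < 0.001; the direction of the frequency difference determines the call
(favorable/unfavorable for improvement comparisons, highly/lowly in melo for
subspecies comparisons). Only variable (shell + cloud) genes are tested —
core and softcore genes cannot differ between groups by definition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .pavcall import VARIABLE_CLASSES

__all__ = [
    "DEFAULT_COMPARISONS",
    "EXCLUDED_GROUPS",
    "group_frequencies",
    "fisher_exact_two_sided",
    "bh_fdr",
    "call_selected_genes",
    "selection_scan",
    "term_enrichment",
]

#: Comparisons run by default: improvement within each subspecies, and
#: melo-vs-agrestis within each breeding stage.
DEFAULT_COMPARISONS = (
    ("IMP_A", "LDR_A"),
    ("IMP_M", "LDR_M"),
    ("IMP_M", "IMP_A"),
    ("LDR_M", "LDR_A"),
)

#: Groups too small for frequency comparisons, excluded by default.
EXCLUDED_GROUPS = frozenset({"WT", "ND", "Putative_Feral"})


def group_frequencies(
    pav: pd.DataFrame, groups: pd.Series | pd.DataFrame
) -> pd.DataFrame:
    """Per-gene presence counts and frequencies in each accession group.

    ``groups`` maps accession id -> group label (a Series, or a DataFrame with
    ``accession_id`` and ``group`` columns). Every accession in the PAV matrix
    must carry a label. Returns one row per gene with columns
    ``n_present_<g>``, ``n_total_<g>``, ``freq_<g>`` for each group g.
    """
    if isinstance(groups, pd.DataFrame):
        groups = groups.set_index("accession_id")["group"]
    unlabelled = [a for a in pav.columns if a not in groups.index]
    if unlabelled:
        raise ValueError(f"accessions without group label: {unlabelled[:10]}")
    labels = groups.loc[pav.columns]
    out = pd.DataFrame(index=pav.index)
    out.index.name = "gene_id"
    for g in labels.unique():
        cols = pav.columns[labels.to_numpy() == g]
        n_present = pav[cols].to_numpy().sum(axis=1).astype(int)
        out[f"n_present_{g}"] = n_present
        out[f"n_total_{g}"] = len(cols)
        out[f"freq_{g}"] = n_present / len(cols)
    return out


def _log_hypergeom_pmf(k: np.ndarray, n1: int, n2: int, m: int) -> np.ndarray:
    """log P(K = k) for K ~ Hypergeom(drawing m from n1 'present-capable' of n1+n2)."""

    def lchoose(n, r):
        return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)

    return lchoose(n1, k) + lchoose(n2, m - k) - lchoose(n1 + n2, m)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Enumerates, with the margins fixed, every admissible table and sums the
    hypergeometric probabilities of all tables whose point probability does
    not exceed that of the observed table (with a 1e-7 relative tolerance on
    the comparison, the usual guard against floating-point ties). Any zero
    margin makes the table degenerate and returns p = 1.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("cell counts must be non-negative integers")
    n1, n2 = a + b, c + d  # row margins
    m = a + c  # first column margin
    if n1 == 0 or n2 == 0 or m == 0 or (b + d) == 0:
        return 1.0
    lo, hi = max(0, m - n2), min(m, n1)
    support = np.arange(lo, hi + 1)
    logp = _log_hypergeom_pmf(support, n1, n2, m)
    log_obs = _log_hypergeom_pmf(np.array([a]), n1, n2, m)[0]
    keep = logp <= log_obs + 1e-7
    p = float(np.exp(logp[keep]).sum())
    return min(p, 1.0)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment, input order preserved.

    q_(i) = min over ranks j >= i of (m * p_(j) / j), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _direction_labels(group_a: str, group_b: str) -> tuple[str, str]:
    """Call labels for a gene with higher frequency in group_a / in group_b."""

    def stage(g):
        return g.split("_")[0]

    def subspecies(g):
        return g.split("_")[-1]

    if stage(group_a) != stage(group_b) and {stage(group_a), stage(group_b)} == {"IMP", "LDR"}:
        # improvement comparison: favorable = higher frequency in IMP
        hi_a = "favorable" if stage(group_a) == "IMP" else "unfavorable"
        hi_b = "unfavorable" if stage(group_a) == "IMP" else "favorable"
        return hi_a, hi_b
    if subspecies(group_a) != subspecies(group_b) and {subspecies(group_a), subspecies(group_b)} == {"M", "A"}:
        hi_a = "highly_in_melo" if subspecies(group_a) == "M" else "lowly_in_melo"
        hi_b = "lowly_in_melo" if subspecies(group_a) == "M" else "highly_in_melo"
        return hi_a, hi_b
    return f"higher_in_{group_a}", f"higher_in_{group_b}"


def call_selected_genes(
    freqs: pd.DataFrame,
    comparison: tuple[str, str],
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.001,
) -> pd.DataFrame:
    """Selection calls for one group comparison.

    ``freqs`` is a :func:`group_frequencies` table restricted to the genes to
    be tested (variable genes). Genes absent from both groups are excluded
    from testing. Fold change is ``max(f_a, f_b) / min(f_a, f_b)``,
    infinite when exactly one frequency is zero. The FDR family is the set of
    genes tested in this comparison.
    """
    group_a, group_b = comparison
    for g in comparison:
        if f"n_present_{g}" not in freqs.columns:
            raise ValueError(f"group {g!r} not present in frequency table")
    pa = freqs[f"n_present_{group_a}"].to_numpy(int)
    ta = freqs[f"n_total_{group_a}"].to_numpy(int)
    pb = freqs[f"n_present_{group_b}"].to_numpy(int)
    tb = freqs[f"n_total_{group_b}"].to_numpy(int)
    testable = (pa + pb) > 0
    res = pd.DataFrame(index=freqs.index[testable])
    res.index.name = "gene_id"
    pa, ta, pb, tb = pa[testable], ta[testable], pb[testable], tb[testable]
    fa, fb = pa / ta, pb / tb
    res["comparison"] = f"{group_a}_vs_{group_b}"
    res["freq_a"], res["freq_b"] = fa, fb
    lo = np.minimum(fa, fb)
    hi = np.maximum(fa, fb)
    with np.errstate(divide="ignore"):
        res["fold_change"] = np.where(lo > 0, hi / np.where(lo > 0, lo, 1.0), np.inf)
    res["p_value"] = [
        fisher_exact_two_sided(int(a_), int(ta_ - a_), int(b_), int(tb_ - b_))
        for a_, ta_, b_, tb_ in zip(pa, ta, pb, tb)
    ]
    res["fdr"] = bh_fdr(res["p_value"].to_numpy())
    label_a, label_b = _direction_labels(group_a, group_b)
    selected = (res["fold_change"] > fc_threshold) & (res["fdr"] < fdr_threshold)
    res["call"] = np.where(
        selected, np.where(fa > fb, label_a, label_b), "ns"
    )
    return res


def selection_scan(
    pav: pd.DataFrame,
    groups: pd.Series | pd.DataFrame,
    gene_classes: pd.DataFrame,
    comparisons=DEFAULT_COMPARISONS,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.001,
) -> dict[str, pd.DataFrame]:
    """Run :func:`call_selected_genes` for each comparison over variable genes.

    ``gene_classes`` is the :func:`panpav.pavcall.classify_matrix` table; only
    shell and cloud genes enter the scan. Returns a dict keyed by
    ``"<A>_vs_<B>"``.
    """
    variable = gene_classes.index[gene_classes["gene_class"].isin(VARIABLE_CLASSES)]
    freqs = group_frequencies(pav.loc[pav.index.intersection(variable)], groups)
    return {
        f"{a}_vs_{b}": call_selected_genes(freqs, (a, b), fc_threshold, fdr_threshold)
        for a, b in comparisons
    }


def term_enrichment(
    selected_genes,
    universe,
    term_map: pd.DataFrame,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """One-sided over-representation test of annotation terms in a gene set.

    ``term_map`` has columns ``term_id``, ``gene_id`` (and optionally
    ``term_name``). For each term with K genes in the universe of size N, and
    k selected genes of the term among n selected genes, the p-value is the
    upper hypergeometric tail P(X >= k); BH FDR is computed across terms and
    ``enriched`` flags FDR below ``fdr_threshold``.
    """
    from scipy.stats import hypergeom

    selected = set(selected_genes)
    universe = set(universe)
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    if not selected:
        return pd.DataFrame(
            columns=["term_id", "term_name", "k", "K", "n", "N", "p_value", "fdr", "enriched"]
        )
    N, n = len(universe), len(selected)
    rows = []
    names = {}
    if "term_name" in term_map.columns:
        names = term_map.drop_duplicates("term_id").set_index("term_id")["term_name"].to_dict()
    for term, sub in term_map.groupby("term_id"):
        term_genes = set(sub["gene_id"]) & universe
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & selected)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": term, "term_name": names.get(term, ""), "k": k, "K": K, "n": n, "N": N, "p_value": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if out.empty:
        out["fdr"] = []
        out["enriched"] = []
        return out
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    out["enriched"] = out["fdr"] < fdr_threshold
    return out.sort_values("p_value").reset_index(drop=True)
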