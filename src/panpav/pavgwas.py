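"""Gene-PAV genome-wide association on shell genes.

Gene presence/absence is the genotype: for each shell gene, a quantitative
trait is regressed on the presence indicator plus optional population-structure
covariates (principal components of the centered PAV matrix), and the presence
coefficient is tested with a two-sided t-test. Genome-wide significance uses
the Bonferroni threshold alpha / m over the m genes actually tested.

The scan is an ordinary fixed-effect least-squares model per gene, fitted via
the Frisch–Waugh–Lovell decomposition (trait and genotype are residualized on
the shared covariates once, then each gene needs only a simple regression),
which is algebraically identical to the full multiple regression for the
presence coefficient and its standard error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .selscan import group_frequencies

__all__ = [
    "bonferroni_threshold",
    "pav_pcs",
    "association_scan",
    "hit_report",
]


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Genome-wide significance threshold alpha / m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"number of tests m must be >= 1, got {m}")
    return alpha / m


def pav_pcs(pav: pd.DataFrame, k: int) -> pd.DataFrame:
    """Top-k principal components of the column-centered presence matrix.

    Rows are accessions, columns PC1..PCk (scores). The sign of each component
    is fixed so that its largest-magnitude gene loading is positive, making
    the decomposition deterministic. ``k=0`` returns an empty covariate frame.
    """
    acc = pav.columns
    if k == 0:
        return pd.DataFrame(index=acc)
    X = pav.to_numpy(dtype=float).T  # accessions x genes
    if k >= min(X.shape):
        raise ValueError(f"k={k} must be < min(n_accessions, n_genes)={min(X.shape)}")
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        raise ValueError("PAV matrix is constant; no variance for PCA")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :k] * S[:k]
    for j in range(k):
        i_max = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i_max] < 0:
            scores[:, j] *= -1.0
    return pd.DataFrame(scores, index=acc, columns=[f"PC{j + 1}" for j in range(k)])


@dataclass(frozen=True)
class ScanResult:
    """Association-scan output: per-gene results and the exclusion log."""

    results: pd.DataFrame
    excluded: pd.DataFrame
    threshold: float
    n_tested: int


def association_scan(
    pav: pd.DataFrame,
    trait: pd.Series,
    covariates: pd.DataFrame | None = None,
    min_carriers: int = 5,
    alpha: float = 0.05,
) -> ScanResult:
    """Single-marker least-squares scan of a trait on gene presence.

    ``pav`` is the shell-gene subset of the PAV matrix (genes x accessions);
    ``trait`` maps accession -> value, missing values allowed (those
    accessions are dropped). Genes with fewer than ``min_carriers`` accessions
    in either presence class are excluded and logged. The significance
    threshold is ``alpha`` divided by the number of genes tested.
    """
    trait = trait.reindex(pav.columns)
    mask = trait.notna().to_numpy()
    if mask.sum() < 3:
        raise ValueError("need at least 3 accessions with non-missing trait values")
    acc = pav.columns[mask]
    y = trait.to_numpy(dtype=float)[mask]
    G = pav.to_numpy(dtype=float)[:, mask]  # genes x n
    n = y.size

    if covariates is not None and covariates.shape[1] > 0:
        C = covariates.reindex(acc).to_numpy(dtype=float)
        if np.isnan(C).any():
            raise ValueError("covariates missing for some phenotyped accessions")
        Z = np.column_stack([np.ones(n), C])
    else:
        Z = np.ones((n, 1))
    q = Z.shape[1]
    # residualize trait and genotypes on the shared covariates (FWL)
    Q, _ = np.linalg.qr(Z)
    ry = y - Q @ (Q.T @ y)
    RG = G - (G @ Q) @ Q.T

    carriers = G.sum(axis=1)
    df = n - q - 1
    usable = (carriers >= min_carriers) & ((n - carriers) >= min_carriers)
    reasons = np.where(usable, "", "min_carriers")
    if df <= 0:
        usable[:] = False
        reasons = np.full(len(G), "insufficient_accessions")

    sxx = (RG**2).sum(axis=1)
    degenerate = usable & (sxx <= 1e-12)
    reasons = np.where(degenerate, "no_residual_variance", reasons)
    usable &= ~degenerate

    effect = np.full(len(G), np.nan)
    se = np.full(len(G), np.nan)
    pvals = np.full(len(G), np.nan)
    idx = np.flatnonzero(usable)
    if idx.size:
        sxy = RG[idx] @ ry
        beta = sxy / sxx[idx]
        rss = (ry @ ry) - beta * sxy
        rss = np.maximum(rss, 0.0)
        sigma2 = rss / df
        se_b = np.sqrt(sigma2 / sxx[idx])
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se_b > 0, beta / se_b, np.inf * np.sign(beta))
        p = 2.0 * stats.t.sf(np.abs(tstat), df)
        effect[idx], se[idx], pvals[idx] = beta, se_b, np.clip(p, 0.0, 1.0)

    m = int(idx.size)
    threshold = bonferroni_threshold(alpha, m) if m else np.nan
    results = pd.DataFrame(
        {
            "gene_id": pav.index[usable],
            "effect": effect[usable],
            "se": se[usable],
            "p_value": pvals[usable],
            "n_used": n,
            "significant": pvals[usable] < threshold,
        }
    ).set_index("gene_id")
    excluded = pd.DataFrame(
        {"gene_id": pav.index[~usable], "reason": reasons[~usable]}
    ).set_index("gene_id")
    return ScanResult(results, excluded, float(threshold), m)


def hit_report(
    scan: ScanResult, pav: pd.DataFrame, groups: pd.Series | pd.DataFrame
) -> pd.DataFrame:
    """Per-group presence frequencies for each significant gene.

    Frequencies come from :func:`panpav.selscan.group_frequencies`, so they
    agree exactly with the selection scan's. Empty when there are no hits.
    """
    hits = scan.results.index[scan.results["significant"]]
    if len(hits) == 0:
        return pd.DataFrame()
    freqs = group_frequencies(pav.loc[hits], groups)
    return freqs[[c for c in freqs.columns if c.startswith("freq_")]]
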