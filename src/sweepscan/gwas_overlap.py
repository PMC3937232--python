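"""Mixed-model GWAS (EMMAX approximation) and the permutation test for
overlap between GWAS hits and selection-candidate windows.

The model is ``y = mu + s b + u + e`` with ``u ~ (0, sigma_a^2 G)`` and a
VanRaden genomic relationship matrix ``G``.  Variance components are
REML-estimated once under the null (no SNP) via the eigendecomposition of
G and a 1-D search in the variance ratio, then every SNP is tested by
generalized least squares with the covariance held fixed — the EMMAX
approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class GRM:
    """Realized genomic relationship matrix from centered allele dosages."""

    matrix: np.ndarray
    allele_freq: np.ndarray
    scale: float  # sum of 2 p_k (1 - p_k)


def genomic_relationship_matrix(dosages: np.ndarray) -> GRM:
    """VanRaden GRM: ``G = Z Z' / sum(2 p q)`` with ``Z`` the dosage matrix
    centered by ``2 p``; monomorphic SNPs are excluded."""
    D = np.asarray(dosages, dtype=float)
    p = D.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all SNPs monomorphic; cannot build a GRM")
    D = D[:, poly]
    p = p[poly]
    Z = D - 2.0 * p
    scale = float((2.0 * p * (1.0 - p)).sum())
    G = (Z @ Z.T) / scale
    return GRM(G, p, scale)


@dataclass
class GwasResult:
    table: pd.DataFrame  # chrom, pos, beta, se, p per SNP
    sigma2_a: float
    sigma2_e: float
    n: int
    boundary: bool = False  # sigma2_a hit the zero boundary


def _reml_neg_loglik(log_lambda: float, eigvals: np.ndarray, yr: np.ndarray) -> float:
    """Negative REML log-likelihood of the null model in log variance ratio
    ``lambda = sigma_a^2 / sigma_e^2`` after rotation by G's eigenvectors.

    ``yr`` are the rotated residuals of y on the rotated intercept.
    """
    lam = np.exp(log_lambda)
    w = lam * eigvals + 1.0  # V = sigma_e^2 (lam G + I)
    n = len(yr)
    # profile sigma_e^2: hat = sum(yr^2 / w) / (n - 1)  (1 fixed effect)
    rss = float((yr**2 / w).sum())
    sigma2e = rss / (n - 1)
    ll = -0.5 * ((n - 1) * np.log(sigma2e) + np.log(w).sum() + (n - 1))
    return -ll


def emmax_scan(
    y: np.ndarray,
    dosages: np.ndarray,
    grm: GRM,
    positions: pd.DataFrame | None = None,
) -> GwasResult:
    """Per-SNP mixed-model association scan with null variance components.

    ``positions`` (chrom, pos per SNP) is carried into the result table
    when given.  SNPs that are monomorphic get NaN rows.
    """
    y = np.asarray(y, dtype=float)
    D = np.asarray(dosages, dtype=float)
    n = len(y)
    if D.shape[0] != n:
        raise ValueError("phenotype and dosage dimensions disagree")
    if y.var() == 0:
        raise ValueError("phenotype has zero variance")

    eigvals, U = np.linalg.eigh(grm.matrix)
    eigvals = np.maximum(eigvals, 0.0)
    yr_full = U.T @ y
    ones_r = U.T @ np.ones(n)

    def rotated_resid(lam: float) -> np.ndarray:
        w = lam * eigvals + 1.0
        b0 = float((ones_r * yr_full / w).sum() / (ones_r**2 / w).sum())
        return yr_full - b0 * ones_r

    def objective(ll: float) -> float:
        return _reml_neg_loglik(ll, eigvals, rotated_resid(np.exp(ll)))

    res = optimize.minimize_scalar(objective, bounds=(-10.0, 10.0), method="bounded")
    if not res.success:
        raise RuntimeError(f"REML optimization failed: {res.message}")
    lam = float(np.exp(res.x))
    boundary = res.x <= -10.0 + 1e-6
    if boundary:
        lam = 0.0
    w = lam * eigvals + 1.0
    yr = rotated_resid(lam)
    sigma2e = float((yr**2 / w).sum() / (n - 1))
    sigma2a = lam * sigma2e

    # GLS of y on [1, dosage] in the rotated basis with diagonal weights
    wi = 1.0 / w
    Dr = U.T @ D
    rows = []
    for j in range(D.shape[1]):
        x = Dr[:, j]
        if D[:, j].var() == 0:
            rows.append((np.nan, np.nan, np.nan))
            continue
        X = np.column_stack([ones_r, x])
        XtWX = X.T @ (wi[:, None] * X)
        XtWy = X.T @ (wi * yr_full)
        try:
            cov = np.linalg.inv(XtWX)
        except np.linalg.LinAlgError:
            rows.append((np.nan, np.nan, np.nan))
            continue
        bhat = cov @ XtWy
        resid = yr_full - X @ bhat
        df = n - 2
        s2 = float((resid**2 * wi).sum() / df)
        se = float(np.sqrt(s2 * cov[1, 1]))
        beta = float(bhat[1])
        t = beta / se
        p = float(2.0 * stats.t.sf(abs(t), df))
        rows.append((beta, se, max(p, np.finfo(float).tiny)))
    tab = pd.DataFrame(rows, columns=["beta", "se", "p"])
    if positions is not None:
        tab.insert(0, "pos", positions["pos"].to_numpy())
        tab.insert(0, "chrom", positions["chrom"].to_numpy())
    return GwasResult(tab, sigma2a, sigma2e, n, boundary)


def snp_variance_explained(beta: float, p: float, var_y: float) -> float:
    """Fraction of phenotypic variance explained by one SNP: 2 p q beta^2 / var_y."""
    if var_y <= 0:
        raise ValueError("var_y must be positive")
    return float(2.0 * p * (1.0 - p) * beta**2 / var_y)


@dataclass
class OverlapResult:
    observed_overlap: int
    perm_counts: np.ndarray
    emp_p: float
    n_perm: int
    gwas_threshold: float
    selection_percentile: float
    unit: str


def overlap_permutation_test(
    gwas: pd.DataFrame,
    selection: pd.DataFrame,
    gwas_threshold: float = 1e-6,
    selection_percentile: float = 0.99,
    unit: str = "snp",
    n_perm: int = 10_000,
    seed: int = 0,
    permute_selection: bool = False,
) -> OverlapResult:
    """Permutation test for excess overlap of GWAS hits with top windows.

    ``gwas`` holds per-SNP (chrom, pos, p); ``selection`` is a window track
    with (chrom, start, end, emp_p).  A unit is a SNP, or a window holding
    at least one GWAS SNP (its p being the minimum over contained SNPs).
    ``observed_overlap`` counts units with GWAS p below the threshold that
    sit in a top-``1 - selection_percentile`` window; the null shuffles the
    GWAS p-values across units (or the candidate labels, with
    ``permute_selection``) and ``emp_p = (#{perm >= obs} + 1) / (n_perm + 1)``.
    """
    if unit not in ("snp", "window"):
        raise ValueError("unit must be 'snp' or 'window'")
    rng = np.random.default_rng(seed)
    sel = selection.dropna(subset=["emp_p"])
    tail = 1.0 - selection_percentile
    cand = sel[sel["emp_p"] <= tail + 1e-12]

    # map each GWAS SNP to its (first) containing window
    win_of = np.full(len(gwas), -1, dtype=np.int64)
    sel = sel.reset_index(drop=True)
    for chrom, sub in sel.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        snps = np.flatnonzero((gwas["chrom"] == chrom).to_numpy())
        pos = gwas["pos"].to_numpy()[snps]
        k = np.searchsorted(starts, pos, side="right") - 1
        ok = (k >= 0) & (pos < ends[np.clip(k, 0, None)])
        win_of[snps[ok]] = sub.index.to_numpy()[k[ok]]

    cand_windows = set(cand.index)
    if unit == "snp":
        pvals = gwas["p"].to_numpy(dtype=float)
        in_cand = np.isin(win_of, list(cand_windows))
    else:
        frame = pd.DataFrame({"w": win_of, "p": gwas["p"].to_numpy(dtype=float)})
        frame = frame[frame["w"] >= 0]
        agg = frame.groupby("w")["p"].min()
        pvals = agg.to_numpy()
        in_cand = np.isin(agg.index.to_numpy(), list(cand_windows))

    hits = pvals < gwas_threshold
    observed = int((hits & in_cand).sum())
    if hits.sum() == 0:
        raise ValueError("no GWAS association passes the threshold; nothing to test")

    perm_counts = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        if permute_selection:
            perm_counts[i] = int((hits & rng.permutation(in_cand)).sum())
        else:
            perm_counts[i] = int((rng.permutation(hits) & in_cand).sum())
    emp_p = float(((perm_counts >= observed).sum() + 1) / (n_perm + 1))
    return OverlapResult(
        observed, perm_counts, emp_p, n_perm, gwas_threshold, selection_percentile, unit
    )
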