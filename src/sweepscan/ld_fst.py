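"""LD-decay profiling (r-squared vs distance) and two-population F_ST scans.

r2 comes from the 2x2 haplotype contingency table:
``D = p_AB - p_A p_B`` and ``r2 = D^2 / (p_A q_A p_B q_B)``.

F_ST uses the two-population variance-components estimator on haploid
allele counts,

    MSG = sum_i n_i p_i (1 - p_i) / sum_i (n_i - 1)
    MSP = sum_i n_i (p_i - p_bar)^2 / (r - 1)
    n_c = (sum n_i - sum n_i^2 / sum n_i) / (r - 1)
    F_ST = (MSP - MSG) / (MSP + (n_c - 1) MSG)

with r = 2 populations and ``p_bar`` the count-weighted mean frequency.
Negative estimates are reported as-is by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .core_data import MISSING, HaplotypePanel

DEFAULT_MAX_DIST = 250_000
DEFAULT_PAIR_CAP = 10_000


def haplotype_r2(panel: HaplotypePanel, site_i: int, site_j: int) -> float:
    """Squared haplotype correlation between two sites; NaN when either
    site is monomorphic among jointly non-missing haplotypes."""
    a = panel.haplotypes[:, site_i]
    b = panel.haplotypes[:, site_j]
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok].astype(float), b[ok].astype(float)
    if len(a) < 2:
        return np.nan
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return np.nan
    d = (a * b).mean() - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def _pairwise_r2(panel: HaplotypePanel, idx: np.ndarray, max_dist: int) -> pd.DataFrame:
    """r2 and bp distance for all pairs among ``idx`` closer than max_dist."""
    H = panel.haplotypes[:, idx].astype(float)
    H[panel.haplotypes[:, idx] == MISSING] = np.nan
    pos = panel.positions()[idx]
    order = np.argsort(pos, kind="mergesort")
    H, pos = H[:, order], pos[order]
    p = np.nanmean(H, axis=0)
    keep = (p > 0) & (p < 1)
    H, pos, p = H[:, keep], pos[keep], p[keep]
    m = H.shape[1]
    dists, r2s = [], []
    for i in range(m):
        hi = np.searchsorted(pos, pos[i] + max_dist, side="right")
        for j in range(i + 1, hi):
            ok = ~(np.isnan(H[:, i]) | np.isnan(H[:, j]))
            if ok.sum() < 2:
                continue
            a, b = H[ok, i], H[ok, j]
            pa, pb = a.mean(), b.mean()
            if pa in (0.0, 1.0) or pb in (0.0, 1.0):
                continue
            d = (a * b).mean() - pa * pb
            r2s.append(d * d / (pa * (1 - pa) * pb * (1 - pb)))
            dists.append(pos[j] - pos[i])
    return pd.DataFrame({"dist": np.array(dists, dtype=np.int64), "r2": r2s})


def default_bins(max_dist: int = DEFAULT_MAX_DIST) -> np.ndarray:
    """20 equal bins over (0, 100 kb] plus coarse bins out to ``max_dist``."""
    edges = list(np.linspace(0, 100_000, 21))
    e = 100_000
    while e < max_dist:
        e = min(e + 50_000, max_dist)
        edges.append(e)
    return np.array(edges, dtype=np.int64)


@dataclass
class LDCurve:
    bins: np.ndarray  # bin edges, len k+1
    mean_r2: np.ndarray
    sd_r2: np.ndarray
    n_pairs: np.ndarray
    pair_samples: list[np.ndarray] = field(default_factory=list)  # per-bin r2 values
    seed: int = 0

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.bins[:-1],
                "bin_hi": self.bins[1:],
                "mean_r2": self.mean_r2,
                "sd_r2": self.sd_r2,
                "n_pairs": self.n_pairs,
            }
        )


def ld_decay_profile(
    panel: HaplotypePanel,
    segments: list[tuple[str, int, int]] | None = None,
    n_snps_sample: int | None = None,
    bins: np.ndarray | None = None,
    max_dist: int = DEFAULT_MAX_DIST,
    seed: int = 0,
    pair_cap: int = DEFAULT_PAIR_CAP,
) -> LDCurve:
    """Binned r2-vs-distance curve from randomly sampled SNPs per segment.

    ``segments`` defaults to one segment spanning each chromosome.  Within
    each segment up to ``n_snps_sample`` sites are drawn (seeded), all
    within-segment pairs closer than ``max_dist`` are computed, and pairs
    are pooled into distance bins; each bin keeps at most ``pair_cap``
    pairs (seeded downsampling).
    """
    rng = np.random.default_rng(seed)
    if bins is None:
        bins = default_bins(max_dist)
    sites = panel.sites
    if segments is None:
        segments = [
            (c, int(sub["pos"].min()), int(sub["pos"].max()) + 1)
            for c, sub in sites.groupby("chrom", sort=False)
        ]
    pieces = []
    for chrom, lo, hi in segments:
        inseg = np.flatnonzero(
            (sites["chrom"] == chrom).to_numpy()
            & (sites["pos"].to_numpy() >= lo)
            & (sites["pos"].to_numpy() < hi)
        )
        if inseg.size < 2:
            import warnings

            warnings.warn(f"segment {chrom}:{lo}-{hi} holds fewer than 2 sites; skipped")
            continue
        if n_snps_sample is not None and inseg.size > n_snps_sample:
            inseg = np.sort(rng.choice(inseg, n_snps_sample, replace=False))
        pieces.append(_pairwise_r2(panel, inseg, max_dist))
    if not pieces:
        raise ValueError("no usable segment")
    pairs = pd.concat(pieces, ignore_index=True)

    k = len(bins) - 1
    mean = np.full(k, np.nan)
    sd = np.full(k, np.nan)
    n = np.zeros(k, dtype=np.int64)
    samples: list[np.ndarray] = []
    which = np.digitize(pairs["dist"].to_numpy(), bins[1:-1], right=True)
    for b in range(k):
        vals = pairs.loc[which == b, "r2"].to_numpy()
        if len(vals) > pair_cap:
            vals = rng.choice(vals, pair_cap, replace=False)
        samples.append(vals)
        n[b] = len(vals)
        if len(vals):
            mean[b] = vals.mean()
            sd[b] = vals.std(ddof=1) if len(vals) > 1 else 0.0
    return LDCurve(bins, mean, sd, n, samples, seed)


def compare_ld_bins(curve_a: LDCurve, curve_b: LDCurve) -> pd.DataFrame:
    """Per-bin Mann-Whitney comparison of the underlying pair-level r2
    samples of two LD curves; bins empty in either curve are skipped."""
    rows = []
    k = min(len(curve_a.pair_samples), len(curve_b.pair_samples))
    for b in range(k):
        va, vb = curve_a.pair_samples[b], curve_b.pair_samples[b]
        if len(va) == 0 or len(vb) == 0:
            continue
        stat, p = mannwhitneyu(va, vb, alternative="two-sided")
        rows.append(
            {
                "bin_lo": curve_a.bins[b],
                "bin_hi": curve_a.bins[b + 1],
                "mean_a": float(np.mean(va)),
                "mean_b": float(np.mean(vb)),
                "statistic": float(stat),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


def fst_site(n1: int, c1: int, n2: int, c2: int) -> float:
    """Variance-components F_ST for one site from haploid allele counts
    (``c`` copies of the allele among ``n`` sampled haplotypes)."""
    p1, p2 = c1 / n1, c2 / n2
    if (c1 + c2) == 0 or (c1 + c2) == (n1 + n2):
        return np.nan
    nt = n1 + n2
    pbar = (c1 + c2) / nt
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / ((n1 - 1) + (n2 - 1))
    msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2  # r - 1 = 1
    nc = nt - (n1 * n1 + n2 * n2) / nt
    denom = msp + (nc - 1) * msg
    if denom == 0:
        return np.nan
    return float((msp - msg) / denom)


def fst_scan(
    pop1_counts: pd.DataFrame,
    pop2_counts: pd.DataFrame,
    sliding_k: int = 3,
    top_fraction: float = 0.001,
    clip_negative: bool = False,
) -> pd.DataFrame:
    """Single-SNP and k-SNP sliding F_ST between two populations.

    Inputs are per-site frames with columns (chrom, pos, count, n) of
    derived/alt copies and sampled haplotypes, joined on (chrom, pos).
    Sliding values are means of ``sliding_k`` consecutive single-SNP
    values; the returned frame also records the ``1 - top_fraction``
    quantile of the sliding values as ``cutoff``.
    """
    merged = pop1_counts.merge(
        pop2_counts, on=["chrom", "pos"], suffixes=("_1", "_2"), how="inner"
    )
    fst = np.array(
        [
            fst_site(int(r.n_1), int(r.count_1), int(r.n_2), int(r.count_2))
            for r in merged.itertuples()
        ]
    )
    if clip_negative:
        fst = np.where(np.isnan(fst), np.nan, np.maximum(fst, 0.0))
    out = merged[["chrom", "pos"]].copy()
    out["fst"] = fst
    out = out.dropna(subset=["fst"]).reset_index(drop=True)
    sliding = (
        out.groupby("chrom", sort=False)["fst"]
        .rolling(sliding_k, center=True)
        .mean()
        .reset_index(level=0, drop=True)
    )
    out["fst_sliding"] = sliding
    valid = out["fst_sliding"].dropna()
    out.attrs["cutoff"] = float(valid.quantile(1.0 - top_fraction)) if len(valid) else np.nan
    return out


def panel_allele_counts(panel: HaplotypePanel) -> pd.DataFrame:
    """Per-site (chrom, pos, count, n) frame for F_ST input."""
    ones, total = panel.allele_counts()
    return pd.DataFrame(
        {
            "chrom": panel.sites["chrom"],
            "pos": panel.sites["pos"],
            "count": ones,
            "n": total,
        }
    )
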