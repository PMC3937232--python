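"""Site-frequency-spectrum statistics: Tajima's D, Fay & Wu's H, windowed
heterozygosity with genome-wide Z-standardization.

Tajima's D is computed from (S, pi), both fold-invariant, so it accepts
folded and unfolded spectra alike.  Fay & Wu's H (the unnormalized
``theta_pi - theta_H`` form) requires polarized, unfolded input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import HaplotypePanel, WindowGrid

DEFAULT_MIN_SITES = 10


@dataclass
class SFSpectrum:
    """Counts of sites by derived (unfolded) or minor (folded) allele count.

    ``counts[i - 1]`` is the number of sites with count ``i``; the vector is
    indexed 1..n-1 unfolded and 1..floor(n/2) folded.
    """

    n: int
    counts: np.ndarray
    folded: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        expect = self.n // 2 if self.folded else self.n - 1
        if len(self.counts) != expect:
            raise ValueError(f"expected {expect} count classes, got {len(self.counts)}")
        if (self.counts < 0).any():
            raise ValueError("negative SFS counts")

    @property
    def S(self) -> int:
        return int(self.counts.sum())

    def fold(self) -> "SFSpectrum":
        if self.folded:
            return self
        n = self.n
        half = n // 2
        folded = np.zeros(half, dtype=np.int64)
        for i in range(1, n):
            folded[min(i, n - i) - 1] += self.counts[i - 1]
        return SFSpectrum(n, folded, folded=True)


def compute_sfs(panel: HaplotypePanel, folded: bool = False) -> SFSpectrum:
    """Sample SFS over the panel's polymorphic sites.

    Unfolded spectra use only ``ancestral_known`` sites and their derived
    counts; folded spectra use minor-allele counts of every site.  Sites
    with missing haplotypes are downsampled implicitly by their non-missing
    counts only when complete; to keep class sizes exact, sites whose
    non-missing count differs from ``n_hap`` are excluded here.
    """
    n = panel.n_hap
    if n < 2:
        raise ValueError("need at least two haplotypes")
    ones, total = panel.allele_counts()
    complete = total == n
    if folded:
        use = complete
        cnt = np.minimum(ones, n - ones)[use]
        counts = np.bincount(cnt[(cnt > 0)], minlength=n // 2 + 1)[1 : n // 2 + 1]
        return SFSpectrum(n, counts, folded=True)
    known = panel.sites["ancestral_known"].to_numpy()
    use = complete & known
    cnt = ones[use]
    cnt = cnt[(cnt > 0) & (cnt < n)]
    counts = np.bincount(cnt, minlength=n)[1:n]
    return SFSpectrum(n, counts, folded=False)


def _pi_from_spectrum(spec: SFSpectrum) -> float:
    """Mean pairwise differences; identical on folded and unfolded spectra."""
    n = spec.n
    denom = n * (n - 1) / 2
    if spec.folded:
        i = np.arange(1, n // 2 + 1)
    else:
        i = np.arange(1, n)
    return float((spec.counts * i * (n - i)).sum() / denom)


def tajima_constants(n: int) -> dict[str, float]:
    """The a1..e2 constants of Tajima's D as functions of sample size."""
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(spectrum: SFSpectrum) -> float:
    """Tajima's D; NaN when the spectrum holds no segregating site."""
    S = spectrum.S
    if S == 0:
        return np.nan
    k = tajima_constants(spectrum.n)
    pi = _pi_from_spectrum(spectrum)
    num = pi - S / k["a1"]
    den = np.sqrt(k["e1"] * S + k["e2"] * S * (S - 1))
    return float(num / den)


def fay_wu_h(spectrum: SFSpectrum) -> float:
    """Unnormalized Fay & Wu's H = theta_pi - theta_H (unfolded only)."""
    if spectrum.folded:
        raise ValueError("Fay & Wu's H needs an unfolded (polarized) spectrum")
    n = spectrum.n
    if spectrum.S == 0:
        return np.nan
    i = np.arange(1, n)
    denom = n * (n - 1)
    theta_pi = float((2.0 * spectrum.counts * i * (n - i)).sum() / denom)
    theta_h = float((2.0 * spectrum.counts * i**2).sum() / denom)
    return theta_pi - theta_h


def window_sfs_stat(
    panel: HaplotypePanel,
    grid: WindowGrid,
    stat: str,
    min_sites: int = DEFAULT_MIN_SITES,
) -> pd.DataFrame:
    """Per-window Tajima's D ('tajd') or Fay & Wu's H ('faywuh') track."""
    if stat not in ("tajd", "faywuh"):
        raise ValueError(f"unknown windowed SFS statistic {stat!r}")
    folded = stat == "tajd"
    assign = grid.assign_sites(panel.sites)
    values = np.full(len(grid), np.nan)
    n_sites = np.zeros(len(grid), dtype=np.int64)
    for w, idx in enumerate(assign):
        if idx.size == 0:
            continue
        sub = panel.take_sites(idx)
        spec = compute_sfs(sub, folded=folded)
        n_sites[w] = spec.S
        if spec.S < min_sites:
            continue
        values[w] = tajimas_d(spec) if stat == "tajd" else fay_wu_h(spec)
    out = grid.windows.copy()
    out["stat"] = stat
    out["value"] = values
    out["n_sites"] = n_sites
    return out


def window_heterozygosity(
    panel: HaplotypePanel,
    grid: WindowGrid,
    min_sites: int = DEFAULT_MIN_SITES,
    diploid_observed: bool = False,
) -> pd.DataFrame:
    """Windowed heterozygosity plus its genome-wide Z score (ZHet).

    Default is expected heterozygosity ``2 p (1 - p)`` from haplotype
    frequencies, averaged over the window's polymorphic sites;
    ``diploid_observed`` switches to the fraction of heterozygous
    individuals.  ZHet standardizes by the mean and SD over non-missing
    windows.
    """
    ones, total = panel.allele_counts()
    with np.errstate(invalid="ignore"):
        p = ones / np.maximum(total, 1)
    if diploid_observed:
        H = panel.haplotypes
        het_site = (H[0::2] != H[1::2]).mean(axis=0)
    else:
        het_site = 2.0 * p * (1.0 - p)
    poly = (ones > 0) & (ones < total)

    assign = grid.assign_sites(panel.sites)
    values = np.full(len(grid), np.nan)
    n_sites = np.zeros(len(grid), dtype=np.int64)
    for w, idx in enumerate(assign):
        use = idx[poly[idx]]
        n_sites[w] = use.size
        if use.size >= min_sites:
            values[w] = het_site[use].mean()
    ok = ~np.isnan(values)
    z = np.full(len(grid), np.nan)
    if ok.sum() >= 2:
        z[ok] = (values[ok] - values[ok].mean()) / values[ok].std(ddof=1)
    out = grid.windows.copy()
    out["stat"] = "het"
    out["value"] = values
    out["zhet"] = z
    out["n_sites"] = n_sites
    return out
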