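"""Composite likelihood ratio sweep scan against a genome-wide background SFS.

The sweep model: a lineage at distance ``d`` from the swept position
escapes the sweep with probability ``p_e = 1 - exp(-alpha * d)``.
Conditional on ``k`` of the ``n`` sampled lineages escaping, the post-sweep
sample is equivalent to ``k + 1`` draws from the pre-sweep population: the
``n - k`` trapped lineages all inherit the allele of one ancestral lineage.
Pre-sweep allele counts at reduced sample sizes come from the background
spectrum by hypergeometric downsampling.

Likelihoods are conditioned on observed polymorphism (classes 1..n-1
renormalized), because input sites are segregating by construction.  The
ratio is maximized over ``alpha`` by a log-spaced grid search refined with
golden-section; ``alpha -> infinity`` recovers the background model, so the
reported ``clr = 2 * max(0, log CL_sweep - log CL_background)`` is
non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom, hypergeom

from .core_data import HaplotypePanel, WindowGrid

ALPHA_MIN = 1e-8
ALPHA_MAX = 1e-2
N_ALPHA = 30
DEFAULT_RADIUS = 100_000
_PE_GRID_SIZE = 400
_PE_FLOOR = 1e-8


@dataclass
class BackgroundSFS:
    """Normalized unfolded spectrum over derived counts 1..n-1."""

    n: int
    probs: np.ndarray
    source: str = "genome-wide"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if len(self.probs) != self.n - 1:
            raise ValueError("background spectrum needs n-1 classes")
        if (self.probs < 0).any() or not np.isclose(self.probs.sum(), 1.0):
            raise ValueError("background spectrum must be a probability vector")


def background_sfs(
    panel: HaplotypePanel, min_sites: int = 100, pseudocount: float = 0.5
) -> BackgroundSFS:
    """Genome-wide unfolded SFS over all polarized polymorphic sites.

    ``pseudocount`` is added to every derived-count class so that no class
    has probability zero; desk-scale panels leave many of the n-1 classes
    unobserved, and a zero-probability class would make the composite
    log-likelihood of any panel containing it undefined.
    """
    from .sfs_stats import compute_sfs

    spec = compute_sfs(panel, folded=False)
    if spec.S < min_sites:
        raise ValueError(
            f"only {spec.S} polarized polymorphic sites; need >= {min_sites} "
            "to calibrate a background spectrum"
        )
    counts = spec.counts + pseudocount
    return BackgroundSFS(panel.n_hap, counts / counts.sum())


def _downsampled_spectra(background: BackgroundSFS) -> np.ndarray:
    """Q[m, j] = P(j derived in a hypergeometric subsample of size m)."""
    n = background.n
    Q = np.zeros((n + 1, n + 1))
    i = np.arange(1, n)  # background classes
    for m in range(1, n + 1):
        j = np.arange(0, m + 1)
        pmf = hypergeom.pmf(j[:, None], n, i[None, :], m)  # (m+1, n-1)
        Q[m, : m + 1] = pmf @ background.probs
    return Q


def sweep_transformed_sfs(
    background: BackgroundSFS, alpha: float, d: float
) -> np.ndarray:
    """Post-sweep probability vector over derived counts 0..n at distance d.

    Lineages escape independently with ``p_e = 1 - exp(-alpha * d)``
    (saturating at 1); the trapped lineages copy one ancestral lineage's
    allele, which creates the monomorphic classes 0 and n.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if d < 0:
        raise ValueError("distance must be non-negative")
    with np.errstate(over="ignore"):
        pe = -np.expm1(-alpha * d)
    pe = min(float(pe), 1.0)
    return _transform_at_pe(background, _downsampled_spectra(background), pe)


def _transform_at_pe(background: BackgroundSFS, Q: np.ndarray, pe: float) -> np.ndarray:
    n = background.n
    T = np.zeros(n + 1)
    bk = binom.pmf(np.arange(n + 1), n, pe)
    for k in range(n):
        if bk[k] == 0.0:
            continue
        m = k + 1
        j = np.arange(0, m + 1)
        qm = Q[m, : m + 1]
        w_derived = j / m  # the exchangeable trapped-ancestor is derived
        # ancestor ancestral: final count j; ancestor derived: j - 1 + (n - k)
        np.add.at(T, j, bk[k] * qm * (1.0 - w_derived))
        np.add.at(T, n - k + j - 1, bk[k] * qm * w_derived)
    if bk[n] > 0:
        T[1:n] += bk[n] * background.probs  # every lineage escaped
    return T


@dataclass
class CLRPoint:
    chrom: str
    pos: int
    clr: float
    alpha_hat: float
    n_sites: int
    boundary: bool = False


class _SweepLikelihood:
    """Precomputed conditioned log-probabilities on a p_e grid.

    The transformed spectrum depends on (alpha, d) only through p_e, so a
    fine p_e grid with linear interpolation makes the scan cheap.
    """

    def __init__(self, background: BackgroundSFS):
        self.bg = background
        Q = _downsampled_spectra(background)
        self.pe_grid = np.concatenate(
            ([_PE_FLOOR], -np.expm1(-np.geomspace(1e-6, 40.0, _PE_GRID_SIZE - 2)), [1.0])
        )
        self.pe_grid = np.unique(np.clip(self.pe_grid, _PE_FLOOR, 1.0))
        n = background.n
        logT = np.empty((len(self.pe_grid), n - 1))
        for r, pe in enumerate(self.pe_grid):
            T = _transform_at_pe(background, Q, pe)
            poly = T[1:n]
            tot = poly.sum()
            with np.errstate(divide="ignore"):
                logT[r] = np.log(poly / tot) if tot > 0 else -np.inf
        self.logT = logT
        with np.errstate(divide="ignore"):
            self.log_bg = np.log(background.probs)

    def log_ratio(self, alpha: float, dist: np.ndarray, counts: np.ndarray) -> float:
        """Sum over sites of log P_sweep - log P_background."""
        with np.errstate(over="ignore"):
            pe = np.clip(-np.expm1(-alpha * dist), _PE_FLOOR, 1.0)
        idx = np.clip(np.searchsorted(self.pe_grid, pe) - 1, 0, len(self.pe_grid) - 2)
        lo, hi = self.pe_grid[idx], self.pe_grid[idx + 1]
        w = np.where(hi > lo, (pe - lo) / np.where(hi > lo, hi - lo, 1.0), 0.0)
        cols = counts - 1
        ls = (1.0 - w) * self.logT[idx, cols] + w * self.logT[idx + 1, cols]
        return float(ls.sum() - self.log_bg[cols].sum())


def _golden_max(f, lo: float, hi: float, tol: float = 1e-2) -> tuple[float, float]:
    """Golden-section maximization of f over [lo, hi] (log-alpha space)."""
    g = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c, d = b - g * (b - a), a + g * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - g * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + g * (b - a)
            fd = f(d)
    x = (a + b) / 2.0
    return x, f(x)


def clr_scan(
    panel: HaplotypePanel,
    background: BackgroundSFS,
    grid_positions: np.ndarray | list[int],
    window_radius: int = DEFAULT_RADIUS,
    chrom: str | None = None,
    alpha_range: tuple[float, float] = (ALPHA_MIN, ALPHA_MAX),
    n_alpha: int = N_ALPHA,
) -> pd.DataFrame:
    """CLR at each grid position, maximized over the sweep intensity alpha.

    Only polarized sites within ``window_radius`` of a grid position enter
    its composite likelihood.  Positions with no site in range come back
    with ``clr = NaN``.
    """
    sites = panel.sites
    known = sites["ancestral_known"].to_numpy()
    if chrom is None:
        chroms = sites["chrom"].unique()
        if len(chroms) != 1:
            raise ValueError("multi-chromosome panel: pass chrom explicitly")
        chrom = chroms[0]
    mask = known & (sites["chrom"] == chrom).to_numpy()
    pos = sites["pos"].to_numpy()[mask]
    counts = sites["derived_count"].to_numpy()[mask]
    seg = (counts > 0) & (counts < background.n)
    pos, counts = pos[seg], counts[seg]

    lik = _SweepLikelihood(background)
    log_amin, log_amax = np.log(alpha_range[0]), np.log(alpha_range[1])
    alphas = np.exp(np.linspace(log_amin, log_amax, n_alpha))

    out = []
    for x in np.asarray(grid_positions):
        lo = np.searchsorted(pos, x - window_radius)
        hi = np.searchsorted(pos, x + window_radius, side="right")
        d = np.abs(pos[lo:hi] - x).astype(float)
        c = counts[lo:hi]
        if len(d) == 0:
            out.append(CLRPoint(chrom, int(x), np.nan, np.nan, 0))
            continue
        vals = np.array([lik.log_ratio(a, d, c) for a in alphas])
        k = int(np.argmax(vals))
        a_lo = log_amin if k == 0 else np.log(alphas[k - 1])
        a_hi = log_amax if k == n_alpha - 1 else np.log(alphas[k + 1])
        log_a, best = _golden_max(lambda la: lik.log_ratio(np.exp(la), d, c), a_lo, a_hi)
        boundary = k in (0, n_alpha - 1)
        clr = 2.0 * max(0.0, best)
        out.append(CLRPoint(chrom, int(x), clr, float(np.exp(log_a)), len(d), boundary))
    return pd.DataFrame([vars(p) for p in out])


def grid_from_windows(grid: WindowGrid) -> np.ndarray:
    """CLR grid positions at the midpoints of a window grid."""
    w = grid.windows
    return ((w["start"] + w["end"]) // 2).to_numpy()


def make_grid(start: int, end: int, spacing: int) -> np.ndarray:
    """Evenly spaced grid positions covering [start, end], endpoints included."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    return np.arange(start, end + 1, spacing)
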