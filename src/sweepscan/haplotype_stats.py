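"""Haplotype-homozygosity scans: EHH decay, iHH integration, raw iHS, nSL,
and standardization within derived-allele-frequency bins.

EHH at a site k sites away from the core is the probability that two
randomly drawn carriers of the core allele are identical over the whole
stretch from the core to that site:

    EHH = sum_g C(e_g, 2) / C(n_c, 2)

with ``e_g`` the multiplicities of the distinct extended haplotypes among
the ``n_c`` carriers.  iHH integrates the EHH curve against physical
distance out to the interpolated crossing of the cutoff; iHS is
``ln(iHH_ancestral / iHH_derived)``.  nSL replaces physical distance by the
number of consecutive segregating sites shared by carrier pairs.

Defaults (EHH cutoff 0.05, minimum DAF 0.05, 0.025-wide standardization
bins, 100-kb maximum gap) follow the conventional settings of the
statistics; they are not data-derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_data import MISSING, HaplotypePanel

DEFAULT_CUTOFF = 0.05
DEFAULT_MIN_DAF = 0.05
DEFAULT_MAX_GAP = 100_000
DEFAULT_BIN_WIDTH = 0.025
MIN_BIN_SITES = 20


@dataclass
class EHHCurve:
    core_index: int
    allele: int
    offsets: np.ndarray  # bp from core, 0 first, increasing magnitude
    values: np.ndarray
    stop_reason: str = "cutoff"  # cutoff | edge | gap

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)


@dataclass(eq=False)
class SiteScore:
    site_index: int
    ihh_a: float = np.nan
    ihh_d: float = np.nan
    raw: float = np.nan
    std: float = np.nan
    daf: float = np.nan
    daf_bin: int = -1
    censored: bool = False


def _pair_hom(group_sizes: np.ndarray, n: int) -> float:
    pairs = n * (n - 1) / 2
    same = (group_sizes * (group_sizes - 1) / 2).sum()
    return float(same / pairs)


def ehh_curve(
    panel: HaplotypePanel,
    core_index: int,
    allele: int,
    side: str,
    cutoff: float = DEFAULT_CUTOFF,
    max_gap: int = DEFAULT_MAX_GAP,
) -> EHHCurve:
    """EHH decay away from the core among carriers of ``allele``.

    ``side`` is ``"down"`` (increasing positions) or ``"up"``.  The walk
    stops when EHH drops below ``cutoff`` (the first sub-cutoff point is
    kept so the crossing can be interpolated), at the end of the site list,
    or when two consecutive sites are more than ``max_gap`` bp apart.
    Missing alleles break haplotype identity.
    """
    if side not in ("up", "down"):
        raise ValueError("side must be 'up' or 'down'")
    H = panel.haplotypes
    pos = panel.positions()
    carriers = np.flatnonzero(H[:, core_index] == allele)
    if carriers.size < 2:
        raise ValueError("fewer than two carriers of the core allele")
    nc = carriers.size
    step = 1 if side == "down" else -1
    chrom = panel.sites["chrom"].to_numpy()
    core_chrom = chrom[core_index]
    core_pos = pos[core_index]

    # group labels: haplotypes sharing the full prefix from the core
    labels = np.zeros(nc, dtype=np.int64)
    offsets = [0]
    values = [1.0]
    reason = "edge"
    j = core_index
    while True:
        j_next = j + step
        if j_next < 0 or j_next >= panel.n_sites or chrom[j_next] != core_chrom:
            reason = "edge"
            break
        if abs(int(pos[j_next]) - int(pos[j])) > max_gap:
            reason = "gap"
            break
        j = j_next
        col = H[carriers, j]
        # refine groups by the allele at this site; MISSING isolates a haplotype
        key = labels * (nc + 3) + np.where(col == MISSING, 3 + np.arange(nc), col)
        _, labels = np.unique(key, return_inverse=True)
        sizes = np.bincount(labels)
        e = _pair_hom(sizes.astype(float), nc)
        offsets.append(int(pos[j]) - int(core_pos))
        values.append(e)
        if e < cutoff:
            reason = "cutoff"
            break
        if sizes.max() < 2:
            # all prefixes distinct: EHH is 0 from here on
            reason = "cutoff" if 0.0 < cutoff else "edge"
            break
    return EHHCurve(core_index, allele, np.array(offsets), np.array(values), reason)


def integrate_ihh(curve: EHHCurve, cutoff: float = DEFAULT_CUTOFF) -> tuple[float, bool]:
    """Trapezoid area under one side of an EHH curve, in bp.

    Integration runs from the core to the linearly interpolated crossing of
    ``cutoff``.  When the curve was truncated (edge/gap) before crossing,
    the area up to the truncation point is returned with ``censored=True``.
    """
    x = np.abs(curve.offsets).astype(float)
    y = curve.values
    if cutoff >= 1.0:
        return 0.0, False
    below = np.flatnonzero(y < cutoff)
    if below.size:
        k = below[0]
        area = float(np.trapezoid(y[:k], x[:k]))
        if k > 0:
            x0, x1 = x[k - 1], x[k]
            y0, y1 = y[k - 1], y[k]
            xc = x0 + (y0 - cutoff) * (x1 - x0) / (y0 - y1) if y0 > y1 else x1
            area += (y0 + cutoff) / 2.0 * (xc - x0)
        return area, False
    # curve never dropped below the cutoff: censored unless it ended exactly on it
    return float(np.trapezoid(y, x)), bool(y[-1] > cutoff)


def ihs_raw(
    panel: HaplotypePanel,
    core_index: int,
    cutoff: float = DEFAULT_CUTOFF,
    max_gap: int = DEFAULT_MAX_GAP,
    min_daf: float = DEFAULT_MIN_DAF,
    drop_censored: bool = False,
) -> SiteScore:
    """Unstandardized iHS = ln(iHH_ancestral / iHH_derived) at one site.

    Undefined (NaN raw) when the site is unpolarized, outside the DAF
    range, an allele class has fewer than two carriers, either iHH is zero,
    or a side was censored and ``drop_censored`` is set.
    """
    score = SiteScore(site_index=core_index)
    site = panel.sites.iloc[core_index]
    if not site["ancestral_known"]:
        return score
    daf = float(site["daf"])
    score.daf = daf
    if not (min_daf <= daf <= 1.0 - min_daf):
        return score
    H = panel.haplotypes[:, core_index]
    if (H == 1).sum() < 2 or (H == 0).sum() < 2:
        return score
    ihh = {}
    censored = False
    for allele in (0, 1):
        total = 0.0
        for side in ("up", "down"):
            curve = ehh_curve(panel, core_index, allele, side, cutoff, max_gap)
            area, cens = integrate_ihh(curve, cutoff)
            censored |= cens
            total += area
        ihh[allele] = total
    score.ihh_a, score.ihh_d = ihh[0], ihh[1]
    score.censored = censored
    if censored and drop_censored:
        return score
    if ihh[0] > 0 and ihh[1] > 0:
        score.raw = float(np.log(ihh[0] / ihh[1]))
    return score


def ihs_scan(panel: HaplotypePanel, **kwargs) -> list[SiteScore]:
    """Raw iHS at every eligible site of the panel."""
    return [ihs_raw(panel, j, **kwargs) for j in range(panel.n_sites)]


def _pair_shared_length(a: np.ndarray, b: np.ndarray, core: int) -> int:
    """Number of consecutive sites around ``core`` over which two
    haplotypes agree, core included."""
    m = len(a)
    lo = core
    while lo - 1 >= 0 and a[lo - 1] == b[lo - 1] and a[lo - 1] != MISSING:
        lo -= 1
    hi = core
    while hi + 1 < m and a[hi + 1] == b[hi + 1] and a[hi + 1] != MISSING:
        hi += 1
    return hi - lo + 1


def nsl_raw(panel: HaplotypePanel, core_index: int, min_daf: float = DEFAULT_MIN_DAF) -> SiteScore:
    """Raw nSL = ln(SL_ancestral / SL_derived), lengths in site counts.

    ``SL_c`` is the mean, over carrier pairs of allele class c, of the
    maximal run of consecutive segregating sites around the core on which
    the pair is identical.
    """
    score = SiteScore(site_index=core_index)
    site = panel.sites.iloc[core_index]
    if not site["ancestral_known"]:
        return score
    score.daf = float(site["daf"])
    if not (min_daf <= score.daf <= 1.0 - min_daf):
        return score
    H = panel.haplotypes
    chrom = panel.sites["chrom"].to_numpy()
    block = np.flatnonzero(chrom == chrom[core_index])
    sub = H[:, block]
    core = int(np.searchsorted(block, core_index))
    sl = {}
    for allele in (0, 1):
        carriers = np.flatnonzero(H[:, core_index] == allele)
        if carriers.size < 2:
            return score
        lengths = [
            _pair_shared_length(sub[carriers[i]], sub[carriers[j]], core)
            for i in range(carriers.size)
            for j in range(i + 1, carriers.size)
        ]
        sl[allele] = float(np.mean(lengths))
    score.ihh_a, score.ihh_d = sl[0], sl[1]
    if sl[0] > 0 and sl[1] > 0:
        score.raw = float(np.log(sl[0] / sl[1]))
    return score


def nsl_scan(panel: HaplotypePanel, **kwargs) -> list[SiteScore]:
    return [nsl_raw(panel, j, **kwargs) for j in range(panel.n_sites)]


def standardize_by_daf(
    scores: list[SiteScore],
    bin_width: float = DEFAULT_BIN_WIDTH,
    min_bin_sites: int = MIN_BIN_SITES,
    reference: list[SiteScore] | None = None,
) -> list[SiteScore]:
    """Standardize raw scores within derived-allele-frequency bins.

    Sites fall into equal-width DAF bins; bins holding fewer than
    ``min_bin_sites`` scored sites are merged with their nearest neighbor
    (by bin-center distance, leftward on ties) until every group is large
    enough or a single group remains.  Within each group,
    ``std = (raw - mean) / SD`` with the sample SD.  Returns the input list
    with ``std`` and ``daf_bin`` filled in place.

    ``reference`` supplies the scores from which the bin layout, means and
    SDs are taken (the genome-wide score set, in the usual usage where a
    candidate region is standardized against the whole genome); by default
    the input scores standardize themselves.
    """
    n_bins = int(np.ceil(1.0 / bin_width))
    scored = [s for s in scores if np.isfinite(s.raw) and np.isfinite(s.daf)]
    if not scored:
        return scores
    ref = (
        [s for s in reference if np.isfinite(s.raw) and np.isfinite(s.daf)]
        if reference is not None
        else scored
    )
    for s in set(scored) | set(ref):
        s.daf_bin = min(int(s.daf / bin_width), n_bins - 1)

    # group = consecutive run of original bins merged together
    groups = [[b] for b in range(n_bins)]
    counts = np.bincount([s.daf_bin for s in ref], minlength=n_bins).tolist()
    gcounts = counts[:]
    while len(groups) > 1:
        small = [i for i, c in enumerate(gcounts) if 0 < c < min_bin_sites]
        if not small:
            break
        i = small[0]
        centers = [np.mean(g) for g in groups]
        cand = []
        if i > 0:
            cand.append((abs(centers[i] - centers[i - 1]), i - 1))
        if i < len(groups) - 1:
            cand.append((abs(centers[i + 1] - centers[i]), i + 1))
        _, j = min(cand)
        lo, hi = min(i, j), max(i, j)
        groups[lo] = groups[lo] + groups[hi]
        gcounts[lo] += gcounts[hi]
        del groups[hi], gcounts[hi]

    bin_to_group = {}
    for gi, g in enumerate(groups):
        for b in g:
            bin_to_group[b] = gi
    stats: dict[int, tuple[float, float]] = {}
    ref_by_group: dict[int, list[float]] = {}
    for s in ref:
        ref_by_group.setdefault(bin_to_group[s.daf_bin], []).append(s.raw)
    for gi, raws in ref_by_group.items():
        arr = np.array(raws)
        if len(arr) < 2 or arr.std(ddof=1) == 0:
            import warnings

            warnings.warn(f"DAF group {gi}: undefined standardization (constant scores)")
            continue
        stats[gi] = (float(arr.mean()), float(arr.std(ddof=1)))
    for s in scored:
        gi = bin_to_group[s.daf_bin]
        s.daf_bin = gi
        if gi in stats:
            mu, sd = stats[gi]
            s.std = float((s.raw - mu) / sd)
    return scores
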