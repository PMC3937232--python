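"""Forward Wright-Fisher simulation of haplotype panels with known truth.

The generator produces the substrate every scan in this package is tested
on: neutral panels, hard-sweep panels conditioned on reaching a target
derived frequency, array-like ascertained SNP subsets, and
polygenic-plus-QTL phenotypes.

Model: diploid Wright-Fisher with random mating, additive selection
(genotype fitnesses 1, 1+s, 1+2s at the selected site), Poisson
recombination along a physical map of ``seq_len`` bp, and infinite-sites
mutation on the integer lattice [0, seq_len) with re-drawn collisions.
Neutral burn-in runs >= 10 N generations from a monomorphic start, so the
ancestral state of every segregating site is known by construction.

All randomness flows through one ``numpy.random.Generator``; runs are
bit-reproducible given ``SimParams.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import HaplotypePanel, _site_frame

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is expected in production
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@dataclass
class SimParams:
    """Parameters of one forward simulation."""

    n_diploids: int = 200
    sample_hap: int = 86
    seq_len: int = 200_000
    mu: float = 1.25e-6
    rho: float = 2.5e-7
    s: float = 0.0
    sweep_pos: int = 100_000
    end_freq: float = 1.0
    seed: int = 0
    burn_in_factor: int = 10
    max_attempts: int = 1000

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("selection coefficient must be >= 0")
        if not 0 < self.end_freq <= 1:
            raise ValueError("end_freq must lie in (0, 1]")
        if self.sample_hap > 2 * self.n_diploids:
            raise ValueError("cannot sample more haplotypes than the population holds")
        if self.sample_hap % 2:
            raise ValueError("sample_hap must be even (diploid sampling)")


@dataclass
class SimTruth:
    """Ground truth of a conditioned sweep run."""

    sweep_pos: int
    s: float
    fixation_generation: int
    trajectory: np.ndarray  # derived frequency per generation, starts at 1/(2N)
    attempts: int
    sample_derived_freq: float = np.nan


@njit(cache=True)
def _make_gametes(pop, newpop, pos, nsites, parents, coins, n_breaks, breaks, offsets):
    """One round of meiosis: fill newpop rows from parental haplotype pairs.

    Row g of ``newpop`` is the gamete contributed by diploid ``parents[g]``
    (haplotype rows 2p and 2p+1 of ``pop``), starting on haplotype
    ``coins[g]`` and switching at each crossover breakpoint.
    """
    n_gam = parents.shape[0]
    for g in range(n_gam):
        base = 2 * parents[g]
        k = n_breaks[g]
        if k == 0:
            src = base + coins[g]
            for j in range(nsites):
                newpop[g, j] = pop[src, j]
        else:
            o = offsets[g]
            for j in range(nsites):
                t = coins[g]
                p = pos[j]
                for m in range(k):
                    if breaks[o + m] <= p:
                        t += 1
                newpop[g, j] = pop[base + (t & 1), j]


class _Population:
    """Mutable Wright-Fisher population state with a growing site buffer."""

    def __init__(self, params: SimParams, rng: np.random.Generator):
        self.p = params
        self.rng = rng
        n2 = 2 * params.n_diploids
        cap = 512
        self.pop = np.zeros((n2, cap), dtype=np.uint8)
        self.buf = np.zeros((n2, cap), dtype=np.uint8)
        self.pos = np.zeros(cap, dtype=np.int64)
        self.occupied = np.zeros(params.seq_len, dtype=bool)
        self.nsites = 0
        self.sel_pos = -1  # position of the selected column, -1 when neutral phase

    # -- helpers -----------------------------------------------------------

    def _grow(self, need: int) -> None:
        cap = self.pop.shape[1]
        while cap < need:
            cap *= 2
        pop = np.zeros((self.pop.shape[0], cap), dtype=np.uint8)
        pop[:, : self.nsites] = self.pop[:, : self.nsites]
        self.pop = pop
        self.buf = np.zeros_like(pop)
        pos = np.zeros(cap, dtype=np.int64)
        pos[: self.nsites] = self.pos[: self.nsites]
        self.pos = pos

    def _sel_col(self) -> int:
        if self.sel_pos < 0:
            return -1
        hits = np.flatnonzero(self.pos[: self.nsites] == self.sel_pos)
        return int(hits[0]) if hits.size else -1

    def sel_freq(self) -> float:
        col = self._sel_col()
        if col < 0:
            return 0.0
        return float(self.pop[:, col].sum()) / self.pop.shape[0]

    def prune(self) -> None:
        """Drop lost and fixed columns; fixed positions stay occupied."""
        n2 = self.pop.shape[0]
        counts = self.pop[:, : self.nsites].sum(axis=0, dtype=np.int64)
        lost = counts == 0
        fixed = counts == n2
        keep = ~(lost | fixed)
        col = self._sel_col()
        if col >= 0:
            keep[col] = True  # the selected column survives even at the boundary
        if keep.all():
            return
        self.occupied[self.pos[: self.nsites][lost]] = False
        k = int(keep.sum())
        self.pop[:, :k] = self.pop[:, : self.nsites][:, keep]
        self.pos[:k] = self.pos[: self.nsites][keep]
        self.nsites = k

    # -- one generation ----------------------------------------------------

    def step(self) -> None:
        p = self.p
        n = p.n_diploids
        n2 = 2 * n
        rng = self.rng
        col = self._sel_col()
        if col >= 0 and p.s > 0:
            dosage = self.pop[0::2, col].astype(np.float64) + self.pop[1::2, col]
            w = 1.0 + p.s * dosage
            parents = rng.choice(n, size=n2, p=w / w.sum())
        else:
            parents = rng.integers(0, n, size=n2)
        coins = rng.integers(0, 2, size=n2).astype(np.uint8)
        n_breaks = rng.poisson(p.rho * p.seq_len, size=n2).astype(np.int64)
        total = int(n_breaks.sum())
        breaks = rng.integers(0, p.seq_len, size=total)
        offsets = np.concatenate(([0], np.cumsum(n_breaks)[:-1])).astype(np.int64)
        _make_gametes(
            self.pop, self.buf, self.pos, self.nsites,
            parents.astype(np.int64), coins, n_breaks, breaks, offsets,
        )
        self.pop, self.buf = self.buf, self.pop

        n_mut = rng.poisson(n2 * p.mu * p.seq_len)
        if self.nsites + n_mut > self.pop.shape[1]:
            self._grow(self.nsites + n_mut)
        for _ in range(n_mut):
            x = int(rng.integers(0, p.seq_len))
            while self.occupied[x]:
                x = int(rng.integers(0, p.seq_len))
            j = self.nsites
            self.pop[:, j] = 0
            self.pop[int(rng.integers(0, n2)), j] = 1
            self.pos[j] = x
            self.occupied[x] = True
            self.nsites += 1
        self.prune()

    def snapshot(self) -> tuple:
        return (
            self.pop[:, : self.nsites].copy(),
            self.pos[: self.nsites].copy(),
            self.occupied.copy(),
            self.nsites,
        )

    def restore(self, snap: tuple) -> None:
        pop, pos, occ, nsites = snap
        if pop.shape[1] > self.pop.shape[1]:
            self._grow(pop.shape[1])
        self.pop[:, :nsites] = pop
        self.pos[:nsites] = pos
        self.occupied[:] = occ
        self.nsites = nsites

    # -- sampling ----------------------------------------------------------

    def sample_panel(self, keep_pos: int | None = None) -> HaplotypePanel:
        """Draw ``sample_hap`` haplotypes (as diploids) and build the panel.

        Columns monomorphic in the sample are dropped unless their position
        equals ``keep_pos``.
        """
        p = self.p
        rng = self.rng
        idx = rng.choice(p.n_diploids, size=p.sample_hap // 2, replace=False)
        rows = np.empty(p.sample_hap, dtype=np.int64)
        rows[0::2] = 2 * idx
        rows[1::2] = 2 * idx + 1
        H = self.pop[rows][:, : self.nsites].astype(np.int8)
        pos = self.pos[: self.nsites]
        counts = H.sum(axis=0, dtype=np.int64)
        seg = (counts > 0) & (counts < p.sample_hap)
        if keep_pos is not None:
            seg |= pos == keep_pos
        order = np.argsort(pos[seg], kind="mergesort")
        H = H[:, seg][:, order]
        pos_out = pos[seg][order]
        nk = len(pos_out)
        sites = _site_frame(["1"] * nk, pos_out, ["A"] * nk, ["G"] * nk)
        panel = HaplotypePanel(H, sites, [f"ind{i}" for i in idx])
        ones, total = panel.allele_counts()
        freq = ones / np.maximum(total, 1)
        panel.sites["ancestral_known"] = True
        panel.sites["derived_count"] = ones
        panel.sites["daf"] = freq
        panel.sites["maf"] = np.minimum(freq, 1 - freq)
        return panel


def simulate_neutral_panel(params: SimParams) -> HaplotypePanel:
    """Neutral Wright-Fisher panel after >= 10 N generations of burn-in."""
    if params.s != 0:
        raise ValueError("neutral simulation requires s == 0")
    if params.mu <= 0 or params.seq_len <= 0:
        raise ValueError("mu and seq_len must be positive")
    rng = np.random.default_rng(params.seed)
    popn = _Population(params, rng)
    for _ in range(params.burn_in_factor * params.n_diploids):
        popn.step()
    return popn.sample_panel()


def simulate_sweep_panel(params: SimParams) -> tuple[HaplotypePanel, SimTruth]:
    """Hard sweep conditioned on the beneficial allele reaching ``end_freq``.

    After neutral burn-in the beneficial mutation is injected at
    ``sweep_pos`` on a single haplotype; runs that lose it restart from the
    injection state.  The panel is sampled in the first generation whose
    derived frequency is >= ``end_freq``.
    """
    if params.s <= 0:
        raise ValueError("sweep simulation requires s > 0")
    if not 0 <= params.sweep_pos < params.seq_len:
        raise ValueError("sweep_pos outside the simulated sequence")
    rng = np.random.default_rng(params.seed)
    popn = _Population(params, rng)
    for _ in range(params.burn_in_factor * params.n_diploids):
        popn.step()

    # clear any standing mutation occupying the target position
    old = np.flatnonzero(popn.pos[: popn.nsites] == params.sweep_pos)
    if old.size:
        keep = np.ones(popn.nsites, dtype=bool)
        keep[old] = False
        k = int(keep.sum())
        popn.pop[:, :k] = popn.pop[:, : popn.nsites][:, keep]
        popn.pos[:k] = popn.pos[: popn.nsites][keep]
        popn.nsites = k
    popn.occupied[params.sweep_pos] = True
    snap = popn.snapshot()

    n2 = 2 * params.n_diploids
    for attempt in range(1, params.max_attempts + 1):
        if popn.nsites + 1 > popn.pop.shape[1]:
            popn._grow(popn.nsites + 1)
        j = popn.nsites
        popn.pop[:, j] = 0
        popn.pop[int(rng.integers(0, n2)), j] = 1
        popn.pos[j] = params.sweep_pos
        popn.nsites = j + 1
        popn.sel_pos = params.sweep_pos

        traj = [1.0 / n2]
        gen = 0
        while True:
            popn.step()
            gen += 1
            f = popn.sel_freq()
            traj.append(f)
            if f <= 0.0:
                break
            if f >= params.end_freq:
                truth = SimTruth(
                    sweep_pos=params.sweep_pos,
                    s=params.s,
                    fixation_generation=gen,
                    trajectory=np.array(traj),
                    attempts=attempt,
                )
                panel = popn.sample_panel(keep_pos=params.sweep_pos)
                at = np.flatnonzero(panel.positions() == params.sweep_pos)
                if at.size:
                    col = panel.haplotypes[:, at[0]]
                    truth.sample_derived_freq = float((col == 1).mean())
                    if truth.sample_derived_freq in (0.0, 1.0):
                        panel = panel.take_sites(
                            np.flatnonzero(panel.positions() != params.sweep_pos)
                        )
                else:
                    truth.sample_derived_freq = 1.0 if params.end_freq == 1.0 else 0.0
                return panel, truth
        popn.restore(snap)
        popn.sel_pos = -1
    raise RuntimeError(
        f"beneficial allele lost in all {params.max_attempts} attempts; "
        "increase s or the population size"
    )


def ascertain_array_sites(
    panel: HaplotypePanel, maf_min: float, target_spacing: int
) -> HaplotypePanel:
    """Array-like ascertainment: MAF floor plus one site per spacing bin.

    Keeps sites with ``maf >= maf_min``, then retains the highest-MAF site
    in each ``target_spacing``-bp bin per chromosome (ties go to the
    leftmost site), mimicking frequency- and spacing-based SNP-chip design.
    """
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    sites = panel.sites
    maf = sites["maf"].to_numpy()
    ok = np.flatnonzero(maf >= maf_min)
    if ok.size == 0:
        raise ValueError("no site passes the MAF filter")
    sub = sites.iloc[ok]
    keep: list[int] = []
    for _, grp in sub.groupby("chrom", sort=False):
        bins = grp["pos"].to_numpy() // target_spacing
        frame = pd.DataFrame({"bin": bins, "maf": grp["maf"].to_numpy(), "row": grp.index})
        # stable sort keeps the leftmost site among ties within a bin
        best = frame.sort_values("maf", kind="mergesort", ascending=False).drop_duplicates("bin")
        keep.extend(int(r) for r in best["row"])
    keep = sorted(keep)
    return panel.take_sites(np.asarray(keep, dtype=np.int64))


@dataclass
class PhenotypeTruth:
    """Realized variance decomposition of a simulated trait."""

    qtl: list[tuple[int, float]]
    var_qtl: float
    var_poly: float
    var_noise: float
    var_y: float
    qtl_fractions: list[float] = field(default_factory=list)


def simulate_phenotypes(
    panel: HaplotypePanel,
    qtl: list[tuple[int, float]],
    h2_poly: float,
    seed: int,
    noise_var: float = 1.0,
) -> tuple[np.ndarray, PhenotypeTruth]:
    """Polygenic-plus-major-QTL phenotypes from diploid dosages.

    ``y = sum_q beta_q * dosage_q + u + e`` where ``u`` sums small random
    effects over every site, rescaled so that ``var(u) / (var(u) + var(e))``
    equals ``h2_poly``, and ``e ~ N(0, noise_var)``.
    """
    if not 0 <= h2_poly < 1:
        raise ValueError("h2_poly must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    D = panel.dosages()
    D = np.nan_to_num(D, nan=0.0)
    n_ind, n_sites = D.shape

    g_qtl = np.zeros(n_ind)
    for idx, beta in qtl:
        if not 0 <= idx < n_sites:
            raise IndexError(f"QTL site index {idx} out of range (n_sites={n_sites})")
        g_qtl += beta * D[:, idx]

    e = rng.normal(0.0, np.sqrt(noise_var), size=n_ind)
    if h2_poly > 0 and n_sites > 0:
        a = rng.normal(0.0, 1.0, size=n_sites)
        u = (D - D.mean(axis=0)) @ a
        sd = u.std()
        target_var = noise_var * h2_poly / (1.0 - h2_poly)
        u = u * (np.sqrt(target_var) / sd) if sd > 0 else np.zeros(n_ind)
    else:
        u = np.zeros(n_ind)

    y = g_qtl + u + e
    var_y = float(y.var())
    fractions = []
    for idx, beta in qtl:
        fractions.append(float((beta * D[:, idx]).var() / var_y) if var_y > 0 else 0.0)
    truth = PhenotypeTruth(
        qtl=list(qtl),
        var_qtl=float(g_qtl.var()),
        var_poly=float(u.var()),
        var_noise=float(e.var()),
        var_y=var_y,
        qtl_fractions=fractions,
    )
    return y, truth
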