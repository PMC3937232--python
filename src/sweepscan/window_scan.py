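"""Window aggregation, genome-wide empirical p-values, candidate-region
calling, and the within-window variance coherence check.

Empirical p-values follow the genome-wide-ranking convention: the window
ranked r-th from the top among N non-missing windows gets ``emp_p = r / N``
(ties share the maximal rank of their group).  Candidate regions are
maximal runs of windows whose empirical p falls within the top
``1 - percentile`` tail, merged across at most ``merge_gap`` intervening
windows on the same chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import WindowGrid

DEFAULT_MIN_SITES = 10


@dataclass
class SweepRegion:
    chrom: str
    start: int
    end: int
    n_windows: int
    best_value: float
    best_emp_p: float
    source: str = ""


def aggregate_windows(
    site_scores: pd.DataFrame,
    grid: WindowGrid,
    transform: str = "abs",
    min_sites: int = DEFAULT_MIN_SITES,
    stat_name: str = "score",
) -> pd.DataFrame:
    """Mean per-window of (optionally absolute) site scores.

    ``site_scores`` needs columns (chrom, pos, score); NaN scores are
    ignored.  Windows with fewer than ``min_sites`` scored sites are
    reported missing (NaN value).
    """
    if transform not in ("abs", "identity"):
        raise ValueError("transform must be 'abs' or 'identity'")
    if len(site_scores) == 0:
        raise ValueError("empty site score list")
    scores = site_scores.dropna(subset=["score"])
    vals = scores["score"].to_numpy(dtype=float)
    if transform == "abs":
        vals = np.abs(vals)
    frame = pd.DataFrame(
        {"chrom": scores["chrom"].to_numpy(), "pos": scores["pos"].to_numpy(), "v": vals}
    )
    assign = grid.assign_sites(frame.rename(columns={"v": "score"}))
    out = grid.windows.copy()
    value = np.full(len(grid), np.nan)
    n_sites = np.zeros(len(grid), dtype=np.int64)
    for w, idx in enumerate(assign):
        n_sites[w] = idx.size
        if idx.size >= min_sites:
            value[w] = frame["v"].to_numpy()[idx].mean()
    out["stat"] = stat_name
    out["value"] = value
    out["n_sites"] = n_sites
    return out


def empirical_pvalues(track: pd.DataFrame, tail: str = "upper") -> pd.DataFrame:
    """Attach genome-wide-ranking empirical p-values to a window track.

    emp_p = (descending rank) / (number of non-missing windows); tied
    values share the maximal rank of their tie group, so the best of 100
    windows gets 0.01 and two tied bests both get 0.02.
    """
    if tail != "upper":
        raise ValueError("only upper-tail ranking is defined")
    out = track.copy()
    vals = out["value"].to_numpy(dtype=float)
    ok = ~np.isnan(vals)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no non-missing windows to rank")
    emp = np.full(len(out), np.nan)
    ranks = pd.Series(vals[ok]).rank(method="max", ascending=False).to_numpy()
    emp[ok] = ranks / n
    out["emp_p"] = emp
    return out


def call_regions(
    track: pd.DataFrame,
    percentile: float = 0.99,
    merge_gap: int = 0,
    source: str = "",
) -> list[SweepRegion]:
    """Merge top-tail windows into candidate sweep regions.

    Windows with ``emp_p <= 1 - percentile`` are retained; retained windows
    separated by at most ``merge_gap`` intervening grid windows on the same
    chromosome merge into one region.  The track is ranked here if it does
    not carry ``emp_p`` yet.
    """
    if not 0 < percentile < 1:
        raise ValueError("percentile must lie in (0, 1)")
    if "emp_p" not in track.columns:
        track = empirical_pvalues(track)
    tail = 1.0 - percentile
    keep = track["emp_p"].to_numpy() <= tail + 1e-12
    regions: list[SweepRegion] = []
    track = track.reset_index(drop=True)
    for chrom, sub in track.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        idx = np.flatnonzero(keep[sub.index.to_numpy()])
        if idx.size == 0:
            continue
        rows = sub.iloc[idx]
        run = [0]
        runs = []
        for i in range(1, len(rows)):
            if idx[i] - idx[i - 1] - 1 <= merge_gap:
                run.append(i)
            else:
                runs.append(run)
                run = [i]
        runs.append(run)
        for r in runs:
            block = rows.iloc[r]
            best = block["value"].idxmax()
            regions.append(
                SweepRegion(
                    chrom=str(chrom),
                    start=int(block["start"].min()),
                    end=int(block["end"].max()),
                    n_windows=len(block),
                    best_value=float(block.loc[best, "value"]),
                    best_emp_p=float(block.loc[best, "emp_p"]),
                    source=source,
                )
            )
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def union_regions(*region_sets: list[SweepRegion]) -> list[SweepRegion]:
    """Union of region sets with overlapping spans merged."""
    allr = sorted(
        (r for rs in region_sets for r in rs), key=lambda r: (r.chrom, r.start)
    )
    merged: list[SweepRegion] = []
    for r in allr:
        if merged and merged[-1].chrom == r.chrom and r.start < merged[-1].end:
            m = merged[-1]
            m.end = max(m.end, r.end)
            m.n_windows += r.n_windows
            if r.best_emp_p < m.best_emp_p:
                m.best_value, m.best_emp_p = r.best_value, r.best_emp_p
            if r.source and r.source not in m.source.split("+"):
                m.source = f"{m.source}+{r.source}" if m.source else r.source
        else:
            merged.append(
                SweepRegion(r.chrom, r.start, r.end, r.n_windows, r.best_value, r.best_emp_p, r.source)
            )
    return merged


def regions_to_frame(regions: list[SweepRegion]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in regions])


def write_regions_bed(regions: list[SweepRegion], path: str) -> None:
    with open(path, "w") as fh:
        for r in regions:
            name = r.source or "region"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{r.best_value:.6g}\n")


def window_variance_check(
    site_scores: pd.DataFrame,
    grid: WindowGrid,
    n_random_groups: int = 1000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Within-window variance of |score| vs random same-sized SNP groups.

    Returns (var_within, var_random, permutation p-value for
    var_within < var_random).  Groups with fewer than two scored sites are
    skipped.
    """
    rng = np.random.default_rng(seed)
    scores = site_scores.dropna(subset=["score"])
    v = np.abs(scores["score"].to_numpy(dtype=float))
    assign = grid.assign_sites(scores)
    sizes = [idx.size for idx in assign if idx.size >= 2]
    if not sizes:
        raise ValueError("no window holds two scored sites")
    var_within = float(
        np.mean([v[idx].var(ddof=1) for idx in assign if idx.size >= 2])
    )

    def random_mean_var() -> float:
        return float(
            np.mean([v[rng.choice(len(v), s, replace=False)].var(ddof=1) for s in sizes])
        )

    rand = np.array([random_mean_var() for _ in range(n_random_groups)])
    var_random = float(rand.mean())
    p = float(((rand <= var_within).sum() + 1) / (n_random_groups + 1))
    return var_within, var_random, p


def read_published_track(
    path: str,
    chrom_col: str | int = 0,
    start_col: str | int = 1,
    value_col: str | int = -1,
    window_size: int = 40_000,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a published per-window score CSV into the track layout.

    Tolerant reader for supplementary score files laid out as one window
    per row with a chromosome, a window start (or midpoint) and a score
    column; columns may be addressed by name or position.  The delimiter is
    sniffed when not given.
    """
    tab = pd.read_csv(path, sep=sep, engine="python")
    def pick(c):
        return tab.columns[c] if isinstance(c, int) else c
    chrom = tab[pick(chrom_col)].astype(str)
    start = tab[pick(start_col)].astype(np.int64)
    value = tab[pick(value_col)].astype(float)
    return pd.DataFrame(
        {"chrom": chrom, "start": start, "end": start + window_size, "value": value}
    )
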