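import numpy as np
import pandas as pd
import pytest

from sweepscan.core_data import _site_frame, build_window_grid
from sweepscan.window_scan import (
    aggregate_windows,
    call_regions,
    empirical_pvalues,
    read_published_track,
    regions_to_frame,
    union_regions,
    window_variance_check,
    write_regions_bed,
)


def site_scores(positions, scores, chrom="1"):
    return pd.DataFrame({"chrom": chrom, "pos": positions, "score": scores})


def grid_for(max_pos, size, step=None, chrom="1"):
    sites = _site_frame([chrom] * 2, [0, max_pos], ["A"] * 2, ["G"] * 2)
    return build_window_grid(sites, size, step)


class TestAggregateWindows:
    def test_abs_mean(self):
        grid = grid_for(900, 1000)
        track = aggregate_windows(site_scores([10, 20], [0.5, -1.5]), grid, min_sites=2)
        assert track["value"].iloc[0] == pytest.approx(1.0)

    def test_window_below_floor_missing(self):
        grid = grid_for(900, 1000)
        track = aggregate_windows(site_scores([1, 2, 3], [1, 1, 1]), grid, min_sites=10)
        assert np.isnan(track["value"].iloc[0])
        assert track["n_sites"].iloc[0] == 3

    def test_empty_scores_raise(self):
        grid = grid_for(900, 1000)
        with pytest.raises(ValueError):
            aggregate_windows(site_scores([], []), grid)

    def test_overlapping_grid_membership(self):
        # 40-kb windows in 5-kb steps: an interior site falls in exactly 8 windows
        grid = grid_for(400_000, 40_000, 5_000)
        track = aggregate_windows(site_scores([200_123], [1.0]), grid, min_sites=1)
        assert int((track["n_sites"] > 0).sum()) == 8

    def test_identity_transform(self):
        grid = grid_for(900, 1000)
        track = aggregate_windows(
            site_scores([10, 20], [0.5, -1.5]), grid, transform="identity", min_sites=2
        )
        assert track["value"].iloc[0] == pytest.approx(-0.5)


class TestEmpiricalPvalues:
    @staticmethod
    def _track(values, chrom="1"):
        n = len(values)
        return pd.DataFrame(
            {
                "chrom": chrom,
                "start": np.arange(n) * 1000,
                "end": (np.arange(n) + 1) * 1000,
                "value": values,
            }
        )

    def test_best_of_100(self):
        vals = np.arange(100, dtype=float)
        track = empirical_pvalues(self._track(vals))
        assert track.loc[track["value"].idxmax(), "emp_p"] == pytest.approx(0.01)

    def test_tied_best_share_max_rank(self):
        vals = np.arange(100, dtype=float)
        vals[0] = vals[99]
        track = empirical_pvalues(self._track(vals))
        tied = track[track["value"] == vals[99]]
        assert np.allclose(tied["emp_p"].to_numpy(), 0.02)

    def test_paper_scale_rank(self):
        # rank 18 among 62,196 windows -> emp_p ~ 0.00029
        rng = np.random.default_rng(0)
        vals = rng.normal(size=62_196)
        track = empirical_pvalues(self._track(vals))
        r18 = np.sort(vals)[::-1][17]
        got = float(track.loc[track["value"] == r18, "emp_p"].iloc[0])
        assert got == pytest.approx(18 / 62_196)
        assert got == pytest.approx(0.00029, abs=1e-5)

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=500)
        track = empirical_pvalues(self._track(vals))
        order_v = np.argsort(-track["value"].to_numpy())
        order_p = np.argsort(track["emp_p"].to_numpy(), kind="stable")
        assert (track["value"].to_numpy()[order_p] == track["value"].to_numpy()[order_v]).all()

    def test_missing_windows_excluded(self):
        vals = [1.0, np.nan, 2.0]
        track = empirical_pvalues(self._track(vals))
        assert np.isnan(track["emp_p"].iloc[1])
        assert track["emp_p"].iloc[2] == pytest.approx(0.5)

    def test_all_missing_raises(self):
        with pytest.raises(ValueError):
            empirical_pvalues(self._track([np.nan, np.nan]))


class TestCallRegions:
    @staticmethod
    def _track_with_top(indices, n=20, chrom="1"):
        vals = np.linspace(0.0, 0.5, n)
        vals[list(indices)] = 10.0 + np.arange(len(indices))
        return pd.DataFrame(
            {
                "chrom": chrom,
                "start": np.arange(n) * 1000,
                "end": (np.arange(n) + 1) * 1000,
                "value": vals,
            }
        )

    def test_adjacent_merge_gap0(self):
        track = self._track_with_top([5, 6, 9])
        regions = call_regions(track, percentile=0.85, merge_gap=0)
        assert len(regions) == 2
        assert regions[0].start == 5000 and regions[0].end == 7000

    def test_merge_gap2_joins(self):
        track = self._track_with_top([5, 6, 9])
        regions = call_regions(track, percentile=0.85, merge_gap=2)
        assert len(regions) == 1
        assert regions[0].n_windows == 3

    def test_exact_top_percent_count(self):
        rng = np.random.default_rng(3)
        n = 1000
        track = pd.DataFrame(
            {
                "chrom": "1",
                "start": np.arange(n) * 1000,
                "end": (np.arange(n) + 1) * 1000,
                "value": rng.permutation(n).astype(float),
            }
        )
        track = empirical_pvalues(track)
        kept = (track["emp_p"] <= 0.01 + 1e-12).sum()
        assert kept == 10

    def test_bad_percentile(self):
        with pytest.raises(ValueError):
            call_regions(self._track_with_top([1]), percentile=1.5)

    def test_regions_disjoint_sorted_cover_retained(self):
        rng = np.random.default_rng(8)
        n = 300
        track = pd.DataFrame(
            {
                "chrom": rng.choice(["1", "2"], n),
                "start": 0,
                "end": 0,
                "value": rng.normal(size=n),
            }
        )
        track = (
            track.sort_values("chrom", kind="mergesort").reset_index(drop=True)
        )
        for c, sub in track.groupby("chrom"):
            track.loc[sub.index, "start"] = np.arange(len(sub)) * 1000
            track.loc[sub.index, "end"] = (np.arange(len(sub)) + 1) * 1000
        track = empirical_pvalues(track)
        regions = call_regions(track, percentile=0.9)
        # disjoint + sorted
        for a, b in zip(regions, regions[1:]):
            assert (a.chrom, a.start) <= (b.chrom, b.start)
            if a.chrom == b.chrom:
                assert a.end <= b.start
        # windows covered equals retained count
        retained = (track["emp_p"] <= 0.1 + 1e-12).sum()
        assert sum(r.n_windows for r in regions) == retained

    def test_union_regions_merges_overlaps(self):
        ta = self._track_with_top([5, 6])
        tb = self._track_with_top([6, 7, 15])
        ra = call_regions(ta, percentile=0.85, source="ihs")
        rb = call_regions(tb, percentile=0.8, source="clr")
        merged = union_regions(ra, rb)
        spans = [(r.start, r.end) for r in merged]
        assert (5000, 8000) in spans
        srcs = {r.source for r in merged if r.start == 5000}
        assert srcs == {"ihs+clr"}

    def test_bed_output(self, tmp_path):
        regions = call_regions(self._track_with_top([5]), percentile=0.9)
        path = tmp_path / "r.bed"
        write_regions_bed(regions, str(path))
        line = path.read_text().strip().split("\t")
        assert line[0] == "1" and int(line[1]) == 5000
        assert not regions_to_frame(regions).empty


class TestWindowVarianceCheck:
    def test_autocorrelated_scores_smaller_within_variance(self):
        rng = np.random.default_rng(5)
        n = 2000
        pos = np.arange(n) * 100
        block_means = rng.normal(0, 2.0, size=n // 40 + 1)
        scores = block_means[pos // 4000] + rng.normal(0, 0.3, size=n)
        grid = grid_for(pos.max(), 4000)
        vw, vr, p = window_variance_check(site_scores(pos, scores), grid, 200, seed=1)
        assert vw < vr
        assert p < 0.05

    def test_iid_scores_null(self):
        rng = np.random.default_rng(6)
        ps = []
        for rep in range(10):
            n = 400
            pos = np.arange(n) * 100
            scores = rng.normal(size=n)
            grid = grid_for(pos.max(), 4000)
            _, _, p = window_variance_check(
                site_scores(pos, scores), grid, 99, seed=rep
            )
            ps.append(p)
        # null p-values should not concentrate near 0
        assert np.mean(ps) > 0.2
        assert min(ps) > 0.005

    def test_constant_scores_zero_variances(self):
        pos = np.arange(100) * 100
        grid = grid_for(pos.max(), 2000)
        vw, vr, _ = window_variance_check(site_scores(pos, np.ones(100)), grid, 50, seed=0)
        assert vw == 0.0 and vr == 0.0


class TestPublishedTrackReader:
    def test_reads_csv_with_named_columns(self, tmp_path):
        path = tmp_path / "ds.csv"
        path.write_text("chr,window_start,iHS\n1,0,0.5\n1,40000,1.5\n2,0,0.7\n")
        track = read_published_track(str(path), "chr", "window_start", "iHS")
        assert len(track) == 3
        assert track["end"].iloc[0] == 40_000
        assert track["value"].iloc[1] == 1.5

    def test_positional_columns_and_sniffed_delimiter(self, tmp_path):
        path = tmp_path / "ds.txt"
        path.write_text("chrom;start;clr\n1;0;3.2\n1;40000;0.1\n")
        track = read_published_track(str(path), 0, 1, 2)
        assert track["value"].tolist() == [3.2, 0.1]


class TestPipelineSmoke:
    def test_sweeps_recovered_neutral_mostly_not(self):
        # scaled-down version of the genome-embedding design: 4 hard sweeps
        # among 16 neutral 100-kb segments; called iHS-or-CLR regions should
        # hit most sweep segments and few neutral ones (fixed seeds)
        import pandas as pd

        from sweepscan.clr_scan import background_sfs, clr_scan, make_grid
        from sweepscan.core_data import HaplotypePanel, build_window_grid
        from sweepscan.haplotype_stats import ihs_scan, standardize_by_daf
        from sweepscan.synthetic_data import (
            SimParams,
            simulate_neutral_panel,
            simulate_sweep_panel,
        )
        from sweepscan.window_scan import union_regions

        L = 100_000
        n_seg = 20
        sweeps = {3, 8, 13, 17}
        base = dict(n_diploids=100, sample_hap=40, seq_len=L, mu=1e-6, rho=2e-6)
        panels = []
        for i in range(n_seg):
            if i in sweeps:
                p, _ = simulate_sweep_panel(
                    SimParams(**base, s=0.15, sweep_pos=L // 2, end_freq=0.9, seed=40 + i)
                )
            else:
                p = simulate_neutral_panel(SimParams(**base, seed=40 + i))
            p.sites["chrom"] = f"seg{i}"
            panels.append(p)

        all_scores = [ihs_scan(p) for p in panels]
        flat = [s for sub in all_scores for s in sub]
        standardize_by_daf(flat, reference=flat)  # genome-wide standardization

        neut = [p for i, p in enumerate(panels) if i not in sweeps][:3]
        pooled = HaplotypePanel(
            np.hstack([p.haplotypes for p in neut]),
            pd.concat([p.sites for p in neut], ignore_index=True),
        )
        bg = background_sfs(pooled)
        site_rows, clr_rows = [], []
        for i, p in enumerate(panels):
            sc = all_scores[i]
            pos = p.positions()
            site_rows.append(
                pd.DataFrame(
                    {
                        "chrom": f"seg{i}",
                        "pos": pos[[s.site_index for s in sc]],
                        "score": [s.std for s in sc],
                    }
                )
            )
            tab = clr_scan(
                p, bg, make_grid(10_000, 90_000, 20_000),
                window_radius=50_000, chrom=f"seg{i}",
            )
            tab["start"] = tab["pos"] - 10_000
            tab["end"] = tab["pos"] + 10_000
            clr_rows.append(tab)

        scores = pd.concat(site_rows, ignore_index=True)
        grid = build_window_grid(scores, 20_000)
        track_ihs = empirical_pvalues(aggregate_windows(scores, grid, min_sites=5))
        track_clr = empirical_pvalues(
            pd.concat(clr_rows, ignore_index=True)
            .rename(columns={"clr": "value"})[["chrom", "start", "end", "value"]]
        )
        regions = union_regions(
            call_regions(track_ihs, percentile=0.95, source="ihs"),
            call_regions(track_clr, percentile=0.95, source="clr"),
        )
        hit = {r.chrom for r in regions}
        sweep_hits = sum(f"seg{i}" in hit for i in sweeps)
        neutral_hits = sum(f"seg{i}" in hit for i in range(n_seg) if i not in sweeps)
        assert sweep_hits >= 3
        assert neutral_hits <= 3
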