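"""Core domain types and I/O shared by every scan.

Data model
----------
A :class:`HaplotypePanel` is a matrix of allele codes (rows = haplotypes,
columns = sites) together with a per-site table and the sample identifiers.
Internally all coordinates are 0-based half-open; VCF positions (1-based)
are converted on read and on write.

Allele codes are 0/1 with ``MISSING`` (-1) for missing data.  Code 0 always
denotes the allele stored in the ``ref`` column of the site table, code 1
the ``alt`` allele.  :func:`polarize_sites` re-orients sites so that, where
the ancestral state is known, code 1 is the derived allele (swapping the
ref/alt labels when it flips codes, which makes the operation idempotent).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = np.int8(-1)

SITE_COLUMNS = [
    "chrom", "pos", "ref", "alt", "ancestral_known", "derived_count", "daf", "maf",
]


class UnphasedGenotypeError(ValueError):
    """Raised when a VCF record carries an unphased diploid genotype."""


def _site_frame(chrom, pos, ref, alt) -> pd.DataFrame:
    n = len(pos)
    return pd.DataFrame(
        {
            "chrom": pd.Series(chrom, dtype=str),
            "pos": pd.Series(pos, dtype=np.int64),
            "ref": pd.Series(ref, dtype=str),
            "alt": pd.Series(alt, dtype=str),
            "ancestral_known": np.zeros(n, dtype=bool),
            "derived_count": np.full(n, -1, dtype=np.int64),
            "daf": np.full(n, np.nan),
            "maf": np.full(n, np.nan),
        }
    )


@dataclass
class HaplotypePanel:
    """Phased binary haplotype matrix plus per-site metadata.

    Attributes
    ----------
    haplotypes:
        ``(n_hap, n_sites)`` int8 matrix with values in {0, 1, MISSING}.
    sites:
        Per-site table with columns ``chrom, pos, ref, alt,
        ancestral_known, derived_count, daf, maf``; ``pos`` is 0-based.
    sample_ids:
        One identifier per diploid individual; haplotype rows ``2i`` and
        ``2i + 1`` belong to ``sample_ids[i]``.  May be empty for panels
        that are not organised in diploids.
    """

    haplotypes: np.ndarray
    sites: pd.DataFrame
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D")
        if self.haplotypes.shape[1] != len(self.sites):
            raise ValueError(
                f"matrix has {self.haplotypes.shape[1]} columns but the site "
                f"table has {len(self.sites)} rows"
            )
        bad = ~np.isin(self.haplotypes, (0, 1, MISSING))
        if bad.any():
            raise ValueError("allele codes must be 0, 1 or MISSING")
        if self.sample_ids and 2 * len(self.sample_ids) != self.n_hap:
            raise ValueError("expected two haplotypes per sample id")

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def positions(self) -> np.ndarray:
        return self.sites["pos"].to_numpy()

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (count of allele 1, count of non-missing haplotypes)."""
        obs = self.haplotypes != MISSING
        ones = (self.haplotypes == 1).sum(axis=0)
        return ones.astype(np.int64), obs.sum(axis=0).astype(np.int64)

    def alt_freq(self) -> np.ndarray:
        ones, total = self.allele_counts()
        with np.errstate(invalid="ignore"):
            return np.where(total > 0, ones / np.maximum(total, 1), np.nan)

    def take_sites(self, index: np.ndarray) -> "HaplotypePanel":
        """Subset panel to the given site (column) indices, order preserved."""
        index = np.asarray(index)
        return HaplotypePanel(
            self.haplotypes[:, index],
            self.sites.iloc[index].reset_index(drop=True),
            list(self.sample_ids),
        )

    def dosages(self) -> np.ndarray:
        """Per-individual allele-1 dosage matrix (n_individuals x n_sites).

        Missing haplotypes propagate to NaN dosages.
        """
        if self.n_hap % 2:
            raise ValueError("dosages need an even number of haplotypes")
        h = self.haplotypes.astype(float)
        h[self.haplotypes == MISSING] = np.nan
        return h[0::2] + h[1::2]


@dataclass
class WindowGrid:
    """Genomic windows ``[start, start + window_size)`` anchored at 0."""

    windows: pd.DataFrame  # columns chrom, start, end
    window_size: int
    step: int

    def __len__(self) -> int:
        return len(self.windows)

    def assign_sites(self, sites: pd.DataFrame) -> list[np.ndarray]:
        """Site row-indices contained in each window (a site may fall in
        several windows when ``step < window_size``)."""
        out: list[np.ndarray] = []
        pos = sites["pos"].to_numpy()
        chrom = sites["chrom"].to_numpy()
        for _, w in self.windows.iterrows():
            mask = (chrom == w.chrom) & (pos >= w.start) & (pos < w.end)
            out.append(np.flatnonzero(mask))
        return out


@dataclass
class IntervalSet:
    """Named half-open intervals, 0-based."""

    records: pd.DataFrame  # columns chrom, start, end, name

    def __post_init__(self) -> None:
        r = self.records
        if (r["start"] > r["end"]).any():
            raise ValueError("interval start exceeds end")

    def __len__(self) -> int:
        return len(self.records)

    def sorted(self) -> "IntervalSet":
        return IntervalSet(
            self.records.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        )


# ---------------------------------------------------------------------------
# VCF input / output


def _parse_region(region: str) -> tuple[str, int, int]:
    chrom, _, span = region.partition(":")
    if not span:
        return chrom, 0, np.iinfo(np.int64).max
    lo, _, hi = span.partition("-")
    # region strings are 1-based inclusive, like samtools
    return chrom, int(lo) - 1, int(hi)


def read_phased_haplotypes(path: str, region: str | None = None) -> HaplotypePanel:
    """Read a phased diploid VCF into a :class:`HaplotypePanel`.

    Multiallelic and non-SNP records are skipped (count logged).  An
    unphased genotype raises :class:`UnphasedGenotypeError`.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    want = _parse_region(region) if region else None

    rows: list[np.ndarray] = []
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    n_skipped = 0
    for v in vcf:
        if want is not None:
            pos0 = v.POS - 1
            if v.CHROM != want[0] or not (want[1] <= pos0 < want[2]):
                continue
        if len(v.ALT) != 1 or not v.is_snp:
            n_skipped += 1
            continue
        geno = np.array(v.genotypes)  # (n_samples, 3): a, b, phased
        if geno.shape[1] != 3:
            raise ValueError(f"non-diploid genotype at {v.CHROM}:{v.POS}")
        if not geno[:, 2].all():
            raise UnphasedGenotypeError(
                f"unphased genotype at {v.CHROM}:{v.POS} ({v.REF}>{v.ALT[0]})"
            )
        alleles = geno[:, :2].reshape(-1).astype(np.int8)  # -1 codes missing
        rows.append(alleles)
        chroms.append(v.CHROM)
        poss.append(v.POS - 1)
        refs.append(v.REF)
        alts.append(v.ALT[0])
    if n_skipped:
        logger.info("skipped %d multiallelic/non-SNP records", n_skipped)
    if want is not None and not rows:
        raise ValueError(f"no biallelic SNP records in region {region!r}")
    if rows:
        matrix = np.stack(rows, axis=1)
    else:
        matrix = np.empty((2 * len(samples), 0), dtype=np.int8)
    panel = HaplotypePanel(matrix, _site_frame(chroms, poss, refs, alts), samples)
    panel.skipped_records = n_skipped  # type: ignore[attr-defined]
    return panel


def write_vcf(panel: HaplotypePanel, path: str) -> None:
    """Write the panel as an uncompressed phased VCF (codes 0 = ref, 1 = alt)."""
    if panel.n_hap % 2:
        raise ValueError("VCF output requires diploid panels")
    ids = panel.sample_ids or [f"S{i}" for i in range(panel.n_hap // 2)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in panel.sites["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(ids) + "\n")
        H = panel.haplotypes
        for j, s in enumerate(panel.sites.itertuples(index=False)):
            calls = []
            for i in range(0, panel.n_hap, 2):
                a = "." if H[i, j] == MISSING else str(int(H[i, j]))
                b = "." if H[i + 1, j] == MISSING else str(int(H[i + 1, j]))
                calls.append(f"{a}|{b}")
            fh.write(
                f"{s.chrom}\t{s.pos + 1}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


# ---------------------------------------------------------------------------
# polarization


def read_ancestral_table(path: str) -> pd.DataFrame:
    """Read a TSV of (chrom, pos [1-based], ancestral allele)."""
    tab = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=["chrom", "pos", "allele"],
        dtype={"chrom": str, "pos": np.int64, "allele": str},
    )
    tab["pos"] -= 1
    return tab


def polarize_sites(
    panel: HaplotypePanel,
    ancestral: pd.DataFrame,
    max_missing: float = 0.10,
) -> HaplotypePanel:
    """Orient allele codes so 1 = derived wherever the ancestral allele is known.

    ``ancestral`` holds columns (chrom, pos, allele) with 0-based positions.
    Sites whose ancestral allele matches neither ref nor alt, or that have
    no ancestral call, come back with ``ancestral_known=False``; they stay
    usable for folded statistics.  ``derived_count``/``daf`` use non-missing
    haplotype counts; ``maf`` is filled for every site from the folded
    frequency.  Sites with more than ``max_missing`` missing haplotypes are
    dropped.

    The operation recomputes the orientation from the (ref, alt, ancestral)
    triple on every call, so applying it twice equals applying it once.
    """
    sites = panel.sites.copy()
    key = pd.MultiIndex.from_frame(sites[["chrom", "pos"]])
    anc = ancestral.drop_duplicates(["chrom", "pos"]).set_index(["chrom", "pos"])["allele"]
    anc_allele = anc.reindex(key).to_numpy(dtype=object)

    H = panel.haplotypes.copy()
    n_mismatch = 0
    known = np.zeros(len(sites), dtype=bool)
    flip = np.zeros(len(sites), dtype=bool)
    ref = sites["ref"].to_numpy(dtype=object)
    alt = sites["alt"].to_numpy(dtype=object)
    for j, a in enumerate(anc_allele):
        if a is None or (isinstance(a, float) and np.isnan(a)):
            continue
        if a == ref[j]:
            known[j] = True
        elif a == alt[j]:
            known[j] = True
            flip[j] = True
        else:
            n_mismatch += 1
    if n_mismatch:
        logger.info("%d sites with ancestral allele matching neither ref nor alt", n_mismatch)

    if flip.any():
        cols = np.flatnonzero(flip)
        block = H[:, cols]
        obs = block != MISSING
        block[obs] = 1 - block[obs]
        H[:, cols] = block
        sites.loc[flip, ["ref", "alt"]] = sites.loc[flip, ["alt", "ref"]].to_numpy()

    out = HaplotypePanel(H, sites, list(panel.sample_ids))
    ones, total = out.allele_counts()
    keep = total >= (1.0 - max_missing) * out.n_hap
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(total > 0, ones / np.maximum(total, 1), np.nan)
    sites = out.sites
    sites["ancestral_known"] = known
    sites["derived_count"] = np.where(known, ones, -1)
    sites["daf"] = np.where(known, freq, np.nan)
    sites["maf"] = np.minimum(freq, 1.0 - freq)
    out.n_ancestral_mismatch = n_mismatch  # type: ignore[attr-defined]
    if not keep.all():
        logger.info("dropping %d sites above the missingness ceiling", (~keep).sum())
        out = out.take_sites(np.flatnonzero(keep))
    return out


# ---------------------------------------------------------------------------
# windows and intervals


def build_window_grid(sites: pd.DataFrame, window_size: int, step: int | None = None) -> WindowGrid:
    """Tile each chromosome with windows anchored at coordinate 0.

    Windows start at ``0, step, 2*step, ...`` up to (and including) the last
    start not beyond the maximal observed site position, so every site is
    covered and, when ``step == window_size``, covered exactly once.
    """
    if step is None:
        step = window_size
    if step <= 0:
        raise ValueError("step must be positive")
    if step > window_size:
        raise ValueError("step cannot exceed window_size")
    recs = []
    for chrom in sites["chrom"].unique():
        max_pos = int(sites.loc[sites["chrom"] == chrom, "pos"].max())
        n_starts = max_pos // step + 1
        for k in range(n_starts):
            recs.append((chrom, k * step, k * step + window_size))
    frame = pd.DataFrame(recs, columns=["chrom", "start", "end"])
    return WindowGrid(frame, window_size, step)


def interval_overlap(regions: IntervalSet, features: IntervalSet) -> pd.DataFrame:
    """All pairs of (region, feature) records sharing >= 1 bp.

    Half-open semantics: [100, 200) does not overlap [200, 300).
    """
    out = []
    feats = features.records
    for chrom, freg in feats.groupby("chrom", sort=False):
        starts = freg["start"].to_numpy()
        ends = freg["end"].to_numpy()
        sub = regions.records[regions.records["chrom"] == chrom]
        for r in sub.itertuples():
            hit = (starts < r.end) & (ends > r.start)
            for fi in freg.index[hit]:
                out.append((r.Index, fi))
    pairs = pd.DataFrame(out, columns=["region_index", "feature_index"])
    return pairs.sort_values(["region_index", "feature_index"]).reset_index(drop=True)


def read_bed(path: str) -> IntervalSet:
    """Read a 3- or 4-column BED file (already 0-based half-open)."""
    tab = pd.read_csv(path, sep="\t", comment="#", header=None)
    if tab.shape[1] < 3:
        raise ValueError("BED needs at least 3 columns")
    tab = tab.iloc[:, :4] if tab.shape[1] >= 4 else tab.assign(name=".")
    tab.columns = ["chrom", "start", "end", "name"]
    tab["chrom"] = tab["chrom"].astype(str)
    return IntervalSet(tab)


def read_gff3(path: str, feature_types: list[str] | None = None) -> IntervalSet:
    """Read GFF3 features into half-open intervals (GFF is 1-based inclusive)."""
    tab = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "source", "type", "start", "end", "score", "strand", "phase", "attrs"],
        dtype={"chrom": str},
    )
    if feature_types:
        tab = tab[tab["type"].isin(feature_types)]
    name = tab["attrs"].str.extract(r"(?:ID|Name)=([^;]+)", expand=False).fillna(".")
    out = pd.DataFrame(
        {"chrom": tab["chrom"], "start": tab["start"] - 1, "end": tab["end"], "name": name}
    ).reset_index(drop=True)
    return IntervalSet(out)


# ---------------------------------------------------------------------------
# score tracks

TRACK_COLUMNS = ["chrom", "start", "end", "stat", "value", "n_sites", "emp_p"]


def write_track(track: pd.DataFrame, path: str) -> None:
    cols = [c for c in TRACK_COLUMNS if c in track.columns]
    track.to_csv(path, sep="\t", index=False, columns=cols, na_rep="NA")


def read_track(path: str) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"chrom": str})
    missing = {"chrom", "start", "end", "value"} - set(tab.columns)
    if missing:
        raise ValueError(f"track file lacks columns: {sorted(missing)}")
    return tab
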