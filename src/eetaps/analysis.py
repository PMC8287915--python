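"""Downstream methylation analytics.

mCpG designation and coverage criteria, window/region averaging, CpG-island
metaprofiles, moving averages, Pearson correlation, nested depth
down-sampling, fragment-end QC, in-silico MspI (reduced-representation)
digestion, and density-dependent bias characterisation.

Site sets are represented as ``{contig: sorted int64 array}`` mappings.
Region and window means are unweighted arithmetic means over covered sites,
matching how region methylation is assigned from per-site calls; a
depth-weighted alternative is available behind a flag.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .calling import CallerConfig, CpGCallTable, FragmentInterval, _attribute_array
from .errors import ParameterError
from .genome import CpGIndex, Methylome, ReferenceGenome, RegionSet

SiteSet = Mapping[str, np.ndarray]


@dataclasses.dataclass(frozen=True)
class McpgCriteria:
    """A CpG is methylated when level > min_level (strict) and
    cleaved_count >= min_cleaved."""

    min_level: float = 0.1
    min_cleaved: int = 1

    def __post_init__(self):
        if not 0.0 <= self.min_level <= 1.0 or self.min_cleaved < 0:
            raise ParameterError("invalid mCpG criteria")


@dataclasses.dataclass(frozen=True)
class CoverageCriteria:
    """Minimal depth for a site to count as covered: 1 for the enrichment
    assay (eeTAPS), 5 for quantitative assays (wgTAPS/rrTAPS)."""

    min_depth_enrichment: int = 1
    min_depth_quantitative: int = 5

    def __post_init__(self):
        if self.min_depth_enrichment < 1 or self.min_depth_quantitative < 1:
            raise ParameterError("coverage depths must be >= 1")


@dataclasses.dataclass(frozen=True)
class ComparisonStats:
    recall: float
    precision: float
    jaccard: float
    pearson_r: float = float("nan")


@dataclasses.dataclass(frozen=True)
class EndStats:
    cg_end_fraction: float
    on_cpg_fraction: float
    distance_histogram: dict
    n_ends: int


def designate_mcpgs(table: CpGCallTable,
                    criteria: McpgCriteria = McpgCriteria()) -> dict:
    """Sites passing the mCpG criteria (level strictly above the threshold)."""
    out = {}
    for c in table.index.contigs:
        lv = table.level(c)
        mask = (table.cleaved[c] >= criteria.min_cleaved) & \
               np.greater(np.nan_to_num(lv, nan=-1.0), criteria.min_level)
        out[c] = table.index[c][mask]
    return out


def covered_sites(table: CpGCallTable, min_depth: int = 1) -> dict:
    """Sites with depth >= min_depth."""
    return {c: table.index[c][table.depth(c) >= min_depth]
            for c in table.index.contigs}


def site_count(sites: SiteSet) -> int:
    return int(sum(len(v) for v in sites.values()))


def _window_frame(table: CpGCallTable, window_size: int,
                  contig_lengths: Mapping[str, int] | None,
                  values: Mapping[str, np.ndarray],
                  covered: Mapping[str, np.ndarray]) -> pd.DataFrame:
    lengths = contig_lengths if contig_lengths is not None else table.index.lengths
    rows = []
    for c in table.index.contigs:
        clen = lengths[c]
        n_windows = max(1, -(-clen // window_size))
        sums = np.zeros(n_windows)
        counts = np.zeros(n_windows, dtype=np.int64)
        pos = table.index[c]
        mask = covered[c]
        if mask.any():
            w = pos[mask] // window_size
            np.add.at(sums, w, values[c][mask])
            np.add.at(counts, w, 1)
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.where(counts > 0, counts, 1),
                             np.nan)
        for i in range(n_windows):
            rows.append((c, i * window_size, min((i + 1) * window_size, clen),
                         means[i], counts[i]))
    return pd.DataFrame(rows, columns=["contig", "start", "end", "mean", "n_sites"])


def window_means(table: CpGCallTable, window_size: int = 100_000,
                 contig_lengths: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Unweighted mean level of covered sites in non-overlapping tiling windows.

    Windows with no covered sites carry NaN (no value), not 0.
    """
    if window_size < 1:
        raise ParameterError("window_size must be >= 1")
    values = {c: np.nan_to_num(table.level(c)) for c in table.index.contigs}
    covered = {c: table.depth(c) > 0 for c in table.index.contigs}
    return _window_frame(table, window_size, contig_lengths, values, covered)


def region_means(table: CpGCallTable, regions: RegionSet,
                 depth_weighted: bool = False) -> pd.DataFrame:
    """Mean level over covered sites whose C lies in [start, end), per region."""
    rows = []
    for rec in regions:
        if rec.contig not in table.index:
            rows.append((rec.contig, rec.start, rec.end, rec.name, np.nan, 0))
            continue
        pos = table.index[rec.contig]
        lo = np.searchsorted(pos, rec.start, side="left")
        hi = np.searchsorted(pos, rec.end, side="left")
        lv = table.level(rec.contig)[lo:hi]
        ok = ~np.isnan(lv)
        if not ok.any():
            rows.append((rec.contig, rec.start, rec.end, rec.name, np.nan, 0))
            continue
        if depth_weighted:
            w = table.depth(rec.contig)[lo:hi][ok]
            mean = float(np.average(lv[ok], weights=w))
        else:
            mean = float(lv[ok].mean())
        rows.append((rec.contig, rec.start, rec.end, rec.name, mean, int(ok.sum())))
    return pd.DataFrame(rows, columns=["contig", "start", "end", "name",
                                       "mean", "n_sites"])


def metaprofile(table: CpGCallTable, regions: RegionSet, flank: int = 4000,
                n_body_bins: int = 20, n_flank_bins: int = 20) -> pd.DataFrame:
    """Mean level across scaled region bodies and fixed-width flanks.

    Bins 0..n_flank_bins-1 are the upstream flank, the next n_body_bins the
    region body (each region scaled to the same bin count), the rest the
    downstream flank.  Regions are unstranded.
    """
    if len(regions) == 0:
        raise ParameterError("region set is empty")
    n_bins = 2 * n_flank_bins + n_body_bins
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    flank_width = flank / n_flank_bins
    for rec in regions:
        if rec.contig not in table.index:
            continue
        pos = table.index[rec.contig]
        lv = table.level(rec.contig)
        lo = np.searchsorted(pos, rec.start - flank, side="left")
        hi = np.searchsorted(pos, rec.end + flank, side="left")
        for j in range(lo, hi):
            x = lv[j]
            if np.isnan(x):
                continue
            p = pos[j]
            if p < rec.start:
                b = int((p - (rec.start - flank)) // flank_width)
                b = min(max(b, 0), n_flank_bins - 1)
            elif p < rec.end:
                b = n_flank_bins + int((p - rec.start) * n_body_bins
                                       // (rec.end - rec.start))
                b = min(b, n_flank_bins + n_body_bins - 1)
            else:
                b = n_flank_bins + n_body_bins + int((p - rec.end) // flank_width)
                b = min(b, n_bins - 1)
            sums[b] += x
            counts[b] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.where(counts > 0, counts, 1), np.nan)
    zone = (["upstream"] * n_flank_bins + ["body"] * n_body_bins
            + ["downstream"] * n_flank_bins)
    return pd.DataFrame({"bin": np.arange(n_bins), "zone": zone,
                         "mean": means, "n_sites": counts})


def moving_average(series, bw: int = 10) -> np.ndarray:
    """Centered moving average of half-width ``bw`` (window 2*bw+1), truncated
    at the series ends; NaN entries are excluded from window means."""
    if bw < 1:
        raise ParameterError("bw must be >= 1")
    s = pd.Series(np.asarray(series, dtype=float))
    if s.empty:
        return np.array([])
    return s.rolling(2 * bw + 1, center=True, min_periods=1).mean().to_numpy()


def correlate(a, b) -> float:
    """Pearson correlation over positions valued (non-NaN) in both inputs;
    NaN when fewer than 2 shared observations or a side has zero variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ParameterError("inputs must be paired (equal length)")
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 2 or np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
        return float("nan")
    return float(sps.pearsonr(a[ok], b[ok]).statistic)


def subsample_fragments(fragments: Sequence, fraction: float,
                        seed: int = 0) -> list:
    """Bernoulli down-sampling with the nested property: for a fixed seed the
    retained set at fraction f1 is a subset of that at f2 >= f1 (one uniform
    draw per fragment, thresholded at the fraction)."""
    if not 0.0 <= fraction <= 1.0:
        raise ParameterError("fraction must lie in [0,1]")
    u = np.random.default_rng(seed).random(len(fragments))
    return [f for f, x in zip(fragments, u) if x < fraction]


def _intersect_count(a: SiteSet, b: SiteSet) -> int:
    n = 0
    for c in set(a) & set(b):
        n += len(np.intersect1d(a[c], b[c], assume_unique=True))
    return n


def detection_stats(called: SiteSet, truth: SiteSet,
                    called_levels=None, truth_levels=None) -> ComparisonStats:
    """Recall, precision and Jaccard of a called site set against truth."""
    inter = _intersect_count(called, truth)
    n_called = site_count(called)
    n_truth = site_count(truth)
    union = n_called + n_truth - inter
    recall = inter / n_truth if n_truth else float("nan")
    precision = inter / n_called if n_called else float("nan")
    jaccard = inter / union if union else float("nan")
    r = float("nan")
    if called_levels is not None and truth_levels is not None:
        r = correlate(called_levels, truth_levels)
    return ComparisonStats(recall, precision, jaccard, r)


def end_composition(fragments: Sequence, genome: ReferenceGenome,
                    cpg_index: CpGIndex,
                    config: CallerConfig = CallerConfig(),
                    max_distance: int = 50) -> EndStats:
    """QC on fragment ends: fraction whose canonical attribution base is C/G,
    signed distance from each end's canonical position to the nearest CpG,
    and the fraction landing exactly on a CpG."""
    seqs = {name: s for name, s in genome}
    n_ends = 0
    n_cg = 0
    hist: dict = {}
    n_on = 0
    by_contig: dict = {}
    for f in fragments:
        by_contig.setdefault(f.contig, []).append(f)
    for contig, frs in by_contig.items():
        seq = seqs[contig]
        pos = cpg_index[contig]
        canon = np.empty(2 * len(frs), dtype=np.int64)
        canon[0::2] = np.array([f.start for f in frs]) - config.dyad_gap
        canon[1::2] = np.array([f.end for f in frs])
        for cpos in canon:
            n_ends += 1
            base = seq[cpos] if 0 <= cpos < len(seq) else "N"
            if base in "CG":
                n_cg += 1
            if len(pos) == 0:
                continue
            i = np.searchsorted(pos, cpos)
            cands = []
            if i < len(pos):
                cands.append(int(pos[i]))
            if i > 0:
                cands.append(int(pos[i - 1]))
            nearest = min(cands, key=lambda p: (abs(cpos - p), p))
            d = int(cpos - nearest)
            if d == 0:
                n_on += 1
            d = max(-max_distance, min(max_distance, d))
            hist[d] = hist.get(d, 0) + 1
    if n_ends == 0:
        return EndStats(float("nan"), float("nan"), {}, 0)
    return EndStats(n_cg / n_ends, n_on / n_ends, dict(sorted(hist.items())),
                    n_ends)


def insilico_mspi(genome: ReferenceGenome, size_min: int = 100,
                  size_max: int = 400,
                  index: CpGIndex | None = None) -> tuple:
    """In-silico MspI digestion (cut C^CGG) with size selection.

    Returns (retained fragment intervals, covered CpG site set): covered
    sites are all CpG dyads fully inside retained fragments.  MspI cleaves
    without base loss, so retained + discarded lengths tile the genome.
    """
    if size_min > size_max:
        raise ParameterError("size_min must be <= size_max")
    idx = index if index is not None else CpGIndex.from_genome(genome)
    retained = []
    covered = {}
    for name, seq in genome:
        cuts = []
        ofs = seq.find("CCGG")
        while ofs != -1:
            cuts.append(ofs + 1)
            ofs = seq.find("CCGG", ofs + 1)
        bounds = [0] + cuts + [len(seq)]
        pos = idx[name]
        keep = np.zeros(len(pos), dtype=bool)
        for a, b in zip(bounds[:-1], bounds[1:]):
            if size_min <= b - a <= size_max:
                retained.append(FragmentInterval(name, a, b))
                lo = np.searchsorted(pos, a, side="left")
                hi = np.searchsorted(pos, b - 1, side="left")
                keep[lo:hi] = True
        covered[name] = pos[keep]
    return retained, covered


def mspi_fragments_all(genome: ReferenceGenome) -> list:
    """All MspI fragments (no size selection), for conservation checks."""
    out = []
    for name, seq in genome:
        cuts = []
        ofs = seq.find("CCGG")
        while ofs != -1:
            cuts.append(ofs + 1)
            ofs = seq.find("CCGG", ofs + 1)
        bounds = [0] + cuts + [len(seq)]
        out.extend(FragmentInterval(name, a, b)
                   for a, b in zip(bounds[:-1], bounds[1:]))
    return out


def density_bias(table: CpGCallTable, truth: Methylome, window_size: int = 10_000,
                 n_density_bins: int = 5,
                 contig_lengths: Mapping[str, int] | None = None,
                 mcpg_level: float = 0.1) -> pd.DataFrame:
    """Signed window-mean error (called - truth), binned by truth mCpG density.

    Truth mCpG density is the count of sites with truth level > mcpg_level
    per window; windows are split into ``n_density_bins`` quantile bins.
    """
    called = window_means(table, window_size, contig_lengths)
    lengths = contig_lengths if contig_lengths is not None else table.index.lengths
    rows = []
    for c in table.index.contigs:
        pos = table.index[c]
        lv = truth.level_array(c)
        clen = lengths[c]
        n_windows = max(1, -(-clen // window_size))
        t_sums = np.zeros(n_windows)
        t_counts = np.zeros(n_windows, dtype=np.int64)
        dens = np.zeros(n_windows, dtype=np.int64)
        if len(pos):
            w = pos // window_size
            np.add.at(t_sums, w, lv)
            np.add.at(t_counts, w, 1)
            np.add.at(dens, w, (lv > mcpg_level).astype(np.int64))
        with np.errstate(invalid="ignore"):
            t_means = np.where(t_counts > 0,
                               t_sums / np.where(t_counts > 0, t_counts, 1), np.nan)
        sub = called[called.contig == c]
        for i in range(n_windows):
            rows.append((c, i * window_size, t_means[i],
                         sub["mean"].to_numpy()[i], dens[i]))
    df = pd.DataFrame(rows, columns=["contig", "start", "truth_mean",
                                     "called_mean", "mcpg_density"])
    df["error"] = df["called_mean"] - df["truth_mean"]
    df = df.dropna(subset=["error"])
    if df.empty:
        return pd.DataFrame(columns=["density_bin", "mean_error", "n_windows"])
    if n_density_bins <= 1 or df["mcpg_density"].nunique() == 1:
        df["density_bin"] = 0
    else:
        df["density_bin"] = pd.qcut(df["mcpg_density"],
                                    min(n_density_bins,
                                        df["mcpg_density"].nunique()),
                                    labels=False, duplicates="drop")
    out = df.groupby("density_bin").agg(
        mean_error=("error", "mean"), n_windows=("error", "size"),
        mean_density=("mcpg_density", "mean")).reset_index()
    return out
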