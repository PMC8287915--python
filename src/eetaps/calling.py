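"""Cleavage-fraction methylation calling from paired-end alignments.

The methylation level of a CpG site is the fraction of fragments that were
cleaved at the site among all fragments that were cleaved at or read
through the site:

    level = cleaved_count / (cleaved_count + readthrough_count)

Fragment intervals are reconstructed from properly paired alignments (read 1
flag 83 or 99, template span).  A fragment's left endpoint ``s`` attributes
cleavage to the CpG whose C sits at ``s - dyad_gap`` and its right
(exclusive) endpoint ``e`` to the CpG at ``e``; when no CpG sits exactly at
the canonical position, the nearest CpG within ``offset_window`` bp is used
(ties resolve to the smaller coordinate).  Endpoints matching no CpG are
treated as shear/molecule ends and contribute no cleavage evidence.  Every
CpG dyad fully interior to the fragment and not attributed to one of its
endpoints counts as read-through.  Sites with zero depth are reported as
uncovered, never as level 0.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import FormatError, ParameterError
from .genome import CpGIndex

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class FragmentInterval:
    """The template span of one properly paired read pair (0-based half-open)."""

    contig: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclasses.dataclass(frozen=True)
class CallerConfig:
    accepted_read1_flags: frozenset = frozenset({83, 99})
    offset_window: int = 2
    dyad_gap: int = 2
    min_mapq: int = 0

    def __post_init__(self):
        if self.offset_window < 0 or self.dyad_gap < 0:
            raise ParameterError("offset_window and dyad_gap must be >= 0")


class CpGCallTable:
    """Per-CpG cleaved and read-through counts with derived methylation levels."""

    def __init__(self, index: CpGIndex,
                 cleaved: Mapping[str, np.ndarray] | None = None,
                 readthrough: Mapping[str, np.ndarray] | None = None):
        self.index = index
        self.cleaved = {c: (np.zeros(len(index[c]), dtype=np.int64)
                            if cleaved is None else
                            np.asarray(cleaved[c], dtype=np.int64))
                        for c in index.contigs}
        self.readthrough = {c: (np.zeros(len(index[c]), dtype=np.int64)
                                if readthrough is None else
                                np.asarray(readthrough[c], dtype=np.int64))
                            for c in index.contigs}
        for c in index.contigs:
            if (self.cleaved[c] < 0).any() or (self.readthrough[c] < 0).any():
                raise ParameterError("counts must be non-negative")

    def depth(self, contig: str) -> np.ndarray:
        return self.cleaved[contig] + self.readthrough[contig]

    def level(self, contig: str) -> np.ndarray:
        """Cleavage fraction; NaN where depth is zero (uncovered)."""
        cl = self.cleaved[contig].astype(float)
        depth = self.depth(contig).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            lv = np.where(depth > 0, cl / np.where(depth > 0, depth, 1), np.nan)
        return lv

    def merged_with(self, other: "CpGCallTable") -> "CpGCallTable":
        """Counts are additive, so batch tallies merge exactly."""
        return CpGCallTable(
            self.index,
            {c: self.cleaved[c] + other.cleaved[c] for c in self.index.contigs},
            {c: self.readthrough[c] + other.readthrough[c] for c in self.index.contigs},
        )

    def to_dataframe(self, include_uncovered: bool = False) -> pd.DataFrame:
        frames = []
        for c in self.index.contigs:
            pos = self.index[c]
            depth = self.depth(c)
            df = pd.DataFrame({
                "contig": c, "start": pos, "end": pos + 2,
                "level": self.level(c),
                "cleaved_count": self.cleaved[c],
                "readthrough_count": self.readthrough[c],
            })
            if not include_uncovered:
                df = df[depth > 0]
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def to_tsv(self, path, include_uncovered: bool = False) -> None:
        df = self.to_dataframe(include_uncovered)
        df["level"] = df["level"].map(
            lambda x: "NA" if np.isnan(x) else f"{x:.6f}")
        df.to_csv(path, sep="\t", index=False)

    def to_bedgraph(self, path) -> None:
        df = self.to_dataframe(include_uncovered=False)
        df[["contig", "start", "end", "level"]].to_csv(
            path, sep="\t", header=False, index=False,
            float_format="%.6f")

    @classmethod
    def from_tsv(cls, path, index: CpGIndex) -> "CpGCallTable":
        df = pd.read_csv(path, sep="\t", dtype={"contig": str})
        table = cls(index)
        for c, sub in df.groupby("contig"):
            pos = index[c]
            idx = np.searchsorted(pos, sub["start"].to_numpy())
            table.cleaved[c][idx] = sub["cleaved_count"].to_numpy()
            table.readthrough[c][idx] = sub["readthrough_count"].to_numpy()
        return table


def load_fragments(path, config: CallerConfig = CallerConfig()) -> list:
    """Extract fragment intervals from a SAM/BAM file.

    Keeps one interval per properly paired read pair (read 1 with an
    accepted flag, default {83, 99}); the interval is the template span from
    the leftmost mapped base of the pair to the rightmost.  Records below
    ``min_mapq`` are dropped; zero/negative template spans are skipped with
    a warning.
    """
    out = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        if not fh.header.get("SQ"):
            raise FormatError("alignment stream lacks contig (@SQ) header lines")
        clens = {sq["SN"]: sq["LN"] for sq in fh.header["SQ"]}
        for rec in fh:
            if rec.flag not in config.accepted_read1_flags:
                continue
            if rec.mapping_quality < config.min_mapq:
                continue
            tlen = rec.template_length
            if tlen > 0:
                start = rec.reference_start
                end = start + tlen
            elif tlen < 0:
                start = rec.next_reference_start
                end = start - tlen
            else:
                logger.warning("skipping %s: zero template span", rec.query_name)
                continue
            contig = rec.reference_name
            if start < 0 or end > clens.get(contig, -1):
                logger.warning("skipping %s: span outside contig", rec.query_name)
                continue
            out.append(FragmentInterval(contig, start, end))
    return out


def intervals_from_fragments(fragments: Iterable) -> list:
    """Truth shortcut: simulator fragments as caller input, bypassing alignment."""
    return [FragmentInterval(f.contig, f.start, f.end) for f in fragments]


def _attribute_array(canonical: np.ndarray, pos: np.ndarray,
                     window: int) -> np.ndarray:
    """Index into ``pos`` of the attributed CpG per canonical position, -1 if none.

    Exact matches win; otherwise the nearest CpG within +-window, ties to
    the smaller coordinate.
    """
    n = len(pos)
    res = np.full(len(canonical), -1, dtype=np.int64)
    if n == 0:
        return res
    idx = np.searchsorted(pos, canonical)
    big = np.iinfo(np.int64).max
    right = np.clip(idx, 0, n - 1)
    dist_r = np.where(idx < n, pos[right] - canonical, big)
    left = np.clip(idx - 1, 0, n - 1)
    dist_l = np.where(idx > 0, canonical - pos[left], big)
    take_left = (dist_l <= dist_r) & (dist_l <= window)
    take_right = (dist_r < dist_l) & (dist_r <= window)
    res[take_left] = left[take_left]
    res[take_right] = right[take_right]
    return res


def attribute_endpoints(fragment: FragmentInterval, cpg_index: CpGIndex,
                        config: CallerConfig = CallerConfig()) -> tuple:
    """Attribute a fragment's endpoints to CpG sites; returns (left, right)
    site positions or None where no CpG lies within the tolerance window."""
    pos = cpg_index[fragment.contig]
    canon = np.array([fragment.start - config.dyad_gap, fragment.end])
    idx = _attribute_array(canon, pos, config.offset_window)
    left = int(pos[idx[0]]) if idx[0] >= 0 else None
    right = int(pos[idx[1]]) if idx[1] >= 0 else None
    return left, right


def tally(fragments: Sequence, cpg_index: CpGIndex,
          config: CallerConfig = CallerConfig()) -> CpGCallTable:
    """Count cleaved endpoints and read-through coverage per CpG site.

    Per fragment: each attributed endpoint site gains one cleaved count
    (a site attributed by both endpoints of the same fragment is counted
    once); every CpG dyad fully inside the span, excluding attributed
    endpoint sites, gains one read-through count.  Results are invariant to
    fragment order and to splitting the input into batches.
    """
    table = CpGCallTable(cpg_index)
    by_contig = defaultdict(list)
    for f in fragments:
        by_contig[f.contig].append(f)
    for contig, frs in by_contig.items():
        if contig not in cpg_index:
            continue
        pos = cpg_index[contig]
        nc = len(pos)
        starts = np.array([f.start for f in frs], dtype=np.int64)
        ends = np.array([f.end for f in frs], dtype=np.int64)
        li = _attribute_array(starts - config.dyad_gap, pos, config.offset_window)
        ri = _attribute_array(ends, pos, config.offset_window)
        ri = np.where((ri == li) & (ri >= 0), -1, ri)  # dedup within fragment
        # interior dyads: start <= p and p + 2 <= end
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends - 1, side="left")
        hi = np.maximum(hi, lo)
        diff = np.zeros(nc + 1, dtype=np.int64)
        np.add.at(diff, lo, 1)
        np.add.at(diff, hi, -1)
        rt = np.cumsum(diff[:-1])
        cleaved = np.zeros(nc, dtype=np.int64)
        for arr in (li, ri):
            hit = arr >= 0
            np.add.at(cleaved, arr[hit], 1)
            inside = hit & (arr >= lo) & (arr < hi)
            np.add.at(rt, arr[inside], -1)
        table.cleaved[contig] += cleaved
        table.readthrough[contig] += rt
    return table


def methylation_levels(table: CpGCallTable) -> CpGCallTable:
    """Levels are derived from counts on demand; returns the table unchanged.

    Kept as an explicit pipeline step: level = cleaved/(cleaved+readthrough)
    where depth > 0, NaN (uncovered) elsewhere — see CpGCallTable.level.
    """
    return table


def call_pipeline(alignments_path, genome, config: CallerConfig = CallerConfig(),
                  index: CpGIndex | None = None) -> CpGCallTable:
    """SAM/BAM -> fragment intervals -> tallied, levelled call table."""
    idx = index if index is not None else CpGIndex.from_genome(genome)
    fragments = load_fragments(alignments_path, config)
    return methylation_levels(tally(fragments, idx, config))
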