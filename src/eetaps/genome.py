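"""Synthetic reference genomes, CpG indexes, region tracks and methylomes.

The generator emits genomes from a first-order (dinucleotide) Markov chain
whose stationary composition matches a requested GC fraction and whose
observed/expected CpG dinucleotide ratio equals ``cpg_depletion`` (1.0 means
no depletion, 0.0 means CG never occurs).  CpG-island-like behaviour comes
from the methylome assignment — sites inside an annotated region track draw
their methylation level from a low-mean Beta distribution, all other sites
from a high-mean one — not from local sequence composition.

Coordinates are 0-based, half-open throughout; a CpG site is identified by
the position of the C on the plus strand and calls are per dyad (both
strands combined).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.optimize import brentq

from .errors import DegenerateInputError, ParameterError, PlacementError

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = 0, 1, 2, 3

BetaParams = Union[float, tuple]


@dataclasses.dataclass(frozen=True)
class ReferenceGenome:
    """An ordered collection of named contig sequences over {A,C,G,T}."""

    contigs: tuple  # tuple of (name, sequence)

    def __post_init__(self):
        names = [n for n, _ in self.contigs]
        if len(names) != len(set(names)):
            raise ParameterError("contig names must be unique")
        for name, seq in self.contigs:
            if not name or not seq:
                raise ParameterError("contig names and sequences must be non-empty")
            if seq != seq.upper():
                raise ParameterError(f"sequence of {name} must be uppercase")

    @property
    def names(self) -> list:
        return [n for n, _ in self.contigs]

    @property
    def lengths(self) -> dict:
        return {n: len(s) for n, s in self.contigs}

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.contigs)

    def sequence(self, contig: str) -> str:
        for n, s in self.contigs:
            if n == contig:
                return s
        raise KeyError(contig)

    def __iter__(self):
        return iter(self.contigs)

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="") for name, seq in self.contigs
        ]
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
            writer.write_file(records)

    @classmethod
    def from_fasta(cls, path) -> "ReferenceGenome":
        contigs = tuple(
            (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
        )
        if not contigs:
            raise ParameterError(f"no sequences found in {path}")
        return cls(contigs)


class CpGIndex:
    """Sorted plus-strand C positions of every CG dinucleotide, per contig."""

    def __init__(self, positions: Mapping[str, np.ndarray], lengths: Mapping[str, int]):
        self.positions = {
            c: np.asarray(p, dtype=np.int64) for c, p in positions.items()
        }
        self.lengths = dict(lengths)
        for c, p in self.positions.items():
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                raise ParameterError(f"CpG positions on {c} must be strictly increasing")

    @classmethod
    def from_genome(cls, genome: ReferenceGenome) -> "CpGIndex":
        positions = {}
        for name, seq in genome:
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            hits = np.where((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))[0]
            positions[name] = hits.astype(np.int64)
        return cls(positions, genome.lengths)

    def __getitem__(self, contig: str) -> np.ndarray:
        return self.positions[contig]

    def __contains__(self, contig: str) -> bool:
        return contig in self.positions

    @property
    def contigs(self) -> list:
        return list(self.positions)

    @property
    def n_sites(self) -> int:
        return int(sum(len(p) for p in self.positions.values()))

    def sites_in(self, contig: str, start: int, end: int) -> np.ndarray:
        """Positions p with start <= p < end on a contig."""
        pos = self.positions[contig]
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        return pos[lo:hi]


class RegionSet:
    """BED-style 0-based half-open intervals, sorted by (contig, start)."""

    def __init__(self, records: Iterable):
        rows = [(c, int(s), int(e), str(n)) for c, s, e, n in records]
        rows.sort(key=lambda r: (r[0], r[1]))
        for c, s, e, _ in rows:
            if s >= e:
                raise ParameterError(f"region on {c} has start {s} >= end {e}")
            if s < 0:
                raise ParameterError("region start must be >= 0")
        self.df = pd.DataFrame(rows, columns=["contig", "start", "end", "name"])

    def __len__(self):
        return len(self.df)

    def __iter__(self):
        return iter(self.df.itertuples(index=False))

    def on(self, contig: str) -> pd.DataFrame:
        return self.df[self.df.contig == contig]

    def to_bed(self, path) -> None:
        self.df.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path) -> "RegionSet":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["contig", "start", "end", "name"],
            usecols=[0, 1, 2, 3], dtype={0: str, 3: str},
        )
        return cls(df.itertuples(index=False, name=None))


class Methylome:
    """Ground-truth methylation level in [0,1] for every CpG site.

    Levels are stored as per-contig arrays aligned with a :class:`CpGIndex`,
    so the domain is by construction the full CpG universe.  The level is
    the total TAPS-convertible modification (5mC + 5hmC, not distinguished).
    """

    def __init__(self, index: CpGIndex, levels: Mapping[str, np.ndarray]):
        self.index = index
        self.levels = {c: np.asarray(v, dtype=float) for c, v in levels.items()}
        for c in index.contigs:
            v = self.levels[c]
            if len(v) != len(index[c]):
                raise ParameterError(f"level array on {c} does not match CpG index")
            if len(v) and (v.min() < 0 or v.max() > 1):
                raise ParameterError("methylation levels must lie in [0,1]")

    def level_array(self, contig: str) -> np.ndarray:
        return self.levels[contig]

    def levels_at(self, contig: str, positions: np.ndarray) -> np.ndarray:
        """Levels for given site positions (must all be CpG sites)."""
        pos = self.index[contig]
        idx = np.searchsorted(pos, positions)
        if np.any(idx >= len(pos)) or np.any(pos[np.clip(idx, 0, len(pos) - 1)] != positions):
            raise ParameterError("some positions are not CpG sites")
        return self.levels[contig][idx]

    def truth_sites(self, min_level: float = 0.1) -> dict:
        """Sites with level strictly above ``min_level`` (the mCpG truth set)."""
        return {
            c: self.index[c][self.levels[c] > min_level] for c in self.index.contigs
        }

    def to_tsv(self, path) -> None:
        frames = []
        for c in self.index.contigs:
            pos = self.index[c]
            frames.append(pd.DataFrame({
                "contig": c, "start": pos, "end": pos + 2,
                "level": np.round(self.levels[c], 6),
            }))
        pd.concat(frames, ignore_index=True).to_csv(
            path, sep="\t", header=False, index=False
        )

    @classmethod
    def from_tsv(cls, path, index: CpGIndex) -> "Methylome":
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["contig", "start", "end", "level"], dtype={0: str},
        )
        levels = {}
        for c in index.contigs:
            sub = df[df.contig == c].sort_values("start")
            pos = sub["start"].to_numpy(dtype=np.int64)
            if len(pos) != len(index[c]) or np.any(pos != index[c]):
                raise ParameterError(f"methylome TSV does not cover CpG index on {c}")
            levels[c] = sub["level"].to_numpy(dtype=float)
        return cls(index, levels)


def _base_probs(gc_fraction: float) -> np.ndarray:
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    return np.array([at, gc, gc, at])


def _transition_matrix(q: np.ndarray, f: float) -> np.ndarray:
    """Markov transitions: each row is q, except C->G is reweighted by f with
    the removed mass redistributed over {A,C,T} proportionally to q."""
    T = np.tile(q, (4, 1))
    row = q.copy()
    row[_G] = f * q[_G]
    others = q.copy()
    others[_G] = 0.0
    if others.sum() > 0:
        row[[_A, _C, _T]] = others[[_A, _C, _T]] / others.sum() * (1.0 - row[_G])
    T[_C] = row
    return T


def _stationary(T: np.ndarray) -> np.ndarray:
    # left eigenvector for eigenvalue 1, via a bordered linear system
    A = np.vstack([T.T - np.eye(4), np.ones(4)])
    b = np.zeros(5)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


def _solve_cpg_weight(q: np.ndarray, depletion: float) -> float:
    """Find the C->G transition weight whose stationary observed/expected CpG
    ratio equals ``depletion``.

    O/E = pi_C * P(G|C) / (pi_C * pi_G) = f*q_G / pi_G(f); renormalisation
    shifts pi_G, so the weight must be solved rather than set to depletion.
    """
    if depletion in (0.0, 1.0) or q[_C] == 0 or q[_G] == 0:
        return depletion

    def gap(f):
        pi = _stationary(_transition_matrix(q, f))
        return f * q[_G] / pi[_G] - depletion

    return float(brentq(gap, 0.0, 1.0, xtol=1e-12))


def _sample_chain(length: int, T: np.ndarray, pi: np.ndarray,
                  rng: np.random.Generator) -> str:
    cum = np.cumsum(T, axis=1)
    cum[:, -1] = 1.0  # guard against round-off
    rows = [tuple(cum[i][:3]) for i in range(4)]
    u = rng.random(length)
    out = np.empty(length, dtype=np.uint8)
    state = int(rng.choice(4, p=pi))
    for i in range(length):
        c0, c1, c2 = rows[state]
        x = u[i]
        state = 0 if x < c0 else 1 if x < c1 else 2 if x < c2 else 3
        out[i] = _BASES[state]
    return out.tobytes().decode("ascii")


def generate_genome(total_length: int, n_contigs: int = 1, gc_fraction: float = 0.5,
                    cpg_depletion: float = 1.0, seed: int = 0) -> ReferenceGenome:
    """Generate a seeded random genome with a target CpG observed/expected ratio.

    Parameters
    ----------
    total_length
        Total bases across all contigs (split near-evenly).
    n_contigs
        Number of contigs, named ``chr1..chrN``.
    gc_fraction
        Stationary G+C fraction of the background composition.
    cpg_depletion
        Target observed/expected CpG dinucleotide ratio; 1.0 = no depletion,
        0.0 = CG never emitted.  Mammalian genomes sit around 0.2-0.25.
    seed
        RNG seed; identical parameters and seed give identical sequences.
    """
    if n_contigs < 1 or total_length < n_contigs:
        raise ParameterError("need total_length >= n_contigs >= 1")
    if not (0.0 <= gc_fraction <= 1.0 and 0.0 <= cpg_depletion <= 1.0):
        raise ParameterError("gc_fraction and cpg_depletion must lie in [0,1]")
    q = _base_probs(gc_fraction)
    f = _solve_cpg_weight(q, cpg_depletion)
    T = _transition_matrix(q, f)
    pi = _stationary(T)
    rng = np.random.default_rng(seed)
    base = total_length // n_contigs
    lengths = [base + (1 if i < total_length % n_contigs else 0)
               for i in range(n_contigs)]
    contigs = tuple(
        (f"chr{i + 1}", _sample_chain(lengths[i], T, pi, rng))
        for i in range(n_contigs)
    )
    return ReferenceGenome(contigs)


def expected_cpg_ratio(gc_fraction: float, cpg_depletion: float) -> float:
    """Stationary observed/expected CpG ratio of the generator (= cpg_depletion)."""
    q = _base_probs(gc_fraction)
    f = _solve_cpg_weight(q, cpg_depletion)
    pi = _stationary(_transition_matrix(q, f))
    if pi[_G] == 0 or pi[_C] == 0:
        return float("nan")
    return float(f * q[_G] / pi[_G])


def observed_cpg_ratio(genome: ReferenceGenome) -> float:
    """Observed/expected CpG ratio by direct mono/dinucleotide counting."""
    n_cg = n_c = n_g = n = n_di = 0
    for _, seq in genome:
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        n_cg += int(np.sum((arr[:-1] == ord("C")) & (arr[1:] == ord("G"))))
        n_c += int(np.sum(arr == ord("C")))
        n_g += int(np.sum(arr == ord("G")))
        n += len(arr)
        n_di += len(arr) - 1
    if n_c == 0 or n_g == 0:
        return float("nan")
    return (n_cg / n_di) / ((n_c / n) * (n_g / n))


def place_regions(genome: ReferenceGenome, n_regions: int, mean_length: int,
                  min_gap: int = 0, seed: int = 0,
                  length_sd: float | None = None) -> RegionSet:
    """Place non-overlapping CGI-like regions separated by at least ``min_gap``.

    Region lengths are drawn from a normal with mean ``mean_length`` and sd
    ``length_sd`` (default mean/10), floored at 2 bp so a region can hold a
    CpG dyad.  Regions are assigned to contigs with probability proportional
    to contig length and placed uniformly in the remaining slack.
    """
    if n_regions < 1 or mean_length < 2 or min_gap < 0:
        raise ParameterError("need n_regions >= 1, mean_length >= 2, min_gap >= 0")
    if n_regions * (mean_length + min_gap) > genome.total_length:
        raise PlacementError("regions cannot fit: n x (mean_length + min_gap) "
                             "exceeds genome length")
    rng = np.random.default_rng(seed)
    sd = mean_length / 10.0 if length_sd is None else length_sd
    lengths = np.maximum(2, np.round(rng.normal(mean_length, sd, n_regions))).astype(int)
    clens = genome.lengths
    names = genome.names
    weights = np.array([clens[c] for c in names], dtype=float)
    weights /= weights.sum()
    for _ in range(200):
        assign = rng.choice(len(names), size=n_regions, p=weights)
        ok = True
        for ci in range(len(names)):
            ls = lengths[assign == ci]
            if len(ls) and ls.sum() + (len(ls) - 1) * min_gap > clens[names[ci]]:
                ok = False
                break
        if ok:
            break
    else:
        raise PlacementError("could not assign regions to contigs without overflow")
    records = []
    k = 0
    for ci, contig in enumerate(names):
        ls = lengths[assign == ci]
        m = len(ls)
        if m == 0:
            continue
        slack = clens[contig] - int(ls.sum()) - (m - 1) * min_gap
        extra = rng.multinomial(slack, np.full(m + 1, 1.0 / (m + 1)))
        start = 0
        for j in range(m):
            start += int(extra[j])
            records.append((contig, start, start + int(ls[j]), f"region_{k}"))
            k += 1
            start += int(ls[j]) + min_gap
    return RegionSet(records)


def _draw_levels(params: BetaParams, size: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(params, (int, float)):
        lvl = float(params)
        if not 0.0 <= lvl <= 1.0:
            raise ParameterError("constant methylation level must lie in [0,1]")
        return np.full(size, lvl)
    a, b = params
    if a <= 0 or b <= 0:
        raise ParameterError("beta shape parameters must be > 0")
    return rng.beta(a, b, size)


def sample_methylome(genome: ReferenceGenome, cgi_like: RegionSet | None = None,
                     background_params: BetaParams = (8.0, 2.0),
                     region_params: BetaParams = (1.0, 9.0),
                     seed: int = 0,
                     index: CpGIndex | None = None) -> Methylome:
    """Draw a ground-truth methylome: Beta-distributed levels, low inside
    CGI-like regions (default mean 0.1) and high elsewhere (default mean 0.8).

    A float may be passed instead of a shape pair to pin levels to a constant
    (the point-mass limit).
    """
    idx = index if index is not None else CpGIndex.from_genome(genome)
    if idx.n_sites == 0:
        raise DegenerateInputError("genome contains no CpG sites")
    rng = np.random.default_rng(seed)
    levels = {}
    for contig in idx.contigs:
        pos = idx[contig]
        lv = _draw_levels(background_params, len(pos), rng)
        if cgi_like is not None:
            in_region = np.zeros(len(pos), dtype=bool)
            for rec in cgi_like.on(contig).itertuples(index=False):
                lo = np.searchsorted(pos, rec.start, side="left")
                hi = np.searchsorted(pos, rec.end, side="left")
                in_region[lo:hi] = True
            if in_region.any():
                lv[in_region] = _draw_levels(region_params, int(in_region.sum()), rng)
        levels[contig] = lv
    return Methylome(idx, levels)
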