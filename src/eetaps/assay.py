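"""Simulation of the eeTAPS assay.

Models the wet-lab chain: high-molecular-weight input molecules sampled
from the genome, TAPS conversion of methylated CpG dyads to dihydrouracil
(DHU), USER (UDG + Endonuclease VIII) double-strand cleavage at converted
dyads with NCG-context-dependent efficiency, size selection, and paired-end
read emission with ground-truth alignments.

Conventions shared with the caller:

* Methylation is symmetric across the CpG dyad; one Bernoulli per site per
  molecule decides conversion and one decides cleavage (no per-strand
  nicking model).
* A double-strand break at CpG site ``i`` excises the 2-base dyad: the
  upstream fragment ends at ``i`` (exclusive) and the downstream fragment
  starts at ``i + dyad_gap`` (default 2).  Exact length conservation,
  sum(fragment lengths) + dyad_gap * cuts == molecule length, holds for
  dyad_gap <= 2 (CpG sites can be as close as 2 bp).
* Molecule ends are tracked separately from cleavage ends in the truth
  output; in real data they are indistinguishable.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pysam

from .errors import DegenerateInputError, ParameterError
from .genome import CpGIndex, Methylome, ReferenceGenome

CLEAVAGE = "cleavage"
MOLECULE_END = "molecule_end"

#: USER cleavage efficiencies on single-mCpG model DNA by NCG context.
#: ACG and TCG are measured values; CCG and GCG default to the overall
#: USER efficiency (0.85) and are configurable.
DEFAULT_CONTEXT_EFFICIENCY = {"ACG": 0.924, "CCG": 0.85, "GCG": 0.85, "TCG": 0.826}
DEFAULT_OVERALL_EFFICIENCY = 0.85


@dataclasses.dataclass(frozen=True)
class EfficiencyModel:
    """Probabilities governing conversion and cleavage chemistry."""

    conversion_rate: float = 1.0
    false_conversion_rate: float = 0.0
    cleavage_by_context: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CONTEXT_EFFICIENCY))
    default_cleavage: float = DEFAULT_OVERALL_EFFICIENCY
    context_dependent: bool = True

    def __post_init__(self):
        probs = [self.conversion_rate, self.false_conversion_rate,
                 self.default_cleavage, *self.cleavage_by_context.values()]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ParameterError("all efficiency-model probabilities must lie in [0,1]")
        missing = {"ACG", "CCG", "GCG", "TCG"} - set(self.cleavage_by_context)
        if missing:
            raise ParameterError(f"context map missing {sorted(missing)}")

    def cleavage_prob(self, context: str | None) -> float:
        if not self.context_dependent or context not in self.cleavage_by_context:
            return self.default_cleavage
        return self.cleavage_by_context[context]


@dataclasses.dataclass(frozen=True)
class Molecule:
    """An un-fragmented input DNA molecule (0-based half-open interval)."""

    id: int
    contig: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclasses.dataclass(frozen=True)
class ConvertedMolecule:
    """A molecule after TAPS conversion; dhu_sites are CpG positions carrying DHU."""

    molecule: Molecule
    dhu_sites: tuple


@dataclasses.dataclass(frozen=True)
class Fragment:
    """A piece of a digested molecule; endpoints carry the methylation signal."""

    contig: str
    start: int
    end: int
    left_end_kind: str
    right_end_kind: str
    molecule_id: int
    left_site: int | None = None
    right_site: int | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclasses.dataclass(frozen=True)
class SimReadPair:
    name: str
    fragment: Fragment
    read1: str
    read2: str
    qual1: str
    qual2: str
    r1_reverse: bool  # True: read 1 sequenced from the minus strand (flag 83)


def sample_molecules(genome: ReferenceGenome, n: int,
                     length_distribution: tuple = (20000, 5000, 500),
                     seed: int = 0) -> list:
    """Sample molecules uniformly over the genome, truncated at contig ends.

    ``length_distribution`` is (mean, sd, min) in bp.  Contigs are chosen
    with probability proportional to length and start positions are uniform.
    """
    mean, sd, min_len = length_distribution
    if min_len < 1:
        raise ParameterError("minimum molecule length must be >= 1")
    if n < 0:
        raise ParameterError("n must be >= 0")
    lengths = genome.lengths
    if mean > max(lengths.values()):
        raise DegenerateInputError(
            "mean molecule length exceeds every contig length")
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    names = genome.names
    weights = np.array([lengths[c] for c in names], dtype=float)
    weights /= weights.sum()
    which = rng.choice(len(names), size=n, p=weights)
    ls = np.maximum(min_len, np.round(rng.normal(mean, sd, n))).astype(np.int64)
    out = []
    for i in range(n):
        contig = names[int(which[i])]
        clen = lengths[contig]
        length = int(min(ls[i], clen))
        start = int(rng.integers(0, clen - length + 1))
        out.append(Molecule(i, contig, start, start + length))
    return out


def whole_contig_molecules(genome: ReferenceGenome, copies: int = 1) -> list:
    """One molecule spanning each contig, repeated ``copies`` times.

    Mirrors the assay's un-fragmented genomic input; useful when shear ends
    must not fall near CpG sites.
    """
    if copies < 1:
        raise ParameterError("copies must be >= 1")
    out = []
    i = 0
    for name, seq in genome:
        for _ in range(copies):
            out.append(Molecule(i, name, 0, len(seq)))
            i += 1
    return out


def convert(molecule: Molecule, methylome: Methylome, model: EfficiencyModel,
            rng: np.random.Generator | int = 0) -> ConvertedMolecule:
    """TAPS conversion: each CpG dyad in the molecule becomes DHU with
    probability m*conversion_rate + (1-m)*false_conversion_rate."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sites = methylome.index.sites_in(molecule.contig, molecule.start,
                                     molecule.end - 1)
    if len(sites) == 0:
        return ConvertedMolecule(molecule, ())
    m = methylome.levels_at(molecule.contig, sites)
    p = m * model.conversion_rate + (1.0 - m) * model.false_conversion_rate
    hit = rng.random(len(sites)) < p
    return ConvertedMolecule(molecule, tuple(int(s) for s in sites[hit]))


def digest(converted: ConvertedMolecule, genome: ReferenceGenome,
           model: EfficiencyModel, dyad_gap: int = 2,
           rng: np.random.Generator | int = 0) -> list:
    """USER digestion: each DHU dyad cleaves independently with the
    context-dependent probability; a cut at site ``i`` splits [a,b) into
    [a,i) and [i+dyad_gap,b).  Zero-length pieces (adjacent cuts) are dropped.
    """
    if dyad_gap < 0:
        raise ParameterError("dyad_gap must be >= 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    mol = converted.molecule
    seq = genome.sequence(mol.contig)
    cuts = []
    for site in converted.dhu_sites:
        context = seq[site - 1: site + 2] if site >= 1 else None
        if rng.random() < model.cleavage_prob(context):
            cuts.append(site)
    fragments = []
    prev_start = mol.start
    prev_kind, prev_site = MOLECULE_END, None
    for site in cuts:
        if site > prev_start:
            fragments.append(Fragment(mol.contig, prev_start, site, prev_kind,
                                      CLEAVAGE, mol.id, prev_site, site))
        prev_start = site + dyad_gap
        prev_kind, prev_site = CLEAVAGE, site
    if mol.end > prev_start:
        fragments.append(Fragment(mol.contig, prev_start, mol.end, prev_kind,
                                  MOLECULE_END, mol.id, prev_site, None))
    return fragments


def run_digestion(molecules: Sequence, methylome: Methylome,
                  genome: ReferenceGenome, model: EfficiencyModel | None = None,
                  dyad_gap: int = 2, seed: int = 0) -> list:
    """Convert and digest a batch of molecules with one RNG stream."""
    model = model if model is not None else EfficiencyModel()
    rng = np.random.default_rng(seed)
    fragments = []
    for mol in molecules:
        conv = convert(mol, methylome, model, rng)
        fragments.extend(digest(conv, genome, model, dyad_gap, rng))
    return fragments


def size_select(fragments: Iterable, min_len: int = 100,
                max_len: int = 1000) -> list:
    """Retain fragments with min_len <= length <= max_len (bounds inclusive)."""
    if min_len > max_len:
        raise ParameterError("min_len must be <= max_len")
    return [f for f in fragments if min_len <= f.length <= max_len]


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _apply_errors(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.where(rng.random(len(arr)) < error_rate)[0]
    if len(hits) == 0:
        return seq
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def emit_reads(fragments: Sequence, genome: ReferenceGenome,
               read_length: int = 80, error_rate: float = 0.0,
               seed: int = 0) -> list:
    """Emit one paired-end read pair per fragment.

    Read 1 is sequenced from the plus or minus strand with equal probability
    (so truth alignments carry read-1 flags 99 and 83 in roughly equal
    numbers).  Fragments shorter than ``read_length`` yield reads truncated
    to the fragment length.  Substitution errors are applied uniformly at
    ``error_rate``; qualities are constant Q40.
    """
    if read_length < 1:
        raise ParameterError("read_length must be >= 1")
    if not 0.0 <= error_rate <= 1.0:
        raise ParameterError("error_rate must lie in [0,1]")
    rng = np.random.default_rng(seed)
    pairs = []
    seqs = {name: s for name, s in genome}
    for k, frag in enumerate(fragments):
        seq = seqs[frag.contig]
        l1 = min(read_length, frag.length)
        l2 = min(read_length, frag.length)
        plus = seq[frag.start: frag.start + l1]
        minus = reverse_complement(seq[frag.end - l2: frag.end])
        plus = _apply_errors(plus, rng, error_rate)
        minus = _apply_errors(minus, rng, error_rate)
        r1_reverse = bool(rng.random() < 0.5)
        read1, read2 = (minus, plus) if r1_reverse else (plus, minus)
        pairs.append(SimReadPair(
            name=f"frag_{k}_{frag.contig}_{frag.start}_{frag.end}",
            fragment=frag, read1=read1, read2=read2,
            qual1="I" * len(read1), qual2="I" * len(read2),
            r1_reverse=r1_reverse,
        ))
    return pairs


def write_fastq(pairs: Sequence, path1, path2) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.name}/1\n{p.read1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.name}/2\n{p.read2}\n+\n{p.qual2}\n")


def sam_header(genome: ReferenceGenome) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in genome],
    })


def write_truth_sam(pairs: Sequence, genome: ReferenceGenome, path) -> None:
    """Write ground-truth alignments: proper pairs with read-1 flag 99 or 83."""
    header = sam_header(genome)
    tid = {name: i for i, (name, _) in enumerate(genome)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for p in pairs:
            frag = p.fragment
            l1, l2 = len(p.read1), len(p.read2)
            tlen = frag.length
            if not p.r1_reverse:
                flags = (99, 147)
                pos1, pos2 = frag.start, frag.end - l2
                seq1, seq2 = p.read1, reverse_complement(p.read2)
                tl1, tl2 = tlen, -tlen
            else:
                flags = (83, 163)
                pos1, pos2 = frag.end - l1, frag.start
                seq1, seq2 = reverse_complement(p.read1), p.read2
                tl1, tl2 = -tlen, tlen
            for flag, pos, mpos, s, tl, which in (
                    (flags[0], pos1, pos2, seq1, tl1, 1),
                    (flags[1], pos2, pos1, seq2, tl2, 2)):
                a = pysam.AlignedSegment(header)
                a.query_name = p.name
                a.flag = flag
                a.reference_id = tid[frag.contig]
                a.reference_start = pos
                a.mapping_quality = 60
                a.cigartuples = [(0, len(s))]
                a.next_reference_id = tid[frag.contig]
                a.next_reference_start = mpos
                a.template_length = tl
                a.query_sequence = s
                a.query_qualities = pysam.qualitystring_to_array("I" * len(s))
                out.write(a)


def write_fragments_tsv(fragments: Sequence, path) -> None:
    """Fragment truth table: contig, start, end, end kinds, source sites."""
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tleft_end_kind\tright_end_kind\t"
                 "molecule_id\tleft_site\tright_site\n")
        for f in fragments:
            ls = "." if f.left_site is None else f.left_site
            rs = "." if f.right_site is None else f.right_site
            fh.write(f"{f.contig}\t{f.start}\t{f.end}\t{f.left_end_kind}\t"
                     f"{f.right_end_kind}\t{f.molecule_id}\t{ls}\t{rs}\n")
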