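import numpy as np
import pytest

import eetaps as e
from eetaps import genome as gn


@pytest.fixture(scope="session")
def small_genome():
    """20 kb, 2 contigs, depleted CpGs — shared read-only toy genome."""
    return e.generate_genome(20_000, 2, 0.5, 0.25, seed=101)


@pytest.fixture(scope="session")
def small_index(small_genome):
    return e.CpGIndex.from_genome(small_genome)


@pytest.fixture(scope="session")
def small_methylome(small_genome, small_index):
    regions = e.place_regions(small_genome, 4, 600, 200, seed=102)
    return e.sample_methylome(small_genome, regions, seed=103, index=small_index)


def naive_cpg_scan(seq: str):
    """Quadratic-free but index-independent CG scan used as an oracle."""
    return [i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"]


def brute_force_tally(fragments, cpg_index, config):
    """Independent quadratic oracle for the cleavage/read-through counts.

    Pure-python double loop over (fragment x site); mirrors the counting
    contract: attributed endpoints are cleaved (deduplicated within one
    fragment), interior dyads not attributed are read-through.
    """
    from eetaps.calling import attribute_endpoints

    cleaved = {c: {} for c in cpg_index.contigs}
    readthrough = {c: {} for c in cpg_index.contigs}
    for frag in fragments:
        left, right = attribute_endpoints(frag, cpg_index, config)
        attributed = {s for s in (left, right) if s is not None}
        for s in attributed:
            cleaved[frag.contig][s] = cleaved[frag.contig].get(s, 0) + 1
        for p in cpg_index[frag.contig]:
            p = int(p)
            if frag.start <= p and p + 2 <= frag.end and p not in attributed:
                readthrough[frag.contig][p] = readthrough[frag.contig].get(p, 0) + 1
    return cleaved, readthrough


def tables_equal(table, cleaved, readthrough):
    for c in table.index.contigs:
        pos = table.index[c]
        want_cl = np.array([cleaved[c].get(int(p), 0) for p in pos])
        want_rt = np.array([readthrough[c].get(int(p), 0) for p in pos])
        if not (np.array_equal(table.cleaved[c], want_cl)
                and np.array_equal(table.readthrough[c], want_rt)):
            return False
    return True
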