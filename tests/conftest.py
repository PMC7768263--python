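import numpy as np
import pandas as pd
import pytest

import rapidfoot as rf


@pytest.fixture(scope="session")
def tiny_sim():
    """One 200 kb chromosome, 40 genes, 10k reads per library (seeded)."""
    return rf.simulate_dataset(rf.SimParams.tiny(seed=11))


@pytest.fixture(scope="session")
def tiny_track(tiny_sim):
    """Occupancy track computed from the tiny simulation."""
    kept_f, _ = rf.filter_alignments(tiny_sim.fusion_reads, tiny_sim.index)
    kept_c, _ = rf.filter_alignments(tiny_sim.control_reads, tiny_sim.index)
    cf = rf.count_fragments(kept_f, tiny_sim.fragments, library_id="fusion")
    cc = rf.count_fragments(kept_c, tiny_sim.fragments, library_id="control")
    return rf.normalize_counts(cf, cc, fragments=tiny_sim.fragments)


@pytest.fixture()
def three_fragment_setup():
    """Chromosome of length 14 with motifs at 2 and 8 -> three fragments."""
    index = rf.find_gatc_sites({"c": "AAGATCTTGATCAA"})
    fragments = rf.make_fragments(index)
    return index, fragments


def random_genome(rng: np.random.Generator, length: int, n_chroms: int = 1) -> dict:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return {
        f"chr{i}": bases[rng.integers(0, 4, size=length)].tobytes().decode()
        for i in range(n_chroms)
    }


def naive_gatc_scan(seq: str) -> list[int]:
    """Per-position substring oracle for the motif scanner."""
    s = seq.upper()
    return [i for i in range(len(s) - 3) if s[i : i + 4] == "GATC"]


def toy_track(scores, starts=None, ends=None, chrom="c") -> rf.OccupancyTrack:
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if starts is None:
        starts = np.arange(n) * 10
        ends = starts + 10
    frags = pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": ends, "fragment_id": np.arange(n)}
    )
    return rf.OccupancyTrack(fragments=frags, scores=scores)
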