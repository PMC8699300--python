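import numpy as np
import pytest

from epiallele.design import LocusSpec, demo_design
from epiallele.reads import MethylationPatternTable


@pytest.fixture(scope="session")
def design():
    return demo_design()


@pytest.fixture(scope="session")
def loci(design):
    return design[0]


@pytest.fixture(scope="session")
def scheme(design):
    return design[1]


def make_locus(name="TINY", n_cpg=3, core_len=40, x_on="forward", seed=99):
    """A small synthetic locus for unit tests (dummy primers, even CpG spacing)."""
    from epiallele.design import _fabricate_core

    span = core_len - 2
    offsets = [round(i * span / max(n_cpg - 1, 1)) for i in range(n_cpg)]
    for i in range(1, len(offsets)):
        offsets[i] = max(offsets[i], offsets[i - 1] + 2)
    fwd, rev = "AGGATTGGAA", "TTAACCTTGG"
    core = _fabricate_core(core_len, offsets, seed)
    from epiallele.design import revcomp

    ref = fwd + core + revcomp(rev)
    return LocusSpec(
        name=name,
        reference_sequence=ref,
        cpg_positions=tuple(len(fwd) + o + 1 for o in offsets),
        primer_forward=fwd,
        primer_reverse=rev,
        x_on=x_on,
    )


def random_pattern_table(rng, samples, locus_name="TINY", n_cpg=6, n_reads=200):
    """A pattern table with uniformly random patterns (brute-force test fixture)."""
    table = MethylationPatternTable()
    reads = {}
    for sample in samples:
        pats = ["".join(rng.choice(["C", "T"], n_cpg)) for _ in range(n_reads)]
        reads[sample] = pats
        for p in pats:
            table.add_pattern(sample, locus_name, p)
    return table, reads
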