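import numpy as np
import pytest

from dysgene import presets, synth


@pytest.fixture(scope="session")
def pe_library():
    return presets.default_pe_library(seed=7)


@pytest.fixture(scope="session")
def tiny_library():
    """A small fast element: 400 bp, 20-bp TIRs, four 90-bp exons."""
    return synth.make_te_library(
        400, [(20, 110), (110, 200), (200, 290), (290, 380)], 20, seed=3, name="TE"
    )


@pytest.fixture(scope="session")
def base_genome():
    return synth.random_genome(60_000, seed=11)


@pytest.fixture(scope="session")
def line_with_insertions(base_genome, pe_library):
    """One 60-kb line with 4 homozygous full insertions plus its 30x
    short-read simulation (truth alignments only)."""
    line = synth.make_line_genome(
        base_genome, pe_library, n_full=4, n_truncated=0, seed=5, line_id="lineA"
    )
    sim = synth.simulate_short_reads(line, coverage=30, seed=5, with_sequences=False)
    return line, sim
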