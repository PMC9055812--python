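import numpy as np
import pandas as pd
import pytest

from cressomics import simulate


@pytest.fixture(scope="session")
def config():
    return simulate.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def annotation(config):
    ann, truth = simulate.gen_annotation(config)
    return ann, truth


@pytest.fixture(scope="session")
def srna_libraries(annotation, config):
    ann, _ = annotation
    return simulate.gen_srna_libraries(ann, config)


@pytest.fixture(scope="session")
def hairpin_set(config):
    return simulate.gen_hairpin_set(config)


@pytest.fixture(scope="session")
def expression(config):
    return simulate.gen_expression_counts(config)


@pytest.fixture(scope="session")
def methylation_calls(annotation, config):
    ann, _ = annotation
    return simulate.gen_methylation_calls(ann, config)


@pytest.fixture(scope="session")
def qc_inputs(config):
    return simulate.gen_contigs_kmers_genotypes(config)


def make_reads(rows):
    """Read frame from (scaffold, start, length, strand, count, five_prime)."""
    recs = [
        {
            "scaffold": s,
            "start": st,
            "end": st + ln,
            "length": ln,
            "strand": strand,
            "count": c,
            "five_prime": fp,
        }
        for (s, st, ln, strand, c, fp) in rows
    ]
    return pd.DataFrame(
        recs,
        columns=["scaffold", "start", "end", "length", "strand", "count", "five_prime"],
    )
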