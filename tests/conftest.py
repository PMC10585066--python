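import numpy as np
import pytest

import thermoscore as ts

#: motif symbol -> accepted sequence bases; an N in the *sequence* matches nothing
ORACLE_BASES = {"A": "A", "C": "C", "G": "G", "T": "T", "N": "ACGT", "R": "AG", "K": "GT"}


def oracle_scan(seq: str, pattern: str) -> int:
    """Naive position-by-position motif count, independent of the regex scanner."""
    m = len(pattern)
    hits = 0
    for i in range(len(seq) - m + 1):
        if all(seq[i + j] in ORACLE_BASES[pattern[j]] for j in range(m)):
            hits += 1
    return hits


@pytest.fixture(scope="session")
def default_sim():
    """One full synthetic study at the default design, shared across tests."""
    return ts.simulate_study(seed=7)


@pytest.fixture(scope="session")
def small_study():
    """A compact study without promoters for fast expression-stage tests."""
    cfg = ts.GeneratorConfig(n_genes=300, with_promoters=False)
    return ts.simulate_study(cfg, seed=11)


def make_study(values, cultivars, treatments, times, replicates, genes=None):
    """Hand-build an ExpressionStudy from an explicit column layout."""
    values = np.asarray(values, dtype=float)
    samples = [
        ts.SampleInfo(
            sample_id=f"{c}_{t}_r{r}", cultivar=c, treatment=t, time_h=h, replicate=r
        )
        for c, t, h, r in zip(cultivars, treatments, times, replicates)
    ]
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    return ts.ExpressionStudy(genes=genes, samples=samples, values=values)
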