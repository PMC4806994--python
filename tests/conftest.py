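import numpy as np
import pandas as pd
import pytest

from mhagscan.io import GenotypeMatrix, TransplantCohort, make_cohort


def make_matrix(calls, lines=None, chromosomes=None, positions=None):
    """Build a small GenotypeMatrix from an int grid (-1/0/1/2)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    lines = lines if lines is not None else ["L1"] * n
    samples = pd.DataFrame(
        {"sample_id": [f"s{i}" for i in range(n)], "line": lines, "sex": 0}
    )
    loci = pd.DataFrame(
        {
            "locus_id": [f"snp{j}" for j in range(m)],
            "chromosome": chromosomes if chromosomes is not None else ["1"] * m,
            "position_bp": positions if positions is not None else list(range(1, m + 1)),
            "assembly": "",
            "alt_chromosome": "",
        }
    )
    return GenotypeMatrix(samples, loci, calls)


def make_pairs(gm, pairs):
    """pairs: list of (donor_id, recipient_id, outcome)."""
    df = pd.DataFrame(pairs, columns=["donor_id", "recipient_id", "outcome"])
    return make_cohort(df, gm)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def random_matrix_factory(rng):
    """Random small matrices including missing calls, for round-trip checks."""

    def factory(n_samples=6, n_loci=9, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        calls = r.choice([-1, 0, 1, 2], size=(n_samples, n_loci), p=[0.1, 0.4, 0.3, 0.2])
        chroms = r.choice(["1", "2", "X", "0"], size=n_loci)
        pos = [0 if c == "0" else int(p) for c, p in zip(chroms, r.integers(1, 10**7, n_loci))]
        lines = ["A"] * (n_samples // 2) + ["B"] * (n_samples - n_samples // 2)
        return make_matrix(calls, lines=lines, chromosomes=list(chroms), positions=pos)

    return factory
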