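"""Shared fixtures: the default codebook, the five-respondent worked
example, and an independent brute-force Alkire-Foster enumerator used as
the oracle for the vectorized estimators."""

from fractions import Fraction

import numpy as np
import pytest

import mdepriv as md


@pytest.fixture(scope="session")
def codebook():
    return md.load_default_codebook()


@pytest.fixture(scope="session")
def example_dataset(codebook):
    return md.worked_example(codebook)


@pytest.fixture(scope="session")
def example_matrix(codebook, example_dataset):
    return md.dichotomize(example_dataset, codebook, missing_policy="drop")


def brute_force_af(b, indicator_weights, sample_weights, k):
    """Censor-and-average enumeration, all in exact rational arithmetic.

    Independent of the package internals: per-row scores are built by
    explicit summation, identification by direct Fraction comparison, and
    the three indices by literal weighted averaging.
    """
    b = [[int(x) for x in row] for row in b]
    m = len(indicator_weights)
    w_ind = [Fraction(w) for w in indicator_weights]
    sw = [Fraction(w) for w in sample_weights]
    scores = [sum(w_ind[j] * row[j] for j in range(m)) for row in b]
    cutoff = Fraction(k, m)
    members = [s >= cutoff for s in scores]
    total = sum(sw, Fraction(0))
    q_mass = sum((sw[i] for i in range(len(b)) if members[i]), Fraction(0))
    hcr = q_mass / total
    censored_sum = sum(
        (sw[i] * scores[i] for i in range(len(b)) if members[i]), Fraction(0)
    )
    m_idx = censored_sum / total
    a = censored_sum / q_mass if q_mass > 0 else None
    return hcr, a, m_idx


@pytest.fixture(scope="session")
def oracle():
    return brute_force_af


@pytest.fixture()
def rng():
    return np.random.default_rng(20200403)
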