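import numpy as np
import pandas as pd
import pytest

from peptide_sip.enrichment_stats import FractionTaxonTable
from peptide_sip.gradient_model import Fraction, GradientProfile, HeavyWindow


@pytest.fixture
def simple_profile():
    """Four-fraction gradient straddling a [1.725, 1.742] heavy window."""
    fractions = [
        Fraction(index=1, density=1.750, copies=100.0),
        Fraction(index=2, density=1.741, copies=400.0),
        Fraction(index=3, density=1.730, copies=200.0),
        Fraction(index=4, density=1.720, copies=300.0),
    ]
    return GradientProfile(treatment="13C", depth="surface", fractions=fractions)


@pytest.fixture
def heavy_window():
    return HeavyWindow(density_min=1.725, density_max=1.742)


def make_table(counts: dict, columns, rank="genus") -> FractionTaxonTable:
    return FractionTaxonTable(
        counts=pd.DataFrame(counts, index=columns).T.astype(float), rank=rank
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
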