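import numpy as np
import pytest

from fftsar.aaindex import RESIDUES, AminoAcidIndex
from fftsar import synthetic


def make_index(accession="TEST000001", description="test index", **overrides):
    """Complete index with residue values 0.01 * (rank + 1), overridable."""
    values = {aa: 0.01 * (i + 1) for i, aa in enumerate(RESIDUES)}
    values.update(overrides)
    return AminoAcidIndex(accession=accession, description=description, values=values)


#: two-record flat file; record 2 has one NA hole
TWO_ENTRY_FLATFILE = """\
H FIXA000001
D handcrafted fixture index one
R PMID:0000000
A Nobody, A.
T A fixture
J Nowhere 1 (2020)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     0.10    0.20    0.30    0.40    0.50    0.60    0.70    0.80    0.90    1.00
     1.10    1.20    1.30    1.40    1.50    1.60    1.70    1.80    1.90    2.00
//
H FIXB000002
D handcrafted fixture index two, one missing value
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     0.11    0.21    0.31    0.41    0.51    0.61    0.71    NA      0.91    1.01
     1.11    1.21    1.31    1.41    1.51    1.61    1.71    1.81    1.91    2.01
//
"""


@pytest.fixture
def fixture_index():
    return make_index()


@pytest.fixture
def small_pool():
    """6 complete + 2 incomplete synthetic indices, fixed seed."""
    return synthetic.make_index_pool(6, seed=11, n_incomplete=2)


@pytest.fixture
def planted():
    """Synthetic dataset with the signal in the first usable index."""
    pool = synthetic.make_index_pool(6, seed=11, n_incomplete=2)
    spec = synthetic.SyntheticSpec(
        wt_length=60,
        n_singles=6,
        n_variants=15,
        planted_accessions=(pool.usable_accessions[0],),
        noise_sd=0.5,
        seed=7,
    )
    dataset, truth = synthetic.make_sar_dataset(spec, pool)
    return pool, dataset, truth


def naive_dft_amplitudes(signal):
    """O(N^2) DFT modulus oracle, full length."""
    s = np.asarray(signal, dtype=float)
    n = len(s)
    k = np.arange(n)
    out = np.empty(n)
    for ki in k:
        out[ki] = abs(np.sum(s * np.exp(-2j * np.pi * ki * np.arange(n) / n)))
    return out
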