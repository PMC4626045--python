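import numpy as np
import pandas as pd
import pytest

from solnmr.domain import ATOM_TABLE_COLUMNS, Ensemble, PeakHeightSeries, ShiftList
from solnmr.synthetic_data import T1_DELAYS_MS, T2_DELAYS_MS, SyntheticSpec


@pytest.fixture
def t1_delays():
    return np.asarray(T1_DELAYS_MS, dtype=float)


@pytest.fixture
def t2_delays():
    return np.asarray(T2_DELAYS_MS, dtype=float)


@pytest.fixture
def noiseless_t1_series(t1_delays):
    heights = 100.0 * np.exp(-t1_delays / 750.0)
    return PeakHeightSeries(
        residue_number=1, experiment="T1", delays_ms=t1_delays, heights=heights
    )


@pytest.fixture
def small_spec():
    return SyntheticSpec(seed=7, n_residues=12, flexible_segments=((4, 6),))


def make_ensemble(coords_per_model, residues=None, atoms_per_residue=("N", "CA", "C", "O")):
    """Ensemble from a list of (n_atoms, 3) arrays; atoms cycle residue-wise."""
    coords = np.stack([np.asarray(c, dtype=float) for c in coords_per_model])
    n_atoms = coords.shape[1]
    n_per = len(atoms_per_residue)
    assert n_atoms % n_per == 0
    n_res = n_atoms // n_per
    residues = residues or list(range(1, n_res + 1))
    rows = [
        (residues[ri], "ALA", atoms_per_residue[ai], "A")
        for ri in range(n_res)
        for ai in range(n_per)
    ]
    table = pd.DataFrame(rows, columns=ATOM_TABLE_COLUMNS)
    return Ensemble(atom_table=table, coords=coords)


@pytest.fixture
def shift_pair():
    apo = ShiftList({7: (8.2, 121.4), 8: (7.9, 108.0), 9: (9.1, 115.5)}, label="apo")
    holo = ShiftList({7: (8.3, 122.4), 8: (7.9, 108.0), 9: (9.1, 115.5)}, label="holo")
    return apo, holo
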