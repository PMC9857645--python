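import numpy as np
import pytest

from lipidquant.model import GlycerideSpecies as S
from lipidquant.model import default_assignment_table
from lipidquant.simulate import GroundTruthComposition

SPECIES_ORDER = (S.MAG_1, S.MAG_2, S.DAG_12, S.DAG_13, S.TAG, S.FFA)


@pytest.fixture(scope="session")
def table():
    return default_assignment_table()


def random_truth(rng: np.random.Generator) -> GroundTruthComposition:
    """A TAG-dominated composition typical of an oleaginous fungus."""
    raw = {
        S.TAG: rng.uniform(50.0, 80.0),
        S.DAG_12: rng.uniform(3.0, 12.0),
        S.DAG_13: rng.uniform(5.0, 18.0),
        S.MAG_1: rng.uniform(0.2, 1.5),
        S.MAG_2: rng.uniform(0.2, 1.5),
        S.FFA: rng.uniform(2.0, 8.0),
    }
    total = sum(raw.values())
    return GroundTruthComposition(
        moles={sp: v / total for sp, v in raw.items()},
        mean_double_bonds=float(rng.uniform(0.7, 1.1)),
        gain=float(rng.lognormal(0.0, 0.5)),
    )


def design_matrix(table):
    """Window x species proton-count matrix, the forward model of the
    deconvolution (used as the independent linear-algebra oracle)."""
    from lipidquant.model import QUANT_WINDOW_ORDER

    counts = table.proton_counts()
    A = np.zeros((len(QUANT_WINDOW_ORDER), len(SPECIES_ORDER)))
    for i, key in enumerate(QUANT_WINDOW_ORDER):
        for j, sp in enumerate(SPECIES_ORDER):
            A[i, j] = counts[key].get(sp, 0)
    return A
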