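import numpy as np
import pytest

from tfcoev.msa import AlignedFamily
from tfcoev.motifs import PositionWeightMatrix
from tfcoev.simulate import PlacedResidue, SyntheticConfig, generate_family


def random_msa(
    rng: np.random.Generator,
    n_seq: int,
    n_col: int,
    alphabet: str = "ACDEFG",
    gap_prob: float = 0.0,
) -> AlignedFamily:
    letters = np.array(list(alphabet))
    seqs = letters[rng.integers(len(letters), size=(n_seq, n_col))]
    if gap_prob > 0:
        seqs[rng.random(seqs.shape) < gap_prob] = "-"
    return AlignedFamily([f"s{i}" for i in range(n_seq)], seqs)


def pwm_from_consensus(tf_id: str, consensus: str, strength: float = 1.0):
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    mat = np.full((4, len(consensus)), (1.0 - strength) / 3 if strength < 1 else 0.0)
    for w, b in enumerate(consensus):
        mat[:, w] = (1.0 - strength) / 3
        mat[base_index[b], w] = strength
    return PositionWeightMatrix(tf_id, mat)


@pytest.fixture
def small_family():
    """30 TFs, 3 subclasses, 2 planted TSDS columns, 1 strongly coupled pair."""
    config = SyntheticConfig(
        n_tf=30,
        n_col=20,
        n_subclass=3,
        tsds_columns=[0, 1],
        coevolving_pairs=[(5, 6, 0.9)],
        seed=7,
    )
    return config, *generate_family(config)


@pytest.fixture
def toy_spec():
    """Minimal protein + DNA placement: a 3-4-5 triangle."""
    return [
        PlacedResidue("A", 1, "ARG", [("CA", 0.0, 0.0, 0.0)]),
        PlacedResidue("B", 1, "DA", [("P", 3.0, 4.0, 0.0)]),
    ]
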