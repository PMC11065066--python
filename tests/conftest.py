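import numpy as np
import pytest

from worktraj import DEFAULT_ALPHABET, SequencePanel, StateSequence


def panel_from_matrix(states, start_age=16, gender="female", alphabet=DEFAULT_ALPHABET):
    """Build an aligned panel directly from an n x L integer state matrix."""
    states = np.asarray(states, dtype=np.int64)
    seqs = [
        StateSequence(
            subject_id=f"s{i}",
            gender=gender,
            birth_year=1930,
            states=row,
            start_age=start_age,
        )
        for i, row in enumerate(states)
    ]
    return SequencePanel(alphabet, seqs)


@pytest.fixture
def small_panel():
    """Four short sequences over ages 16-19 forming two obvious pairs."""
    return panel_from_matrix(
        [
            [1, 1, 5, 5],
            [1, 5, 5, 6],
            [7, 2, 2, 2],
            [7, 2, 2, 4],
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240416)
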