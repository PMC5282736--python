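import numpy as np
import pytest

from morphospace import (
    CharacterMatrix,
    INAPPLICABLE,
    MISSING,
    PipelineConfig,
    lobopodian_preset,
    run,
)


@pytest.fixture
def tiny_matrix():
    """3 taxa x 3 unordered binary characters with one missing and one
    inapplicable cell."""
    return CharacterMatrix(
        ["A", "B", "C"],
        [[0, 1, MISSING], [0, INAPPLICABLE, 1], [1, 1, 1]],
    )


@pytest.fixture
def random_matrix_factory():
    """Random small matrices with specials and polymorphisms."""

    def make(seed, n_taxa=6, n_char=10, n_states=3, p_special=0.15, p_poly=0.1):
        rng = np.random.default_rng(seed)
        cells = []
        for _ in range(n_taxa):
            row = []
            for _ in range(n_char):
                u = rng.random()
                if u < p_special / 2:
                    row.append(MISSING)
                elif u < p_special:
                    row.append(INAPPLICABLE)
                elif u < p_special + p_poly:
                    row.append(
                        frozenset(
                            rng.choice(n_states, size=2, replace=False).tolist()
                        )
                    )
                else:
                    row.append(int(rng.integers(n_states)))
            cells.append(row)
        return CharacterMatrix(
            [f"t{i}" for i in range(n_taxa)], cells, alphabet=range(n_states)
        )

    return make


@pytest.fixture(scope="session")
def preset_data():
    return lobopodian_preset(seed=11)


@pytest.fixture(scope="session")
def preset_run():
    """One moderately sized pipeline run on the synthetic lobopodian
    stand-in, shared across tests."""
    config = PipelineConfig(preset="lobopodian", seed=11, n_iterations=1000,
                            hv_samples=10000)
    return run(config)
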