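import numpy as np
import pytest

from esfpred import synthetic


def ideal_ca_trace(n: int, res_per_turn: float = 3.6, rise: float = 1.5,
                   radius: float = 2.3) -> np.ndarray:
    """Parametric ideal alpha-helix C-alpha trace (right-handed, along +z)."""
    t = np.arange(n, dtype=float)
    w = 2.0 * np.pi / res_per_turn
    return np.c_[radius * np.cos(w * t), radius * np.sin(w * t), rise * t]


@pytest.fixture(scope="session")
def helix20():
    return synthetic.build_helix(20)


@pytest.fixture(scope="session")
def bundle2():
    chain, seg, meta = synthetic.build_bundle(
        [synthetic.HelixSpec(18), synthetic.HelixSpec(18)])
    return chain, seg, meta


@pytest.fixture(scope="session")
def small_corpus():
    spec = synthetic.CorpusSpec(n_proteins=6, seed=7)
    return synthetic.make_corpus(spec)
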