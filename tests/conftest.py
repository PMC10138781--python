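import numpy as np
import pandas as pd
import pytest

from protolex.phonology import load_rules
from protolex.synth import SynthConfig, generate_lexicon


@pytest.fixture(scope="session")
def rules():
    return load_rules()


@pytest.fixture(scope="session")
def small_lexicon(rules):
    """A 2,000-type synthetic lexicon with phoneme forms attached."""
    from protolex.phonology import to_phonemes

    cfg = SynthConfig(n_types=2000, n_stems=900)
    lex, truth = generate_lexicon(cfg, seed=101)
    phon = [to_phonemes(f, rules).phonemes for f in lex["form"]]
    return lex.assign(phon=phon), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def simulate_ordinal(n, beta_x=1.2, beta_g=0.7,
                     thresholds=(-2.0, -0.5, 0.5, 2.0), seed=0):
    """Plain fixed-effects proportional-odds data for ordinal tests."""
    r = np.random.default_rng(seed)
    x = r.normal(size=n)
    g = r.integers(0, 2, n).astype(float)
    eta = beta_x * x + beta_g * g
    th = np.asarray(thresholds)
    cum = 1.0 / (1.0 + np.exp(-(th[None, :] - eta[:, None])))
    y = 1 + (r.random(n)[:, None] > cum).sum(axis=1)
    return pd.DataFrame({"rating": y, "x": x, "g": g})
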