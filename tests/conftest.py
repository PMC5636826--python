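import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hexgram.alphabets import BEST_ENCODING, example_property_table
from hexgram.classify import ModelConfig
from hexgram.ngrams import extract_features
from hexgram.peptides import PeptideRecord, PeptideSet, extract_hexapeptides
from hexgram.quipt import select_features
from hexgram.synthdata import MotifSpec, SynthConfig, default_motif, generate_peptide_set

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def best_enc():
    return BEST_ENCODING


@pytest.fixture(scope="session")
def property_table():
    return example_property_table()


@pytest.fixture
def tiny_set():
    """Four hand-written peptides, two per class."""
    return PeptideSet(
        [
            PeptideRecord("a1", "KLVFFA", 1),
            PeptideRecord("a2", "ILVILVIL", 1),
            PeptideRecord("n1", "DDDDDD", 0),
            PeptideRecord("n2", "KPRKPRKP", 0),
        ],
        name="tiny",
    )


@pytest.fixture(scope="session")
def strong_synth():
    """Clean planted-motif set (motif in every positive, no negative)."""
    cfg = SynthConfig(
        seed=7,
        n_pos=60,
        n_neg=60,
        motifs=(MotifSpec(default_motif(), p_pos=1.0, p_neg=0.0),),
    )
    ps, truth = generate_peptide_set(cfg)
    return cfg, ps, truth


@pytest.fixture(scope="session")
def strong_model(strong_synth):
    """A forest trained on the clean planted-motif set."""
    from hexgram.classify import train_model

    cfg, ps, _ = strong_synth
    fm = extract_features(extract_hexapeptides(ps), cfg.encoding)
    hits = select_features(fm, alpha=0.05)
    model = train_model(
        fm, [h.feature_id for h in hits], ModelConfig(seed=11, n_trees=100)
    )
    return model, fm, ps


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
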