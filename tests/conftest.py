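import numpy as np
import pytest

import semnetkit as sk


@pytest.fixture
def tiny_corpus():
    return sk.Corpus([["a", "b", "a"], ["b"]])


@pytest.fixture
def small_space():
    """12 random 6-dimensional word vectors (deterministic)."""
    rng = np.random.default_rng(0)
    vecs = rng.normal(size=(12, 6))
    return sk.SemanticSpace([f"w{i:02d}" for i in range(12)], vecs)


@pytest.fixture
def synth_corpus():
    cfg = sk.SynthCorpusConfig(n_clusters=3, words_per_cluster=4,
                               n_collocation_pairs=2, n_documents=120,
                               doc_length=40, seed=0)
    return sk.generate_synthetic_corpus(cfg)


@pytest.fixture
def norms_csv(tmp_path):
    path = tmp_path / "norms.csv"
    path.write_text("cue,associate,count\nx,y,3\nx,z,1\ny,x,2\n")
    return path
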