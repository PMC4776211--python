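import numpy as np
import pytest

from esomics import TetranucleotideESOM, tnf
from esomics import synthetic as syn


@pytest.fixture(scope="session")
def three_genome_mixture():
    """Seeded 3-genome community at high divergence, no chimeras."""
    models = syn.simulate_community(3, 0.8, seed=3)
    contigs, truth = syn.simulate_contigs(models, 100, chimera_rate=0.0, seed=3)
    return models, contigs, truth


@pytest.fixture(scope="session")
def trained_map(three_genome_mixture):
    """ESOM trained on the long contigs of the 3-genome mixture."""
    _, contigs, truth = three_genome_mixture
    train = tnf(contigs, min_len=3000)
    n = len(train)
    # smallest grid honoring the 5x emergent-map convention
    rows = int(np.ceil(np.sqrt(5 * n / 1.3)))
    cols = int(np.ceil(5 * n / rows))
    som = TetranucleotideESOM(rows=rows, cols=cols, epochs=10, random_state=3).fit(train)
    return som, train, truth


@pytest.fixture(scope="session")
def tiny_bundle():
    from esomics.pipeline import make_fixtures

    return make_fixtures("tiny", seed=1)
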