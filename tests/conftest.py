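import numpy as np
import pytest

import phylofoot as pf

MEME_ONE = """\
MEME version 4

ALPHABET= ACGT

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

MOTIF m1 altname
letter-probability matrix: alength= 4 w= 6 nsites= 20
 0.910000  0.030000  0.030000  0.030000
 0.030000  0.910000  0.030000  0.030000
 0.030000  0.030000  0.910000  0.030000
 0.030000  0.030000  0.030000  0.910000
 0.910000  0.030000  0.030000  0.030000
 0.250000  0.250000  0.250000  0.250000
"""

MEME_TWO = MEME_ONE + """\

MOTIF m2
letter-probability matrix: alength= 4 w= 3
 0.910000  0.030000  0.030000  0.030000
 0.030000  0.910000  0.030000  0.030000
 0.030000  0.030000  0.910000  0.030000
"""


@pytest.fixture
def meme_one(tmp_path):
    path = tmp_path / "one.meme"
    path.write_text(MEME_ONE)
    return path


@pytest.fixture
def meme_two(tmp_path):
    path = tmp_path / "two.meme"
    path.write_text(MEME_TWO)
    return path


@pytest.fixture(scope="session")
def acg_motif():
    return pf.motif_from_consensus("ACG", p_consensus=0.91)


@pytest.fixture(scope="session")
def acg_pssm(acg_motif):
    return pf.build_pssm(acg_motif)


@pytest.fixture(scope="session")
def small_world():
    """3-species, 120-gene world with 12 fully conserved planted targets."""
    cfg = pf.SimConfig(
        n_species=3, n_genes=120, positive_fraction=0.1, conservation_prob=1.0, seed=1
    )
    return pf.generate_world(cfg, pf.demo_motifs(1))


@pytest.fixture(scope="session")
def small_scan(small_world):
    return pf.scan_world(small_world, p_threshold=1e-4)


def random_feature_table(n_rows: int, species: list[str], seed: int = 0):
    """A feature table of pure noise (for training-set plumbing tests)."""
    rng = np.random.default_rng(seed)
    cols = pf.feature_columns(species)
    import pandas as pd

    data = rng.random((n_rows, len(cols)))
    idx = pd.Index([f"g{i:05d}" for i in range(n_rows)], name="gene_id")
    return pd.DataFrame(data, columns=cols, index=idx)
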