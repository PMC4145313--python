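import numpy as np
import pytest

from commrer import synthetic_data as sd
from commrer import tree_model as tm


def random_newick(rng, n_tips, min_len=0.05, max_len=2.0):
    """Random binary tree newick with uniform branch lengths (test helper)."""
    subtrees = [f"t{i}" for i in range(n_tips)]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b = subtrees.pop(int(j))
        a = subtrees.pop(int(i))
        la, lb = rng.uniform(min_len, max_len, size=2)
        subtrees.append(f"({a}:{la:.10g},{b}:{lb:.10g})")
    return subtrees[0] + ";"


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_tree():
    return tm.read_newick("((A:1,B:2):1,C:3);")


@pytest.fixture(scope="session")
def sim_tree():
    """Medium simulated reference tree shared across tests."""
    return sd.simulate_reference_tree(40, 4, seed=7)


@pytest.fixture(scope="session")
def study_bundle(tmp_path_factory):
    """Small on-disk synthetic study shared by pipeline tests."""
    cfg = sd.StudyConfig.default(seed=11)
    for h in cfg.habitats:
        h.n_samples = 3
    cfg.markers_per_sample = 40
    cfg.codon_pairs_per_sample = 6
    cfg.codon_length = 90
    cfg.n_genes_per_sample = 800
    out = tmp_path_factory.mktemp("bundle") / "study"
    sd.simulate_study(cfg, out)
    return out
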