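import random

import pytest

from codemlbatch import fixtures, identity
from codemlbatch.templates import GridSpec


@pytest.fixture()
def example_dataset(tmp_path):
    """Small generated dataset: 4 genes x all families, 3 hypothesis trees."""
    return fixtures.make_example_dataset(tmp_path / "data", seed=0)


@pytest.fixture()
def full_request():
    return identity.parse_model_spec("s[0:1:2:3:7:8:8a],b,c,w")


@pytest.fixture()
def tiny_grid():
    return GridSpec(kappas=(2.0,), omegas=(0.5,))


@pytest.fixture()
def rng():
    return random.Random(20240917)


def scan_dataset(info):
    """Parse the generated dataset's filenames into identities."""
    import os
    msas = [identity.parse_msa_filename(n, path=os.path.join(info["msa_dir"], n))
            for n in sorted(os.listdir(info["msa_dir"]))]
    trees = [identity.parse_tree_filename(n, path=os.path.join(info["tree_dir"], n))
             for n in sorted(os.listdir(info["tree_dir"]))]
    return msas, trees
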