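import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # reference_plink helper

from genomat import MISSING, open_bed, write_bed
from genomat.synthetic_data import make_fixture_suite

SUITE_SEED = 20240917  # frozen study-conditions seed for the fixture suite


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    """The standard synthetic fixture suite (multichrom, qc, related, gwas)."""
    out = tmp_path_factory.mktemp("suite")
    manifest = make_fixture_suite(out, seed=SUITE_SEED)
    return manifest


@pytest.fixture()
def small_fileset(tmp_path):
    """The 5-sample x 3-variant fixture used throughout the format tests."""
    geno = np.array(
        [[0, 1, 2],
         [2, 2, 1],
         [1, MISSING, 0],
         [0, 0, 0],
         [2, 1, 1]],
        dtype=np.int8,
    )
    root = tmp_path / "small"
    write_bed(geno, root)
    return root, geno


@pytest.fixture()
def random_fileset(tmp_path):
    """50 samples x 20 variants with missingness, plus its source matrix."""
    rng = np.random.default_rng(42)
    geno = rng.binomial(2, 0.3, size=(50, 20)).astype(np.int8)
    geno[rng.random((50, 20)) < 0.05] = MISSING
    root = tmp_path / "random"
    write_bed(geno, root)
    return root, geno


@pytest.fixture()
def per_chromosome_filesets(tmp_path):
    """Three 199-sample filesets of 300 variants each (one per chromosome)."""
    rng = np.random.default_rng(7)
    roots, genos = [], []
    for c in range(3):
        geno = rng.binomial(2, rng.uniform(0.1, 0.5, 300), size=(199, 300)).astype(np.int8)
        root = tmp_path / f"chr{c + 1}"
        write_bed(geno, root)
        roots.append(root)
        genos.append(geno)
    return roots, genos


@pytest.fixture()
def open_chromosomes(per_chromosome_filesets):
    roots, genos = per_chromosome_filesets
    return [open_bed(r) for r in roots], genos
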