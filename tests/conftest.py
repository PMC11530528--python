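import numpy as np
import pytest

from muse import MultiScaleDataset, SyntheticSpec, TrainConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def small_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """Desk-scale generator spec small enough for fast unit tests."""
    kwargs = dict(
        n_entities=60,
        n_classes=4,
        graph_size_range=(8, 14),
        hidden_fraction=0.3,
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticSpec(**kwargs)


def fast_config(seed: int = 0, **overrides) -> TrainConfig:
    kwargs = dict(
        seed=seed,
        max_em_iterations=2,
        epochs_per_step=4,
        hidden=16,
        network_hidden=16,
        dropout=0.0,
    )
    kwargs.update(overrides)
    return TrainConfig(**kwargs)


@pytest.fixture
def small_dataset():
    return MultiScaleDataset.from_spec(small_spec(seed=0))


@pytest.fixture
def tiny_pdb(tmp_path):
    """Minimal 3-residue single-chain PDB file."""
    lines = [
        "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N",
        "ATOM      2  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C",
        "ATOM      3  C   ALA A   1       2.000   0.000   0.000  1.00  0.00           C",
        "ATOM      4  N   GLY A   2       3.000   0.000   0.000  1.00  0.00           N",
        "ATOM      5  CA  GLY A   2       4.000   0.000   0.000  1.00  0.00           C",
        "ATOM      6  C   GLY A   2       5.000   0.000   0.000  1.00  0.00           C",
        "ATOM      7  N   SER A   3       6.000   0.000   0.000  1.00  0.00           N",
        "ATOM      8  CA  SER A   3       7.000   5.000   0.000  1.00  0.00           C",
        "ATOM      9  C   SER A   3       8.000   5.000   0.000  1.00  0.00           C",
        "END",
    ]
    path = tmp_path / "tiny.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path
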