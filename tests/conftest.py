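import numpy as np
import pytest

from siftsim import (
    BitLayout,
    FingerprintDataset,
    GridConfig,
    InteractionFingerprint,
    SynthConfig,
    generate_dataset,
    run_grid,
)


def random_dataset(rng, n_ligands=6, n_residues=4, density=0.3, name="rand"):
    """Small random dataset with at least one set bit (so filtering is
    well-defined) and both activity classes present."""
    layout = BitLayout(tuple(f"RES{i}" for i in range(1, n_residues + 1)))
    bits = (rng.random((n_ligands, len(layout))) < density).astype(np.uint8)
    if not bits.any():
        bits[0, 0] = 1
    active = rng.random(n_ligands) < 0.5
    active[0], active[-1] = True, False
    fps = tuple(
        InteractionFingerprint(f"L{i}", bits[i], bool(active[i]))
        for i in range(n_ligands)
    )
    return FingerprintDataset(name, layout, fps)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def default_datasets():
    """Ten default-config synthetic datasets with their references."""
    datasets, references = [], []
    for s in range(10):
        ds, ref = generate_dataset(SynthConfig(seed=100 + s), name=f"D{s}")
        datasets.append(ds)
        references.append(ref)
    return datasets, references


@pytest.fixture(scope="session")
def default_grid(default_datasets):
    """Full 90-variant grid over the ten default synthetic datasets."""
    datasets, references = default_datasets
    return run_grid(datasets, references, GridConfig(seed=42))
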