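import numpy as np
import pytest

from aflphylo.data import BinaryCharacterMatrix
from aflphylo.simulate import SimulationConfig, simulate_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_matrix():
    """6 samples / 3 species / 12 loci, fixed by hand."""
    calls = np.array(
        [
            [1, 1, 0, 0, 1, 0, 1, 1, 0, 0, 1, 0],
            [1, 1, 0, 0, 1, 0, 1, 0, 0, 0, 1, 0],
            [0, 1, 1, 0, 0, 1, 0, 1, 1, 0, 0, 1],
            [0, 1, 1, 0, 0, 1, 0, 1, 1, 1, 0, 1],
            [0, 0, 1, 1, 0, 1, 1, 0, 1, 0, 1, 1],
            [0, 0, 1, 1, 0, 0, 1, 0, 1, 0, 1, 1],
        ],
        dtype=np.int8,
    )
    ids = ["a1", "a2", "b1", "b2", "c1", "c2"]
    species = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C", "c2": "C"}
    return BinaryCharacterMatrix(calls, ids, [f"L{i}" for i in range(12)], species)


@pytest.fixture(scope="session")
def study_scale_dataset():
    """10 species / 38 samples / 659 loci, mirroring the emulation target."""
    per_species = [5, 1, 10, 1, 5, 3, 3, 4, 2, 4]  # sums to 38
    cfg = SimulationConfig(
        n_species=10,
        individuals_per_species=1,
        n_loci=659,
        seed=42,
        n_replicate_samples=0,
    )
    # build with uneven individuals: simulate per-species states then expand
    import dendropy

    from aflphylo.simulate import simulate_binary_characters, simulate_species_tree

    rng = np.random.default_rng(42)
    tree = simulate_species_tree(10, 1.0, 0.5, rng=rng)
    cfg2 = SimulationConfig(n_species=10, individuals_per_species=1, n_loci=659,
                            polymorphism_rate=0.0, seed=42)
    base, truth = simulate_binary_characters(tree, cfg2, rng=rng)
    rows, ids, smap = [], [], {}
    for sp, k in zip(sorted(base.species()), per_species):
        row = base.calls[base.rows_for_species(sp)[0]]
        for i in range(k):
            flips = rng.random(row.shape) < 0.01
            rows.append(np.where(flips, 1 - row, row))
            sid = f"{sp}_{i + 1}"
            ids.append(sid)
            smap[sid] = sp
    return BinaryCharacterMatrix(np.array(rows, dtype=np.int8), ids,
                                 list(base.locus_ids), smap)
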