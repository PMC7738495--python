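import numpy as np
import pytest

from consortia import FamilyProfile, ProfileMatrix, ReferencePanel


@pytest.fixture
def tiny_panel() -> ReferencePanel:
    """Three genomes, hand-sized so every gain can be enumerated by eye."""
    return ReferencePanel(
        {
            "gA": FamilyProfile("gA", frozenset({"f1", "f2", "f3"})),
            "gB": FamilyProfile("gB", frozenset({"f3", "f4"})),
            "gC": FamilyProfile("gC", frozenset({"f5", "f9"})),
        }
    )


@pytest.fixture
def canonical_tsv(tmp_path):
    """A canonical profile-matrix file for byte-exact round trips."""
    path = tmp_path / "profiles.tsv"
    path.write_text(
        "id\tPF00001\tPF00002\tPF00003\n"
        "s1\t1\t0\t1\n"
        "s2\t0\t1\t1\n",
        encoding="utf-8",
    )
    return path


def random_instance(rng: np.random.Generator, max_genomes=12, max_families=200):
    """A random panel + metagenome pair for oracle comparisons."""
    n_genomes = int(rng.integers(2, max_genomes + 1))
    n_families = int(rng.integers(10, max_families + 1))
    families = [f"PF{i:05d}" for i in range(n_families)]
    genomes = {}
    for g in range(n_genomes):
        p = rng.uniform(0.05, 0.5)
        mask = rng.random(n_families) < p
        if not mask.any():
            mask[int(rng.integers(n_families))] = True
        genomes[f"g{g:02d}"] = FamilyProfile(
            f"g{g:02d}", frozenset(f for f, m in zip(families, mask) if m)
        )
    meta_mask = rng.random(n_families) < rng.uniform(0.2, 0.8)
    if not meta_mask.any():
        meta_mask[0] = True
    meta = FamilyProfile("meta", frozenset(f for f, m in zip(families, meta_mask) if m))
    return ReferencePanel(genomes), meta
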