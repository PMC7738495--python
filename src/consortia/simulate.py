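"""Synthetic data with planted ground truth for every pipeline stage.

Three generators mirror the three kinds of input the pipeline consumes:

* a reference panel of genome family profiles with a shared core and random
  accessory content (plus a disjoint-block variant for exact recovery
  experiments);
* a cohort of metagenome profiles, each the family union of a planted
  community of panel genomes, perturbed by false-present / false-absent
  noise, optionally with group-private family blocks that induce functional
  clustering by group;
* host-labelled taxon relative-abundance tables with planted host-enriched
  taxa under a zero-inflated log-normal abundance model.

Every generator takes an explicit seed and is bit-reproducible; the planted
truth is returned alongside the data so recovery can be scored exactly.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ecology import AbundanceTable
from .profiles import FamilyProfile, ProfileMatrix, ReferencePanel

__all__ = [
    "CohortTruth",
    "PlantedSample",
    "AbundanceTruth",
    "generate_reference_panel",
    "generate_disjoint_panel",
    "generate_metagenome_cohort",
    "generate_host_abundance_tables",
]


def _family_ids(n: int, prefix: str = "PF") -> list[str]:
    # zero-padded so lexicographic order equals numeric order (stable tie-breaks)
    return [f"{prefix}{i + 1:05d}" for i in range(n)]


def _genome_ids(n: int) -> list[str]:
    return [f"G{i + 1:03d}" for i in range(n)]


@dataclass(frozen=True)
class PlantedSample:
    planted_genomes: frozenset[str]
    group: str


@dataclass(frozen=True)
class CohortTruth:
    """Ground truth of a simulated metagenome cohort."""

    samples: Mapping[str, PlantedSample]
    fp_rate: float
    fn_rate: float
    group_private_families: Mapping[str, frozenset[str]] = field(default_factory=dict)


@dataclass(frozen=True)
class AbundanceTruth:
    """Ground truth of a simulated host-labelled abundance table."""

    enriched_taxa: frozenset[str]
    target_host: str
    effect_size: float
    sigma_log: float
    zero_inflation: Mapping[str, float]
    zeroed_samples: tuple[str, ...] = ()  # rows that came out entirely zero

    def __post_init__(self) -> None:
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")


def generate_reference_panel(
    n_genomes: int = 110,
    n_families: int = 400,
    core_fraction: float = 0.25,
    accessory_prob: float = 0.3,
    seed: int = 0,
) -> ReferencePanel:
    """Panel of genomes sharing a core plus independent accessory families.

    ``round(core_fraction * n_families)`` families are present in every
    genome; each remaining family enters each genome independently with
    probability ``accessory_prob``.
    """
    if n_genomes < 1:
        raise ValueError("need at least one genome")
    if not (0.0 <= core_fraction <= 1.0 and 0.0 <= accessory_prob <= 1.0):
        raise ValueError("core_fraction and accessory_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    families = _family_ids(n_families)
    n_core = round(core_fraction * n_families)
    core = families[:n_core]
    accessory = np.asarray(families[n_core:], dtype=object)
    genomes: dict[str, FamilyProfile] = {}
    for gid in _genome_ids(n_genomes):
        mask = rng.random(len(accessory)) < accessory_prob
        genomes[gid] = FamilyProfile(gid, frozenset(core) | frozenset(accessory[mask]))
    return ReferencePanel(genomes, frozenset(families))


def generate_disjoint_panel(
    n_genomes: int,
    families_per_genome: int = 30,
    seed: int = 0,
) -> ReferencePanel:
    """Panel of pairwise-disjoint genomes with equal family counts.

    Families are shuffled and dealt out in equal blocks, so a noise-free
    union of any subset yields an exactly linear coverage curve — the setting
    where planted communities are recoverable exactly.
    """
    if n_genomes < 1 or families_per_genome < 1:
        raise ValueError("n_genomes and families_per_genome must be positive")
    rng = np.random.default_rng(seed)
    families = np.asarray(_family_ids(n_genomes * families_per_genome), dtype=object)
    rng.shuffle(families)
    genomes = {
        gid: FamilyProfile(
            gid,
            frozenset(families[i * families_per_genome : (i + 1) * families_per_genome]),
        )
        for i, gid in enumerate(_genome_ids(n_genomes))
    }
    return ReferencePanel(genomes, frozenset(families))


def generate_metagenome_cohort(
    panel: ReferencePanel,
    n_samples: int,
    community_size: int | tuple[int, int] = (3, 8),
    fp_rate: float = 0.0,
    fn_rate: float = 0.0,
    groups: Mapping[str, int] | None = None,
    group_private_families: int = 0,
    genome_weights: Sequence[float] | None = None,
    seed: int = 0,
) -> tuple[ProfileMatrix, CohortTruth]:
    """Simulate metagenome profiles as noisy unions of planted communities.

    Each sample plants ``community_size`` genomes (an int, or an inclusive
    ``(lo, hi)`` range sampled uniformly) drawn without replacement from the
    panel, takes the union of their families, adds its group's private family
    block, then flips noise: every present family is dropped with probability
    ``fn_rate`` and every absent family (panel universe plus all private
    blocks) appears with probability ``fp_rate``.

    ``groups`` maps group name to its number of samples (must sum to
    ``n_samples``); by default all samples belong to one group ``"all"``.
    ``group_private_families`` families are private to each group and shared
    by all its samples, inducing within-group functional similarity.

    ``genome_weights`` (one non-negative weight per genome in sorted id
    order) biases planting: skewed weights make some genomes recur across
    most samples, the way archetypal taxa recur across real microbiomes.
    Uniform by default.
    """
    if n_samples < 1:
        raise ValueError("need at least one sample")
    if not (0.0 <= fp_rate <= 1.0 and 0.0 <= fn_rate <= 1.0):
        raise ValueError("noise rates must lie in [0, 1]")
    if isinstance(community_size, int):
        lo = hi = community_size
    else:
        lo, hi = community_size
    if not 1 <= lo <= hi <= len(panel):
        raise ValueError("community sizes must lie in [1, panel size]")
    if groups is None:
        groups = {"all": n_samples}
    if sum(groups.values()) != n_samples:
        raise ValueError("group sizes must sum to n_samples")
    if group_private_families < 0:
        raise ValueError("group_private_families must be non-negative")

    rng = np.random.default_rng(seed)
    genome_ids = np.asarray(sorted(panel.genome_ids), dtype=object)
    probs = None
    if genome_weights is not None:
        w = np.asarray(genome_weights, dtype=float)
        if w.shape != genome_ids.shape or (w < 0).any() or w.sum() == 0:
            raise ValueError("genome_weights needs one non-negative weight per genome")
        probs = w / w.sum()

    private: dict[str, frozenset[str]] = {}
    for gi, group in enumerate(sorted(groups)):
        block = _family_ids(group_private_families, prefix=f"GP{gi + 1:02d}_")
        private[group] = frozenset(block)
    universe = sorted(panel.family_universe | frozenset().union(*private.values()))
    fam_index = {f: j for j, f in enumerate(universe)}

    sample_groups = [g for g in sorted(groups) for _ in range(groups[g])]
    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    presence = np.zeros((n_samples, len(universe)), dtype=np.uint8)
    truth_samples: dict[str, PlantedSample] = {}
    for i, (sid, group) in enumerate(zip(sample_ids, sample_groups)):
        k = int(rng.integers(lo, hi + 1))
        planted = rng.choice(genome_ids, size=k, replace=False, p=probs)
        present: set[str] = set(private[group])
        for gid in planted:
            present |= panel[str(gid)].families
        row = np.zeros(len(universe), dtype=bool)
        for f in present:
            row[fam_index[f]] = True
        noise = rng.random(len(universe))
        keep = row & (noise >= fn_rate)
        flip_in = ~row & (noise < fp_rate)
        presence[i] = (keep | flip_in).astype(np.uint8)
        truth_samples[sid] = PlantedSample(frozenset(str(g) for g in planted), group)

    matrix = ProfileMatrix(tuple(sample_ids), tuple(universe), presence)
    truth = CohortTruth(
        samples=truth_samples,
        fp_rate=fp_rate,
        fn_rate=fn_rate,
        group_private_families={g: b for g, b in private.items() if b},
    )
    return matrix, truth


def generate_host_abundance_tables(
    n_taxa: int = 40,
    hosts: Sequence[str] = ("pig", "mouse", "human"),
    n_per_host: int = 50,
    enriched_taxa: int | Sequence[str] = 3,
    effect_size: float = 4.0,
    zero_inflation: float | Mapping[str, float] = 0.1,
    seed: int = 0,
    target_host: str | None = None,
    sigma_log: float = 0.8,
) -> tuple[AbundanceTable, AbundanceTruth]:
    """Simulate host-labelled relative abundances with planted enrichment.

    Raw abundances of taxon *t* in a sample are log-normal with a
    taxon-specific baseline (log-mean drawn once per taxon from N(0, 1)) and
    ``sigma_log`` spread; taxa in the enriched set are multiplied by
    ``effect_size`` in the target host (default: the first host).  Entries
    are then zeroed with the host's ``zero_inflation`` probability and each
    row is normalised to sum to 1.  Rows that end up entirely zero are left
    zero and flagged in the truth record.

    ``enriched_taxa`` may be a count (the first taxa are planted) or an
    explicit sequence of taxon ids; ``effect_size = 1`` plants nothing.
    """
    if n_taxa < 1 or n_per_host < 1:
        raise ValueError("n_taxa and n_per_host must be positive")
    if effect_size <= 0:
        raise ValueError("effect_size must be positive")
    hosts = list(hosts)
    if target_host is None:
        target_host = hosts[0]
    if target_host not in hosts:
        raise ValueError(f"target host {target_host!r} not among hosts")
    if isinstance(zero_inflation, Mapping):
        zi = {h: float(zero_inflation[h]) for h in hosts}
    else:
        zi = {h: float(zero_inflation) for h in hosts}
    if any(not 0.0 <= v <= 1.0 for v in zi.values()):
        raise ValueError("zero_inflation must lie in [0, 1]")

    taxa = [f"T{i + 1:03d}" for i in range(n_taxa)]
    if isinstance(enriched_taxa, int):
        if not 0 <= enriched_taxa <= n_taxa:
            raise ValueError("enriched taxon count out of range")
        enriched = frozenset(taxa[:enriched_taxa])
    else:
        enriched = frozenset(enriched_taxa)
        if not enriched <= set(taxa):
            raise ValueError("enriched_taxa must be generated taxon ids")
    if effect_size == 1.0:
        enriched = frozenset()  # no shift → nothing is actually planted

    rng = np.random.default_rng(seed)
    mu = rng.normal(0.0, 1.0, size=n_taxa)  # taxon-specific baseline log-mean
    enriched_idx = [i for i, t in enumerate(taxa) if t in enriched]
    # planted taxa get the typical baseline: a multiplicative shift on a
    # community dominant self-dilutes under row normalisation and would not
    # represent the modest-abundance taxa host enrichment is about
    mu[enriched_idx] = 0.0
    sample_ids: list[str] = []
    host_labels: list[str] = []
    rows: list[np.ndarray] = []
    zeroed: list[str] = []
    enriched_mask = np.asarray([t in enriched for t in taxa])
    for h in hosts:
        for j in range(n_per_host):
            sid = f"{h}_{j + 1:03d}"
            raw = rng.lognormal(mean=mu, sigma=sigma_log)
            if h == target_host:
                raw = np.where(enriched_mask, raw * effect_size, raw)
            raw[rng.random(n_taxa) < zi[h]] = 0.0
            total = raw.sum()
            if total > 0:
                raw = raw / total
            else:
                zeroed.append(sid)
            sample_ids.append(sid)
            host_labels.append(h)
            rows.append(raw)

    data = pd.DataFrame(np.vstack(rows), index=pd.Index(sample_ids), columns=taxa)
    host = pd.Series(host_labels, index=pd.Index(sample_ids))
    table = AbundanceTable(data=data, host=host)
    truth = AbundanceTruth(
        enriched_taxa=enriched,
        target_host=target_host,
        effect_size=effect_size,
        sigma_log=sigma_log,
        zero_inflation=zi,
        zeroed_samples=tuple(zeroed),
    )
    return table, truth
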