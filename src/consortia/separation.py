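"""Group-separation testing of functional profiles by label permutation.

Metagenome presence/absence profiles are compared with the Jaccard distance
(1 − Jaccard index); whether samples cluster by group (e.g. country of
origin) is assessed with a distance-based pseudo-F — the ratio of
between-group to within-group sums of squared distances with the standard
PERMANOVA decomposition — whose null distribution is obtained by permuting
the group labels.  When the number of distinct label arrangements is small
enough the test enumerates all of them and the p-value is exact.
"""

from __future__ import annotations

import math
from collections.abc import Iterator, Mapping, Sequence
from dataclasses import dataclass

import numpy as np

from .profiles import ProfileMatrix

__all__ = [
    "DistanceMatrix",
    "PermTestResult",
    "jaccard_distance_matrix",
    "pseudo_f",
    "permutation_group_test",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """A symmetric distance matrix with zero diagonal over named entities."""

    entity_ids: tuple[str, ...]
    distances: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "entity_ids", tuple(self.entity_ids))
        d = np.asarray(self.distances, dtype=float)
        object.__setattr__(self, "distances", d)
        n = len(self.entity_ids)
        if d.shape != (n, n):
            raise ValueError(f"distance matrix shape {d.shape} does not match {n} entities")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        if (d < -1e-12).any():
            raise ValueError("distances must be non-negative")


@dataclass(frozen=True)
class PermTestResult:
    """Observed pseudo-F, permutation p-value and bookkeeping of the test."""

    statistic: float
    p_value: float
    n_permutations: int
    seed: int
    exhaustive: bool


def jaccard_distance_matrix(matrix: ProfileMatrix) -> DistanceMatrix:
    """Pairwise Jaccard distances (1 − Jaccard index) between all entities.

    Computed from the binary matrix in one shot; a pair of all-zero profiles
    has distance 0 (identical, by the both-empty convention).
    """
    if matrix.n_entities < 2:
        raise ValueError("need at least two entities for a distance matrix")
    b = matrix.presence.astype(np.float64)
    inter = b @ b.T
    sizes = b.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 1.0)
    d = 1.0 - jac
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(matrix.entity_ids, d)


def pseudo_f(d_squared: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Distance-based pseudo-F from squared distances and integer group codes.

    Uses the standard decomposition SS_total = Σ_{i<j} d²_ij / N and
    SS_within = Σ_g Σ_{i<j∈g} d²_ij / n_g;
    F = (SS_between / (a−1)) / (SS_within / (N−a)).  Degenerate cases (no
    distance variation) return 0; a perfect separation (zero within-group
    distances with positive between) returns +inf.
    """
    n = len(codes)
    iu = np.triu_indices(n, k=1)
    ss_total = d_squared[iu].sum() / n
    if ss_total <= 0.0:
        return 0.0
    ss_within = 0.0
    for g in range(n_groups):
        members = np.flatnonzero(codes == g)
        if len(members) > 1:
            sub = d_squared[np.ix_(members, members)]
            ss_within += sub[np.triu_indices(len(members), k=1)].sum() / len(members)
    ss_between = ss_total - ss_within
    if ss_within <= 0.0:
        return math.inf if ss_between > 0 else 0.0
    return (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))


def _multiset_permutations(counts: list[int]) -> Iterator[tuple[int, ...]]:
    """All distinct arrangements of a label multiset given per-label counts."""
    total = sum(counts)
    buf = [0] * total

    def rec(pos: int, counts: list[int]) -> Iterator[tuple[int, ...]]:
        if pos == total:
            yield tuple(buf)
            return
        for label, c in enumerate(counts):
            if c:
                counts[label] -= 1
                buf[pos] = label
                yield from rec(pos + 1, counts)
                counts[label] += 1

    yield from rec(0, counts)


def permutation_group_test(
    dist: DistanceMatrix,
    labels: Mapping[str, str],
    n_permutations: int = 999,
    seed: int = 0,
) -> PermTestResult:
    """Permutation test of group separation on a distance matrix.

    The observed pseudo-F is compared against label permutations; the sampled
    p-value uses the add-one correction p = (1 + #{F* ≥ F}) / (1 + n_perm).
    If the total number of distinct label arrangements is ≤ ``n_permutations``
    the test enumerates them all and reports the exact p (identity included).
    Every group must have at least two members.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be at least 1")
    ids = dist.entity_ids
    missing = [s for s in ids if s not in labels]
    if missing:
        raise ValueError(f"samples without group labels: {missing}")
    group_names = sorted({labels[s] for s in ids})
    if len(group_names) < 2:
        raise ValueError("need at least two groups")
    code_of = {g: i for i, g in enumerate(group_names)}
    codes = np.array([code_of[labels[s]] for s in ids], dtype=np.intp)
    counts = np.bincount(codes, minlength=len(group_names))
    if (counts < 2).any():
        small = [g for g, c in zip(group_names, counts) if c < 2]
        raise ValueError(f"every group needs at least two members; too small: {small}")

    d2 = dist.distances**2
    n_groups = len(group_names)
    observed = pseudo_f(d2, codes, n_groups)
    if observed == 0.0:
        # no distance variation at all: nothing to separate
        return PermTestResult(0.0, 1.0, 0, seed, exhaustive=True)

    n = len(ids)
    total_arrangements = math.factorial(n)
    for c in counts:
        total_arrangements //= math.factorial(int(c))

    if total_arrangements <= n_permutations:
        hits = 0
        for arrangement in _multiset_permutations([int(c) for c in counts]):
            f = pseudo_f(d2, np.asarray(arrangement, dtype=np.intp), n_groups)
            if f >= observed:
                hits += 1
        return PermTestResult(
            statistic=observed,
            p_value=hits / total_arrangements,
            n_permutations=total_arrangements,
            seed=seed,
            exhaustive=True,
        )

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        if pseudo_f(d2, perm, n_groups) >= observed:
            hits += 1
    return PermTestResult(
        statistic=observed,
        p_value=(1 + hits) / (1 + n_permutations),
        n_permutations=n_permutations,
        seed=seed,
        exhaustive=False,
    )
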