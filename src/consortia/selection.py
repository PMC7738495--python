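"""Greedy minimal-consortium selection with knee-point community sizing.

For each metagenome profile, isolates from a reference panel are ranked by an
iterative scoring that rewards matches (consortium families also present in the
metagenome) and penalises mismatches (consortium families the metagenome lacks):

    score(C) = |C ∩ M| − λ · |C \\ M|

where ``C`` is the pooled family set of the consortium, ``M`` the metagenome's
family set, and λ ≥ 0 the mismatch weight (default 1).  At every step the
genome with the largest marginal score gain is added; ties are broken by
lexicographic genome id so results are fully reproducible.  With λ = 0 this is
the classic greedy maximum-coverage algorithm and inherits its (1 − 1/e)
approximation guarantee.

The number of species kept per sample is then decided from the cumulative
functional-coverage curve: the knee is the step whose point lies furthest
(perpendicular distance) from the chord joining the curve's first and last
points.  Flat or linear curves have no knee, in which case the whole selection
is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np

from .profiles import FamilyProfile, ReferencePanel, functional_coverage

__all__ = [
    "SelectionConfig",
    "CoverageCurve",
    "SelectionResult",
    "consortium_score",
    "marginal_gain",
    "greedy_rank",
    "knee_point",
    "select_minimal_community",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Tunable parameters of the greedy selection.

    lambda_mismatch
        Weight λ of the mismatch penalty; 0 turns the score into pure coverage.
    max_k
        Hard cap on the number of greedy steps (0 = unbounded).
    knee_tolerance
        Minimum chord distance for a knee to count; below it the curve is
        treated as flat/linear and the whole selection is kept.  Set it around
        the noise amplitude of the coverage values (the default 1e-9 only
        catches exactly linear curves).
    stop_on_nonpositive_gain
        Stop as soon as no remaining genome improves the score.
    """

    lambda_mismatch: float = 1.0
    max_k: int = 0
    knee_tolerance: float = 1e-9
    stop_on_nonpositive_gain: bool = True

    def __post_init__(self) -> None:
        if self.lambda_mismatch < 0:
            raise ValueError("lambda_mismatch must be non-negative")
        if self.knee_tolerance < 0:
            raise ValueError("knee_tolerance must be non-negative")
        if self.max_k < 0:
            raise ValueError("max_k must be non-negative (0 = unbounded)")


@dataclass(frozen=True)
class CoverageCurve:
    """Cumulative functional coverage after each greedy step (non-decreasing)."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        values = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", values)
        for v in values:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"coverage value {v} outside [0, 1]")
        if any(b < a for a, b in zip(values, values[1:])):
            raise ValueError("coverage curve must be non-decreasing")

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)

    def __getitem__(self, i):
        return self.values[i]


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of minimal-community selection for one sample.

    ``ranked_genomes`` is the full greedy order, ``community`` its prefix of
    length ``knee_k``.  ``degenerate`` flags the empty selection that arises
    when no genome has positive gain at the first step.
    """

    sample_id: str
    ranked_genomes: tuple[str, ...]
    marginal_scores: tuple[float, ...]
    curve: CoverageCurve
    knee_k: int
    community: tuple[str, ...]
    degenerate: bool = False

    def __post_init__(self) -> None:
        if len(set(self.ranked_genomes)) != len(self.ranked_genomes):
            raise ValueError("ranked_genomes contains duplicates")
        if len(self.marginal_scores) != len(self.ranked_genomes):
            raise ValueError("marginal_scores must align with ranked_genomes")
        if len(self.curve) != len(self.ranked_genomes):
            raise ValueError("curve must have one value per greedy step")
        if self.degenerate:
            if self.ranked_genomes or self.knee_k != 0:
                raise ValueError("degenerate result must be empty with knee_k = 0")
        else:
            if not 1 <= self.knee_k <= len(self.ranked_genomes):
                raise ValueError("knee_k must lie in [1, number of picks]")
        if self.community != self.ranked_genomes[: self.knee_k]:
            raise ValueError("community must be the knee_k-prefix of ranked_genomes")


def consortium_score(
    consortium: FamilyProfile, meta: FamilyProfile, lambda_mismatch: float
) -> float:
    """Matches minus λ-weighted mismatches of a pooled consortium profile."""
    if lambda_mismatch < 0:
        raise ValueError("lambda_mismatch must be non-negative")
    matches = len(consortium.families & meta.families)
    mismatches = len(consortium.families - meta.families)
    return matches - lambda_mismatch * mismatches


def marginal_gain(
    candidate: str,
    current_union: FamilyProfile,
    meta: FamilyProfile,
    panel: ReferencePanel,
    lambda_mismatch: float,
) -> float:
    """Score gain from adding ``candidate`` to the current consortium union.

    Only the candidate's families not already in the union contribute, so a
    candidate fully contained in the union gains exactly 0 for any λ.
    """
    if lambda_mismatch < 0:
        raise ValueError("lambda_mismatch must be non-negative")
    new = panel[candidate].families - current_union.families
    return len(new & meta.families) - lambda_mismatch * len(new - meta.families)


def greedy_rank(
    meta: FamilyProfile,
    panel: ReferencePanel,
    config: SelectionConfig = SelectionConfig(),
) -> tuple[tuple[str, ...], tuple[float, ...], CoverageCurve]:
    """Rank panel genomes by steepest marginal score gain against ``meta``.

    Returns the pick order, the marginal gain realised at each pick, and the
    cumulative coverage curve (coverage of ``meta`` by the union of the first
    i picks).  Iteration stops at ``max_k`` picks, when the panel is
    exhausted, or — with ``stop_on_nonpositive_gain`` — when the best
    remaining gain is ≤ 0.
    """
    if not meta.families:
        raise ValueError("greedy selection needs a non-empty metagenome profile")
    lam = config.lambda_mismatch
    remaining = sorted(panel.genome_ids)
    union: set[str] = set()
    covered = 0
    n_meta = len(meta.families)
    ranked: list[str] = []
    gains: list[float] = []
    curve: list[float] = []
    while remaining:
        if config.max_k and len(ranked) >= config.max_k:
            break
        best_id: str | None = None
        best_gain = -np.inf
        for gid in remaining:  # sorted → lexicographic tie-break via strict >
            new = panel[gid].families - union
            gain = len(new & meta.families) - lam * len(new - meta.families)
            if gain > best_gain:
                best_gain = gain
                best_id = gid
        if config.stop_on_nonpositive_gain and best_gain <= 0:
            break
        assert best_id is not None
        remaining.remove(best_id)
        new = panel[best_id].families - union
        union |= panel[best_id].families
        covered += len(new & meta.families)
        ranked.append(best_id)
        gains.append(float(best_gain))
        curve.append(covered / n_meta)
    return tuple(ranked), tuple(gains), CoverageCurve(tuple(curve))


def knee_point(curve: CoverageCurve | Sequence[float], tolerance: float = 1e-9) -> int:
    """1-based index of the knee of a cumulative coverage curve.

    The knee is the point at maximum perpendicular distance from the chord
    joining the first and last curve points (ties toward the smaller index).
    Curves shorter than 3 points, and curves whose maximum distance falls
    below ``tolerance`` (flat or linear — no knee), return the full curve
    length, i.e. every pick is kept.
    """
    values = np.asarray(list(curve), dtype=float)
    n = len(values)
    if n == 0:
        raise ValueError("knee_point needs a non-empty curve")
    if n < 3:
        return n
    x = np.arange(1, n + 1, dtype=float)
    dx, dy = x[-1] - x[0], values[-1] - values[0]
    norm = float(np.hypot(dx, dy))
    # perpendicular distance of (x_i, y_i) from the first-to-last chord
    dist = np.abs(dy * (x - x[0]) - dx * (values - values[0])) / norm
    best = int(np.argmax(dist))  # argmax takes the first maximum: smaller index wins ties
    if dist[best] < tolerance:
        return n
    return best + 1


def select_minimal_community(
    meta: FamilyProfile,
    panel: ReferencePanel,
    config: SelectionConfig = SelectionConfig(),
    sample_id: str | None = None,
) -> SelectionResult:
    """Full per-sample procedure: greedy ranking, then knee-point truncation.

    The knee never extends a selection — it only truncates the greedy ranking.
    If no genome achieves positive gain at the first step the result is empty
    and flagged ``degenerate``.
    """
    sid = sample_id if sample_id is not None else meta.entity_id
    ranked, gains, curve = greedy_rank(meta, panel, config)
    if not ranked:
        return SelectionResult(
            sample_id=sid,
            ranked_genomes=(),
            marginal_scores=(),
            curve=CoverageCurve(()),
            knee_k=0,
            community=(),
            degenerate=True,
        )
    k = knee_point(curve, config.knee_tolerance)
    return SelectionResult(
        sample_id=sid,
        ranked_genomes=ranked,
        marginal_scores=gains,
        curve=curve,
        knee_k=k,
        community=ranked[:k],
    )
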