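import numpy as np
import pytest

from consortia import (
    FamilyProfile,
    ReferencePanel,
    SelectionConfig,
    consortium_score,
    greedy_rank,
    knee_point,
    marginal_gain,
    select_minimal_community,
    union_profile,
)
from conftest import random_instance


def profile(name, fams):
    return FamilyProfile(name, frozenset(fams))


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def oracle_best_pick(panel, meta, picked, lam):
    """Exhaustive per-step enumeration: recompute every candidate's score gain
    from the full consortium score, pick the max, ties lexicographic."""
    current = union_profile(sorted(picked), panel) if picked else profile("e", set())
    base = consortium_score(current, meta, lam)
    best = None
    for gid in sorted(set(panel.genome_ids) - set(picked)):
        ext = union_profile(sorted(set(picked) | {gid}), panel)
        gain = consortium_score(ext, meta, lam) - base
        if best is None or gain > best[1]:
            best = (gid, gain)
    return best


def oracle_greedy_max_coverage(panel, meta):
    """Classic greedy maximum coverage, written independently with raw sets."""
    covered: set[str] = set()
    order = []
    remaining = sorted(panel.genome_ids)
    while remaining:
        gains = [(len((panel[g].families & meta.families) - covered), g) for g in remaining]
        best_gain = max(g for g, _ in gains)
        gid = min(g for gval, g in gains if gval == best_gain)  # lexicographic tie
        if best_gain <= 0:
            break
        order.append(gid)
        covered |= panel[gid].families & meta.families
        remaining.remove(gid)
    return order


def oracle_knee(values, tolerance=1e-9):
    """Chord-distance knee recomputed point by point with scalar arithmetic."""
    n = len(values)
    if n < 3:
        return n
    x1, y1, xn, yn = 1.0, values[0], float(n), values[-1]
    norm = ((xn - x1) ** 2 + (yn - y1) ** 2) ** 0.5
    best_i, best_d = 1, -1.0
    for i, y in enumerate(values, start=1):
        d = abs((yn - y1) * (i - x1) - (xn - x1) * (y - y1)) / norm
        if d > best_d + 1e-15:
            best_i, best_d = i, d
    return n if best_d < tolerance else best_i


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

class TestScoring:
    @pytest.mark.parametrize(
        "cons, meta, lam, expected",
        [
            ({"f1", "f2"}, {"f1", "f2", "f3"}, 1.0, 2.0),
            ({"f1", "f4"}, {"f1", "f2"}, 1.0, 0.0),
            ({"f1", "f4"}, {"f1", "f2"}, 0.0, 1.0),
        ],
    )
    def test_consortium_score(self, cons, meta, lam, expected):
        assert consortium_score(profile("c", cons), profile("m", meta), lam) == expected

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            consortium_score(profile("c", {"f1"}), profile("m", {"f1"}), -0.5)
        with pytest.raises(ValueError):
            SelectionConfig(lambda_mismatch=-1)

    def test_marginal_gain_counts_only_new_families(self, tiny_panel):
        meta = profile("m", {"f1", "f2", "f3"})
        empty = profile("e", set())
        assert marginal_gain("gA", empty, meta, tiny_panel, 1.0) == 3.0
        # gB adds f4 (mismatch) on top of f3 already present via gA
        current = tiny_panel["gA"]
        assert marginal_gain("gB", current, meta, tiny_panel, 1.0) == -1.0
        # candidate fully contained in the union gains zero for any lambda
        for lam in (0.0, 1.0, 7.0):
            assert marginal_gain("gA", current, meta, tiny_panel, lam) == 0.0


# ---------------------------------------------------------------------------
# Greedy ranking
# ---------------------------------------------------------------------------

class TestGreedyRank:
    def test_hand_checked_instance(self, tiny_panel):
        meta = profile("m", {"f1", "f2", "f3", "f4", "f5"})
        ranked, gains, curve = greedy_rank(meta, tiny_panel, SelectionConfig())
        assert ranked == ("gA", "gB")
        assert gains == (3.0, 1.0)
        assert curve.values == (0.6, 0.8)

    def test_lexicographic_tie_break(self):
        fams = frozenset({"f1", "f2"})
        panel = ReferencePanel(
            {"zz": FamilyProfile("zz", fams), "aa": FamilyProfile("aa", fams)}
        )
        ranked, _, _ = greedy_rank(profile("m", {"f1", "f2"}), panel, SelectionConfig())
        assert ranked[0] == "aa"

    def test_empty_meta_rejected(self, tiny_panel):
        with pytest.raises(ValueError):
            greedy_rank(profile("m", set()), tiny_panel, SelectionConfig())

    def test_max_k_caps_steps(self, tiny_panel):
        meta = profile("m", {"f1", "f2", "f3", "f4", "f5"})
        ranked, _, _ = greedy_rank(meta, tiny_panel, SelectionConfig(max_k=1))
        assert ranked == ("gA",)

    def test_matches_independent_max_coverage_greedy_at_lambda_zero(self):
        rng = np.random.default_rng(20240817)
        cfg = SelectionConfig(lambda_mismatch=0.0)
        for _ in range(25):
            panel, meta = random_instance(rng, max_genomes=8, max_families=60)
            ranked, _, _ = greedy_rank(meta, panel, cfg)
            assert list(ranked) == oracle_greedy_max_coverage(panel, meta)

    def test_every_pick_is_per_step_optimal(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            panel, meta = random_instance(rng, max_genomes=8, max_families=60)
            for lam in (0.0, 1.0):
                cfg = SelectionConfig(lambda_mismatch=lam)
                ranked, gains, _ = greedy_rank(meta, panel, cfg)
                picked: list[str] = []
                for gid, gain in zip(ranked, gains):
                    exp_id, exp_gain = oracle_best_pick(panel, meta, picked, lam)
                    assert gid == exp_id
                    assert gain == pytest.approx(exp_gain)
                    picked.append(gid)

    def test_curve_non_decreasing_and_deterministic(self):
        rng = np.random.default_rng(99)
        for _ in range(10):
            panel, meta = random_instance(rng, max_genomes=10, max_families=80)
            cfg = SelectionConfig(lambda_mismatch=float(rng.choice([0, 0.5, 1, 2])))
            a = greedy_rank(meta, panel, cfg)
            b = greedy_rank(meta, panel, cfg)
            assert a == b
            vals = a[2].values
            assert all(y >= x for x, y in zip(vals, vals[1:]))


# ---------------------------------------------------------------------------
# Knee point
# ---------------------------------------------------------------------------

class TestKneePoint:
    @pytest.mark.parametrize(
        "curve, expected",
        [
            ([0.5, 1.0, 1.0, 1.0, 1.0], 2),  # single right-angle bend
            ([0.25, 0.5, 0.75, 1.0], 4),  # exactly linear -> keep all
            ([0.70, 0.90, 0.95, 0.97, 0.98], 2),  # hand-checked chord distances
            ([0.4], 1),
            ([0.4, 0.9], 2),
        ],
    )
    def test_known_curves(self, curve, expected):
        assert knee_point(curve) == expected
        assert oracle_knee(curve) == expected

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            knee_point([])

    def test_matches_scalar_oracle_on_random_curves(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(3, 25))
            vals = np.sort(rng.random(n)).tolist()
            assert knee_point(vals) == oracle_knee(vals)

    def test_tie_toward_smaller_index(self):
        # symmetric double bend: indices 2 and 4 have equal chord distance
        curve = [0.0, 0.5, 0.5, 0.5, 1.0]
        assert knee_point(curve) == 2


# ---------------------------------------------------------------------------
# Full per-sample selection
# ---------------------------------------------------------------------------

class TestSelectMinimalCommunity:
    def test_single_genome_panel(self):
        panel = ReferencePanel({"g1": profile("g1", {"f1", "f2"})})
        r = select_minimal_community(profile("m", {"f1", "f2"}), panel, SelectionConfig(), "m")
        assert r.community == ("g1",)
        assert r.knee_k == 1
        assert not r.degenerate

    def test_planted_disjoint_instance_recovered_exactly(self):
        # 10 pairwise-disjoint genomes of equal size; meta = union of 4 of them.
        fams = [f"PF{i:04d}" for i in range(120)]
        genomes = {
            f"g{i:02d}": profile(f"g{i:02d}", fams[i * 12 : (i + 1) * 12])
            for i in range(10)
        }
        panel = ReferencePanel(genomes)
        chosen = ["g02", "g04", "g05", "g09"]
        meta = profile("m", frozenset().union(*(genomes[g].families for g in chosen)))
        # brute force: any non-planted genome is disjoint from meta -> gain -12
        for g in set(genomes) - set(chosen):
            assert marginal_gain(g, profile("e", set()), meta, panel, 1.0) == -12.0
        r = select_minimal_community(meta, panel, SelectionConfig(), "m")
        assert sorted(r.community) == chosen
        assert r.knee_k == 4  # linear curve -> no knee -> keep all picks
        assert list(r.curve) == pytest.approx([0.25, 0.5, 0.75, 1.0])

    def test_disjoint_meta_yields_degenerate_empty_result(self, tiny_panel):
        r = select_minimal_community(profile("m", {"zz"}), tiny_panel, SelectionConfig(), "m")
        assert r.degenerate
        assert r.ranked_genomes == ()
        assert r.community == ()
        assert r.knee_k == 0

    def test_knee_truncates_but_never_extends(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            panel, meta = random_instance(rng, max_genomes=10, max_families=80)
            r = select_minimal_community(meta, panel, SelectionConfig())
            if not r.degenerate:
                assert 1 <= r.knee_k <= len(r.ranked_genomes)
                assert r.community == r.ranked_genomes[: r.knee_k]
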