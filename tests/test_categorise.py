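import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dwellsense as dw
from dwellsense.categorise import (
    HSFP,
    LSFP,
    RSFP,
    categorise_scores,
    classify_window,
    mad_deviation_scores,
    project_window,
)
from dwellsense.nmf import acls_nmf, cluster_feature_space
from dwellsense.sfp import SixHourSFP, unflatten_window


def reference_mad_rule(counts, b=1.4826):
    """Independent direct implementation of the categorisation rule."""
    counts = list(counts)
    med = float(np.median(counts))
    devs = [abs(c - med) for c in counts]
    mad = float(np.median(devs))
    if mad == 0:
        scores = [0.0] * len(counts)
    else:
        scores = [d / (b * mad) for d in devs]
    out = []
    for s in scores:
        out.append(HSFP if s < 1 else (LSFP if s < 2.5 else RSFP))
    return scores, out


class TestMADScores:
    def test_zero_dispersion(self):
        assert np.array_equal(mad_deviation_scores([10, 10, 10, 10]), np.zeros(4))

    def test_hand_computed_example(self):
        scores = mad_deviation_scores([50, 48, 52, 49, 2])
        assert scores[4] == pytest.approx(47 / 1.4826, rel=1e-9)
        assert (scores[:4] < 2.5).all()

    def test_single_cluster(self):
        assert np.array_equal(mad_deviation_scores([37]), np.array([0.0]))

    def test_validation(self):
        with pytest.raises(ValueError):
            mad_deviation_scores([])
        with pytest.raises(ValueError):
            mad_deviation_scores([0, 3])

    def test_one_sided_mode_ignores_large_clusters(self):
        two = mad_deviation_scores([100, 20, 21, 22, 19])
        one = mad_deviation_scores([100, 20, 21, 22, 19], one_sided=True)
        assert two[0] > 2.5 and one[0] == 0.0


class TestCategorisation:
    @pytest.mark.parametrize(
        "score,expected",
        [(0.5, HSFP), (1.7, LSFP), (3.0, RSFP), (1.0, LSFP), (2.5, RSFP), (0.999, HSFP)],
    )
    def test_bands_and_boundaries(self, score, expected):
        assert categorise_scores([score]) == [expected]

    def test_every_cluster_gets_exactly_one_category(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            counts = rng.integers(1, 50, size=rng.integers(1, 8))
            cats = categorise_scores(mad_deviation_scores(counts))
            assert len(cats) == len(counts)
            assert set(cats) <= {HSFP, LSFP, RSFP}

    def test_matches_brute_force_rule_for_all_sorted_arrays_up_to_length_5(self):
        # scores are permutation-equivariant (see below), so sorted arrays
        # cover every multiset of cluster sizes in {1..20}
        for length in range(1, 6):
            for counts in itertools.combinations_with_replacement(range(1, 21), length):
                got = categorise_scores(mad_deviation_scores(counts))
                _, want = reference_mad_rule(counts)
                assert got == want, counts

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.integers(1, 30), min_size=1, max_size=6), st.randoms())
    def test_scores_are_permutation_equivariant(self, counts, rnd):
        perm = list(range(len(counts)))
        rnd.shuffle(perm)
        base = mad_deviation_scores(counts)
        shuffled = mad_deviation_scores([counts[i] for i in perm])
        assert np.allclose(shuffled, base[perm])

    def test_shrinking_a_small_cluster_never_moves_it_towards_routine(self):
        # with the median pinned by the other clusters, a below-median count
        # only becomes more deviant as it shrinks
        counts = [20, 20, 20, 20, 8]
        order = {HSFP: 0, LSFP: 1, RSFP: 2}
        last = -1
        for c in range(8, 0, -1):
            counts[4] = c
            cat = categorise_scores(mad_deviation_scores(counts))[4]
            assert order[cat] >= last
            last = order[cat]


@pytest.fixture(scope="module")
def crafted_profile():
    """Three repeated patterns; the third occurs rarely."""
    rng = np.random.default_rng(7)
    pat_a = np.zeros(48)
    pat_a[8:14] = [5, 9, 7, 4, 2, 1]
    pat_b = np.zeros(48)
    pat_b[30:36] = [3, 6, 8, 8, 4, 2]
    pat_rare = np.zeros(48)
    pat_rare[0:48:8] = 12  # hallway firing every hour
    cols = [pat_a] * 20 + [pat_b] * 19 + [pat_rare] * 2
    V = np.column_stack([c + rng.poisson(0.3, 48) for c in cols]).astype(float)
    model = acls_nmf(V, 3, seed=7)
    assignment = cluster_feature_space(model, seed=7)
    profile = dw.categorise_clusters("night", model, assignment)
    return V, profile


class TestClassifyWindow:
    def test_rare_training_member_classifies_rare(self, crafted_profile):
        V, profile = crafted_profile
        assert RSFP in profile.cluster_categories
        sfp = SixHourSFP(
            home_id="h1",
            window_start="2024-02-01 00:00:00",
            category="night",
            counts=unflatten_window(V[:, -1].astype(int)),
        )
        category, cluster = classify_window(sfp, profile)
        assert category == RSFP

    def test_routine_training_member_classifies_routine(self, crafted_profile):
        V, profile = crafted_profile
        sfp = SixHourSFP(
            home_id="h1",
            window_start="2024-02-01 00:00:00",
            category="night",
            counts=unflatten_window(V[:, 0].astype(int)),
        )
        category, _ = classify_window(sfp, profile)
        assert category in (HSFP, LSFP)

    def test_projection_is_nonnegative(self, crafted_profile):
        V, profile = crafted_profile
        h = project_window(V[:, 3], profile.model)
        assert (h >= 0).all()

    def test_missing_category_is_an_error(self, crafted_profile):
        _, cat_profile = crafted_profile
        profile = dw.ClusterProfile(home_id="h1", categories={"night": cat_profile})
        sfp = SixHourSFP(
            home_id="h1",
            window_start="2024-02-01 06:00:00",
            category="morning",
            counts=np.zeros((6, 8), dtype=int),
        )
        with pytest.raises(KeyError):
            classify_window(sfp, profile)
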