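import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synaptage import (
    CandidateParams,
    ClassParams,
    ProfileClass,
    SimConfig,
    TemporalProfile,
    arcsinh_normalize,
    classify_profile,
    classify_proteins,
    cluster_mean_profiles,
    select_candidates,
    simulate_dataset,
    subtract_analogous,
)
from synaptage.network import ClusterSet
from synaptage.profiles import CHANGING_CLASSES

from conftest import make_table


def prof(y, m, o):
    return TemporalProfile(id="x", region="HC", values=(y, m, o))


class TestClassifyProfile:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ((1.0, 1.3, 1.6), ProfileClass.steady_up),
            ((1.6, 1.3, 1.0), ProfileClass.steady_down),
            ((1.0, 1.02, 1.5), ProfileClass.late_up),
            ((1.5, 1.48, 1.0), ProfileClass.late_down),
            ((1.0, 1.01, 1.02), ProfileClass.flat),
            ((1.0, 1.5, 1.0), ProfileClass.early_change),  # rise then fall
            ((1.0, 1.3, 1.35), ProfileClass.early_change),  # real first step, short total
        ],
    )
    def test_stated_rule(self, values, expected):
        assert classify_profile(prof(*values)) is expected

    @given(
        st.tuples(
            st.floats(-5, 5, allow_nan=False),
            st.floats(-5, 5, allow_nan=False),
            st.floats(-5, 5, allow_nan=False),
        )
    )
    @settings(deadline=None, max_examples=300)
    def test_exhaustive_and_mirror_symmetric(self, values):
        cls = classify_profile(prof(*values))
        assert isinstance(cls, ProfileClass)
        mirrored = classify_profile(prof(*(-v for v in values)))
        pairs = {
            ProfileClass.steady_up: ProfileClass.steady_down,
            ProfileClass.steady_down: ProfileClass.steady_up,
            ProfileClass.late_up: ProfileClass.late_down,
            ProfileClass.late_down: ProfileClass.late_up,
            ProfileClass.flat: ProfileClass.flat,
            ProfileClass.early_change: ProfileClass.early_change,
        }
        assert mirrored is pairs[cls]

    def test_planted_classes_recovered_at_moderate_noise(self):
        cfg = SimConfig(n_proteins=500, n_candidates=0, replicate_cv=0.05, seed=13)
        table, truth = simulate_dataset(cfg)
        pred = classify_proteins(arcsinh_normalize(table), "HC")
        truth_cls = truth.classes("HC")
        changing = [p for p, c in truth_cls.items() if c in CHANGING_CLASSES]
        agreement = np.mean([pred[p] is truth_cls[p] for p in changing])
        assert agreement >= 0.90

    def test_flat_max_cannot_exceed_step_min(self):
        with pytest.raises(ValueError):
            ClassParams(step_min=0.1, flat_max=0.2)


class TestClusterMeanProfiles:
    def _table(self):
        return make_table(
            {
                ("HC", "young"): [[1.0], [3.0], [10.0]],
                ("HC", "mid"): [[1.0], [3.0], [10.0]],
                ("HC", "old"): [[1.0], [3.0], [10.0]],
            },
            ["P1", "P2", "P3"],
            normalized=True,
        )

    def test_two_member_cluster_is_arithmetic_mean(self):
        cs = ClusterSet(clusters=[["P1", "P2"]], converged=True, n_iterations=1)
        (profile,) = cluster_mean_profiles(cs, self._table(), "HC")
        assert profile.values == (2.0, 2.0, 2.0)

    def test_singleton_equals_own_profile_when_included(self):
        cs = ClusterSet(clusters=[["P3"]], converged=True, n_iterations=1)
        assert cluster_mean_profiles(cs, self._table(), "HC") == []
        (profile,) = cluster_mean_profiles(cs, self._table(), "HC", include_singletons=True)
        assert profile.values == (10.0, 10.0, 10.0)

    def test_member_order_is_irrelevant(self):
        t = self._table()
        cs1 = ClusterSet(clusters=[["P1", "P2", "P3"]], converged=True, n_iterations=1)
        cs2 = ClusterSet(clusters=[["P3", "P1", "P2"]], converged=True, n_iterations=1)
        assert cluster_mean_profiles(cs1, t, "HC")[0].values == pytest.approx(
            cluster_mean_profiles(cs2, t, "HC")[0].values
        )


class TestSubtractAnalogous:
    def test_shared_class_proteins_are_removed(self):
        a = {"P1": ProfileClass.late_up, "P2": ProfileClass.late_up, "P3": ProfileClass.late_up}
        b = {"P2": ProfileClass.late_up, "P3": ProfileClass.late_up, "P4": ProfileClass.late_up}
        ua, ub, removed = subtract_analogous(a, b)
        assert (ua, ub, removed) == (["P1"], ["P4"], ["P2", "P3"])

    def test_disjoint_sets_remove_nothing(self):
        ua, ub, removed = subtract_analogous(
            {"P1": ProfileClass.steady_up}, {"P2": ProfileClass.steady_up}
        )
        assert removed == [] and ua == ["P1"] and ub == ["P2"]

    def test_class_mismatch_retains_protein(self):
        ua, ub, removed = subtract_analogous(
            {"P1": ProfileClass.steady_up}, {"P1": ProfileClass.late_up}
        )
        assert removed == [] and ua == ["P1"] and ub == ["P1"]

    @given(
        st.dictionaries(st.sampled_from(["P1", "P2", "P3", "P4", "P5"]),
                        st.sampled_from(list(ProfileClass))),
        st.dictionaries(st.sampled_from(["P3", "P4", "P5", "P6"]),
                        st.sampled_from(list(ProfileClass))),
    )
    @settings(deadline=None, max_examples=100)
    def test_three_way_partition_property(self, a, b):
        ua, ub, removed = subtract_analogous(a, b)
        union = set(a) | set(b)
        assert set(ua) | set(ub) | set(removed) == union
        assert set(removed).isdisjoint(ua) and set(removed).isdisjoint(ub)
        for p in set(ua) & set(ub):
            assert a[p] != b[p]  # retained in both only under class mismatch


class TestSelectCandidates:
    def _two_region_table(self, hc, occ):
        cells = {}
        for age, v in zip(("young", "mid", "old"), hc):
            cells[("HC", age)] = [[v] * 3]
        for age, v in zip(("young", "mid", "old"), occ):
            cells[("OCC", age)] = [[v] * 3]
        return make_table(cells, ["P1"], normalized=True)

    def test_divergent_protein_is_a_candidate_with_score(self):
        table = self._two_region_table((1.0, 1.0, 2.0), (1.0, 1.0, 1.0))
        (rep,) = select_candidates(["P1"], table)
        assert rep.verdict
        assert rep.divergence_score == pytest.approx(1.0)

    def test_identical_regions_is_not_a_candidate(self):
        table = self._two_region_table((1.0, 1.2, 1.5), (1.0, 1.2, 1.5))
        (rep,) = select_candidates(["P1"], table)
        assert not rep.verdict
        assert "diverge_old" in rep.gates_failed

    def test_early_divergence_fails_concordance(self):
        table = self._two_region_table((1.5, 1.0, 2.0), (1.0, 1.0, 1.0))
        (rep,) = select_candidates(["P1"], table)
        assert not rep.verdict
        assert "concord_young" in rep.gates_failed

    def test_raising_diverge_min_never_adds_candidates(self, normalized_dataset):
        _, table, _ = normalized_dataset
        loose = select_candidates(table.protein_ids, table, CandidateParams(diverge_min=0.30))
        tight = select_candidates(table.protein_ids, table, CandidateParams(diverge_min=0.50))
        loose_ids = {r.protein for r in loose if r.verdict}
        tight_ids = {r.protein for r in tight if r.verdict}
        assert tight_ids <= loose_ids

    def test_planted_candidates_recovered(self):
        cfg = SimConfig(n_proteins=500, n_candidates=20, replicate_cv=0.10,
                        candidate_divergence_fc=2.0, seed=19)
        table, truth = simulate_dataset(cfg)
        reports = select_candidates(table.protein_ids, arcsinh_normalize(table))
        found = {r.protein for r in reports if r.verdict}
        planted = set(truth.candidates())
        recall = len(found & planted) / len(planted)
        precision = len(found & planted) / len(found)
        assert recall >= 0.9
        assert precision >= 0.8

    def test_reports_sorted_by_descending_divergence(self, normalized_dataset):
        _, table, _ = normalized_dataset
        reports = select_candidates(table.protein_ids, table)
        scores = [r.divergence_score for r in reports]
        assert scores == sorted(scores, reverse=True)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CandidateParams(concord_max=0.5, diverge_min=0.4)
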