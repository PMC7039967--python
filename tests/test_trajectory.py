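import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemangiomics import (
    GroupMeanProfile,
    ShapeClass,
    SimConfig,
    build_basic_list,
    build_profiles,
    classify_shape,
    interpolation_range_filter,
    select_candidates,
    simulate_ih_experiment,
    two_group_ttest,
)
from hemangiomics.trajectory import IH_CONTRASTS, contrast_name


def dense_interpolant_range(m1, m2, m3, n=2001):
    """Independent oracle: evaluate the piecewise-linear interpolant of
    (1,m1),(2,m2),(3,m3) on a dense grid and return its (min, max)."""
    xs = np.linspace(1, 3, n)
    ys = np.interp(xs, [1, 2, 3], [m1, m2, m3])
    return ys.min(), ys.max()


class TestClassifyShape:
    @pytest.mark.parametrize("means,expected", [
        ((4, 3, 2), ShapeClass.LD),
        ((2, 3, 4), ShapeClass.LI),
        ((1, 3, 2), ShapeClass.CD),
        ((3, 1, 2), ShapeClass.CU),
        ((2, 2, 2), ShapeClass.FLAT),
        ((2, 2, 3), ShapeClass.LI),   # one tied difference -> linear class
        ((3, 2, 2), ShapeClass.LD),
    ])
    def test_sign_patterns(self, means, expected):
        assert classify_shape(*means) is expected

    def test_epsilon_turns_small_wiggle_flat(self):
        assert classify_shape(1.0, 1.05, 0.98, epsilon=0.1) is ShapeClass.FLAT
        assert classify_shape(1.0, 1.05, 0.98, epsilon=0.0) is ShapeClass.CD

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.tuples(*[st.integers(-50, 50) for _ in range(3)]),
           st.integers(-100, 100))
    def test_invariant_under_constant_shift(self, means, c):
        # integer grid keeps the shift exact in floating point
        m1, m2, m3 = (float(v) for v in means)
        assert classify_shape(m1, m2, m3) is classify_shape(m1 + c, m2 + c, m3 + c)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.tuples(*[st.floats(-50, 50) for _ in range(3)]))
    def test_negation_swaps_classes(self, means):
        m1, m2, m3 = means
        swap = {ShapeClass.LD: ShapeClass.LI, ShapeClass.LI: ShapeClass.LD,
                ShapeClass.CD: ShapeClass.CU, ShapeClass.CU: ShapeClass.CD,
                ShapeClass.FLAT: ShapeClass.FLAT}
        assert classify_shape(-m1, -m2, -m3) is swap[classify_shape(m1, m2, m3)]


class TestInterpolationRangeFilter:
    @pytest.mark.parametrize("mp,kept", [(2.5, True), (5.0, False), (2.0, True)])
    def test_examples_on_decreasing_profile(self, mp, kept):
        assert interpolation_range_filter(4, 3, 2, mp) is kept

    def test_all_24_strict_arrangements_match_dense_oracle(self):
        """Every strict ordering of {m1,m2,m3} x every placement of mp in
        the 4 resulting intervals agrees with the dense-evaluation oracle."""
        base = [1.0, 2.0, 3.0]
        for m1, m2, m3 in itertools.permutations(base):
            lo, hi = dense_interpolant_range(m1, m2, m3)
            for mp in (0.5, 1.5, 2.5, 3.5):  # one point in each open interval
                expected = bool(lo <= mp <= hi)
                assert interpolation_range_filter(m1, m2, m3, mp) is expected

    def test_boundary_equality_kept(self):
        assert interpolation_range_filter(4, 3, 2, 4.0)
        assert interpolation_range_filter(4, 3, 2, 2.0)


class TestProfilesAndSelection:
    def _profile(self, sig, means=(1.0, 2.0, 3.0, 4.0, 2.5)):
        names = [contrast_name(a, b) for a, b in IH_CONTRASTS]
        return GroupMeanProfile("g", *means, sig=dict(zip(names, sig)))

    @pytest.mark.parametrize("sig,expected", [
        ((False, True, False, False), True),   # only m1-m2
        ((False, False, False, False), False),
        ((False, False, False, True), True),   # only m0-mp
    ])
    def test_select_candidates_is_any_flag(self, sig, expected):
        assert select_candidates(self._profile(sig)) is expected

    def test_build_profiles_means_and_boundary_q(self):
        """Group means are arithmetic means; q exactly at the FDR level
        counts as significant (<=)."""
        cols = [f"{g}_{i}" for g in ("control", "6mo", "12mo", "24mo", "propranolol")
                for i in (1, 2)]
        values = np.array([[1.0, 1, 2, 4, 3, 3, 3, 3, 3, 3]])
        m = pd.DataFrame(values, index=["g1"], columns=cols)
        from hemangiomics import ExpressionMatrix, SampleSheet
        matrix = ExpressionMatrix(m)
        sheet = SampleSheet(pd.DataFrame(
            {"sample": cols, "group": [c.rsplit("_", 1)[0] for c in cols]}))
        de = pd.DataFrame({
            "feature": ["g1"] * 4,
            "contrast": [contrast_name(a, b) for a, b in IH_CONTRASTS],
            "q": [0.05, 0.2, 0.9, 0.01],
        })
        prof = build_profiles(matrix, sheet, de, fdr=0.05)[0]
        assert prof.m1 == pytest.approx(3.0)  # (2+4)/2
        assert prof.sig[contrast_name("6mo", "control")] is True  # q == fdr
        assert prof.sig[contrast_name("12mo", "6mo")] is False

    def test_missing_contrast_is_error(self):
        cols = [f"{g}_{i}" for g in ("control", "6mo", "12mo", "24mo", "propranolol")
                for i in (1, 2)]
        from hemangiomics import ExpressionMatrix, SampleSheet
        matrix = ExpressionMatrix(pd.DataFrame(np.ones((1, 10)), index=["g1"],
                                               columns=cols))
        sheet = SampleSheet(pd.DataFrame(
            {"sample": cols, "group": [c.rsplit("_", 1)[0] for c in cols]}))
        de = pd.DataFrame({"feature": ["g1"], "q": [0.01],
                           "contrast": [contrast_name("6mo", "control")]})
        with pytest.raises(ValueError, match="missing contrasts"):
            build_profiles(matrix, sheet, de)


class TestBuildBasicList:
    def _profiles(self):
        names = [contrast_name(a, b) for a, b in IH_CONTRASTS]
        sig_yes = dict(zip(names, (True, False, False, False)))
        sig_no = dict(zip(names, (False, False, False, False)))
        return [
            GroupMeanProfile("keep", 1, 4, 3, 2, 2.5, sig=dict(sig_yes)),
            GroupMeanProfile("not_sig", 1, 4, 3, 2, 2.5, sig=dict(sig_no)),
            GroupMeanProfile("out_of_range", 1, 4, 3, 2, 9.0, sig=dict(sig_yes)),
        ]

    def test_composition_of_rules(self):
        basic, calls = build_basic_list(self._profiles())
        assert list(basic.genes) == ["keep"]
        table = calls.set_index("gene")
        assert not table.loc["not_sig", "selected"]
        assert not table.loc["out_of_range", "prop_in_range"]

    def test_selected_implies_sig_and_in_range(self):
        _, calls = build_basic_list(self._profiles())
        sel = calls[calls["selected"]]
        assert (sel["any_significant"] & sel["prop_in_range"]).all()

    def test_empty_profiles_empty_set(self):
        basic, calls = build_basic_list([])
        assert len(basic) == 0
        assert calls.empty

    def test_noisy_simulation_recovers_planted_list(self):
        """Basic list on a low-noise simulation matches the planted
        in-range, non-flat gene set with Jaccard >= 0.95."""
        cfg = SimConfig(n_genes=400, noise_sd=0.05, effect_size=2,
                        samples_per_group=5, seed=17)
        matrix, sheet, truth = simulate_ih_experiment(cfg)
        groups = sheet.group_of()
        de = pd.concat([two_group_ttest(matrix, groups, c) for c in IH_CONTRASTS],
                       ignore_index=True)
        profiles = build_profiles(matrix, sheet, de)
        basic, _ = build_basic_list(profiles, epsilon=cfg.effect_size / 4)
        planted = set(truth.selected.index[truth.selected])
        got = set(basic.genes)
        jaccard = len(got & planted) / len(got | planted)
        assert jaccard >= 0.95
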