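"""Closed-form diversity/gradation indices and Morisita–Horn overlap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rookvoc import complexity as cx
from rookvoc.embed_cluster import NOISE, SoftMembership


def _m(probs, hard=0, uid="u"):
    return SoftMembership(np.asarray(probs, dtype=float), hard, uid)


def _profile(probs, individual="A", unit_type="call", **kw):
    return cx.RepertoireProfile(
        individual=individual,
        unit_type=unit_type,
        mean_probs=np.asarray(probs, dtype=float),
        n_units=1,
        **kw,
    )


class TestEffectiveNumbers:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([1, 0, 0], 1.0),
            ([0.25] * 4, 4.0),
            ([0.5, 0.5, 0.0], 2.0),
        ],
    )
    def test_shannon(self, p, expected):
        assert cx.effective_number_shannon(np.array(p, dtype=float)) == pytest.approx(
            expected, abs=1e-9
        )

    @pytest.mark.parametrize(
        "p, expected",
        [
            ([1, 0], 1.0),
            ([0.2] * 5, 5.0),
            ([0.5, 0.25, 0.25], 1.0 / 0.375),
        ],
    )
    def test_simpson(self, p, expected):
        assert cx.effective_number_simpson(np.array(p, dtype=float)) == pytest.approx(
            expected, abs=1e-9
        )

    def test_invalid_vectors_rejected(self):
        with pytest.raises(ValueError):
            cx.effective_number_shannon(np.array([0.5, 0.4]))
        with pytest.raises(ValueError):
            cx.effective_number_simpson(np.array([1.5, -0.5]))


class TestNormalization:
    @pytest.mark.parametrize(
        "d_eff, K, expected", [(1.0, 5, 0.0), (5.0, 5, 1.0), (2.0, 3, 0.5)]
    )
    def test_linear_map(self, d_eff, K, expected):
        assert cx.normalize_diversity(d_eff, K) == pytest.approx(expected, abs=1e-12)

    def test_single_cluster_degenerate(self):
        with pytest.warns(UserWarning, match="K=1"):
            assert cx.normalize_diversity(1.0, 1) == 0.0

    def test_out_of_range_effective_number(self):
        with pytest.raises(ValueError):
            cx.normalize_diversity(6.0, 5)


class TestGradationAndDiversity:
    def test_one_hot_unit_scores_zero(self):
        m = _m([1.0, 0.0, 0.0])
        assert cx.unit_gradation(m, "shannon").value == 0.0
        assert cx.unit_gradation(m, "simpson").value == 0.0

    def test_uniform_unit_scores_one(self):
        m = _m([0.25] * 4)
        assert cx.unit_gradation(m, "shannon").value == pytest.approx(1.0, abs=1e-12)

    def test_two_cluster_unit_among_eighty(self):
        p = np.zeros(80)
        p[:2] = 0.5
        got = cx.unit_gradation(_m(p), "shannon").value
        assert got == pytest.approx(1.0 / 79.0, abs=1e-12)

    def test_diversity_formula_chain(self):
        prof = _profile([0.5, 0.5, 0.0])
        assert cx.individual_diversity(prof, "simpson").value == pytest.approx(0.5, abs=1e-12)

    def test_gradation_strictly_increases_under_mixing(self):
        K = 6
        one_hot = np.eye(K)[0]
        uniform = np.full(K, 1.0 / K)
        last = {"shannon": -1.0, "simpson": -1.0}
        for lam in np.linspace(0.0, 1.0, 9):
            p = (1 - lam) * one_hot + lam * uniform
            for kind in ("shannon", "simpson"):
                value = cx.unit_gradation(_m(p), kind).value
                assert value > last[kind]
                last[kind] = value


class TestProfiles:
    def test_single_unit_profile_is_its_vector(self):
        prof = cx.build_profile([_m([0.2, 0.8])], "A")
        np.testing.assert_allclose(prof.mean_probs, [0.2, 0.8])

    def test_mean_of_one_hots(self):
        prof = cx.build_profile([_m([1, 0, 0]), _m([0, 1, 0])], "A")
        np.testing.assert_allclose(prof.mean_probs, [0.5, 0.5, 0.0])

    def test_mean_stays_on_simplex(self, rng):
        ms = [_m(np.diag(np.ones(4))[i % 4] * 0.7 + 0.075) for i in range(9)]
        prof = cx.build_profile(ms, "A")
        assert prof.mean_probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_noise_exclusion_switch(self):
        ms = [_m([1, 0], hard=0), _m([0.5, 0.5], hard=NOISE)]
        with_noise = cx.build_profile(ms, "A")
        without = cx.build_profile(ms, "A", include_noise=False)
        np.testing.assert_allclose(with_noise.mean_probs, [0.75, 0.25])
        np.testing.assert_allclose(without.mean_probs, [1.0, 0.0])

    def test_empty_profile_errors(self):
        with pytest.raises(ValueError):
            cx.build_profile([], "A")


class TestMorisitaHorn:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([0.3, 0.7], [0.3, 0.7], 1.0),
            ([1, 0, 0], [0, 0.5, 0.5], 0.0),
            ([0.5, 0.5, 0.0], [0.5, 0.0, 0.5], 0.5),
        ],
    )
    def test_closed_form(self, x, y, expected):
        got = cx.morisita_horn(np.array(x, dtype=float), np.array(y, dtype=float))
        assert got == pytest.approx(expected, abs=1e-9)

    def test_symmetric_and_relabel_invariant(self, rng):
        x = rng.dirichlet(np.ones(6))
        y = rng.dirichlet(np.ones(6))
        assert cx.morisita_horn(x, y) == cx.morisita_horn(y, x)
        perm = rng.permutation(6)
        np.testing.assert_allclose(
            cx.morisita_horn(x, y), cx.morisita_horn(x[perm], y[perm]), rtol=1e-12
        )

    def test_equals_one_iff_identical(self, rng):
        x = rng.dirichlet(np.ones(5))
        assert cx.morisita_horn(x, x) == pytest.approx(1.0, abs=1e-12)
        y = x.copy()
        y[0] += 0.05
        y[1] -= 0.05
        assert cx.morisita_horn(x, y) < 1.0


class TestOverlapMatrices:
    def _profiles(self):
        return [
            _profile([0.5, 0.5, 0], "A", "call", sex="F", colony="S"),
            _profile([0.5, 0.5, 0], "B", "call", sex="M", colony="S"),
            _profile([0, 0, 1.0], "A", "song", sex="F", colony="S"),
            _profile([0.5, 0.5, 0], "B", "song", sex="M", colony="S"),
        ]

    def test_identical_call_profiles_overlap_one(self):
        mats = cx.overlap_matrices(self._profiles())
        call = mats["call"]
        assert call.values[0, 1] == pytest.approx(1.0)
        np.testing.assert_allclose(call.values, call.values.T)

    def test_self_cross_cell_for_disjoint_call_song(self):
        mats = cx.overlap_matrices(self._profiles())
        cross = mats["call_vs_song"]
        assert cross.includes_self_cross
        i = cross.row_labels.index("A")
        assert cross.values[i, i] == pytest.approx(0.0)  # A's call ⊥ A's song
        j = cross.col_labels.index("B")
        assert cross.values[j, j] == pytest.approx(1.0)  # B reuses call units in song

    def test_missing_profile_marked_nan(self):
        profiles = self._profiles()[:3]  # B has no song profile
        mats = cx.overlap_matrices(profiles)
        cross = mats["call_vs_song"]
        j = cross.col_labels.index("B")
        assert np.isnan(cross.values[0, j])

    def test_heatmap_order_is_permutation(self):
        mats = cx.overlap_matrices(self._profiles())
        order = cx.heatmap_order(mats["call"])
        assert sorted(order) == list(range(len(mats["call"].row_labels)))


class TestTidyExports:
    def test_factor_coding(self):
        assert cx.pair_factors("F", "M", "S", "S") == ("FM", "within")
        assert cx.pair_factors("M", "F", "S", "C") == ("FM", "between")
        assert cx.pair_factors("F", "F", "S", "C") == ("FF", "between")

    def test_tidy_table_rows_and_roundtrip(self, tmp_path):
        profiles = [
            _profile([1, 0], "A", "call", sex="F", colony="S"),
            _profile([1, 0], "B", "call", sex="M", colony="S"),
            _profile([0, 1], "C", "call", sex="F", colony="C"),
        ]
        mats = cx.overlap_matrices(profiles)
        tidy = cx.overlap_tidy_table(mats, profiles)
        assert len(tidy) == 3  # 3 unordered pairs in the call block
        fm = tidy[(tidy.individual_a == "A") & (tidy.individual_b == "B")].iloc[0]
        assert fm.sex_pair == "FM" and fm.colony_pair == "within"

        grad = pd.DataFrame(
            [
                {
                    "unit_id": "u0",
                    "individual": "A",
                    "sex": "F",
                    "colony": "S",
                    "unit_type": "call",
                    "index_kind": "shannon",
                    "value": 0.25,
                }
            ]
        )
        div = pd.DataFrame(
            [
                {
                    "individual": "A",
                    "sex": "F",
                    "colony": "S",
                    "unit_type": "call",
                    "index_kind": "shannon",
                    "value": 0.5,
                }
            ]
        )
        paths = cx.export_stats_tables(grad, div, tidy, tmp_path)
        back = pd.read_csv(paths["gradation"])
        assert back.loc[0, "value"] == 0.25

    def test_missing_metadata_column_is_schema_error(self, tmp_path):
        bad = pd.DataFrame([{"unit_id": "u0", "value": 0.1}])
        ok = pd.DataFrame(
            [
                {
                    "individual": "A",
                    "sex": "F",
                    "colony": "S",
                    "unit_type": "call",
                    "index_kind": "shannon",
                    "value": 0.5,
                }
            ]
        )
        with pytest.raises(ValueError, match="missing column"):
            cx.export_stats_tables(bad, ok, pd.DataFrame(), tmp_path)


class TestSimplexProperties:
    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(0.01, 10.0), min_size=2, max_size=12))
    def test_indices_bounded_and_ordered(self, weights):
        p = np.array(weights) / np.sum(weights)
        K = p.size
        d1 = cx.effective_number_shannon(p)
        d2 = cx.effective_number_simpson(p)
        assert 1.0 - 1e-9 <= d2 <= d1 + 1e-9 <= K + 2e-9
        n1 = cx.normalize_diversity(d1, K)
        n2 = cx.normalize_diversity(d2, K)
        assert 0.0 <= n2 <= n1 + 1e-9 and n1 <= 1.0
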