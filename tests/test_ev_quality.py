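import copy

import numpy as np
import pandas as pd
import pytest

from evbal import (
    classify_particle_protein_ratio,
    generate_marker_panels,
    generate_size_distributions,
    log_transform,
    nta_normalize_and_test,
    purity_scores,
    scale_marker_matrix,
)
from evbal.ev_quality import marker_matrix


class TestMarkerScaling:
    def test_minmax_definition(self):
        df = pd.DataFrame([[10.0, 20.0, 30.0]], index=["m"], columns=list("abc"))
        assert scale_marker_matrix(df).values.tolist() == [[0.0, 0.5, 1.0]]

    def test_constant_row_maps_to_half(self):
        df = pd.DataFrame([[7.0, 7.0, 7.0]], index=["m"], columns=list("abc"))
        assert scale_marker_matrix(df).values.tolist() == [[0.5, 0.5, 0.5]]

    def test_rows_span_zero_to_one(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.random((10, 4)) * 100)
        s = scale_marker_matrix(df).values
        assert np.allclose(s.min(axis=1), 0.0)
        assert np.allclose(s.max(axis=1), 1.0)

    def test_rank_variant(self):
        df = pd.DataFrame([[5.0, 1.0, 3.0]], index=["m"], columns=list("abc"))
        assert scale_marker_matrix(df, method="rank").values.tolist() == [[1.0, 0.0, 0.5]]

    def test_scaled_ordering_robust_to_rescaling_interior_column(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.random((20, 4)) + 0.5, columns=list("abcd"))
        scaled = scale_marker_matrix(df)
        bumped = df.copy()
        bumped["b"] = df["b"] * 10.0
        scaled2 = scale_marker_matrix(bumped)
        # rows where column b was neither min nor max keep their ordering
        # of the remaining columns
        for i in range(20):
            r = df.iloc[i]
            if r["b"] not in (r.min(), r.max()):
                rest = [c for c in "acd"]
                assert list(scaled.iloc[i][rest].rank()) == list(
                    scaled2.iloc[i][rest].rank()
                )


class TestPurityScores:
    def test_perfect_separation(self):
        panel, quant = generate_marker_panels(["A", "B"], seed=0)
        ev = panel.ev_markers
        non_ev = panel.non_ev_markers
        scaled = pd.DataFrame(
            1.0, index=ev + non_ev, columns=["A", "B"]
        )
        scaled.loc[non_ev] = 0.0
        rep = purity_scores(scaled, panel)
        assert (rep.ev_score == 1.0).all()
        assert (rep.contamination_score == 0.0).all()

    def test_identical_columns_give_equal_scores(self):
        panel, quant = generate_marker_panels(["A", "B"], seed=1)
        mm = marker_matrix(log_transform(quant), panel)
        mm["B"] = mm["A"]
        scaled = scale_marker_matrix(pd.concat([mm, mm["A"].rename("C")], axis=1))
        rep = purity_scores(scaled, panel)
        assert rep.ev_score["A"] == pytest.approx(rep.ev_score["B"])

    def test_contamination_orders_with_spike_level(self):
        scores = []
        for level in (0.0, 0.01, 0.3):
            panel, quant = generate_marker_panels(
                ["A", "B"], contamination_level=level, noise_sd=0.0, seed=2
            )
            mm = marker_matrix(log_transform(quant), panel)
            # add a clean reference column so min-max has contrast
            ref = mm.mean(axis=1) * 0 + mm.max(axis=1)
            scaled = scale_marker_matrix(pd.concat([mm, ref.rename("ref")], axis=1))
            scores.append(purity_scores(scaled, panel).contamination_score["A"])
        assert scores[0] <= scores[1] <= scores[2]

    def test_missing_markers_error(self):
        panel, quant = generate_marker_panels(["A", "B"], seed=3)
        empty = quant.data.iloc[:0]
        from evbal.containers import QuantMatrix

        with pytest.raises(KeyError, match="missing"):
            marker_matrix(
                QuantMatrix(empty, pd.Series([], dtype=object)), panel
            )


class TestRatioClassification:
    @pytest.mark.parametrize(
        "ratio,expected",
        [
            (4e10, "high"),
            (5e9, "low"),
            (2.5e10, "indeterminate"),
            (1e9, "below-low"),
            (2e9, "low"),
            (2e10, "low"),
            (3e10, "indeterminate"),
            (3.0000001e10, "high"),
        ],
    )
    def test_thresholds(self, ratio, expected):
        assert classify_particle_protein_ratio(ratio, 1.0) == expected

    def test_total_on_positive_ratios(self):
        rng = np.random.default_rng(0)
        for r in 10 ** rng.uniform(0, 14, 200):
            assert classify_particle_protein_ratio(r, 1.0) in {
                "high",
                "low",
                "indeterminate",
                "below-low",
            }

    def test_nonpositive_protein_rejected(self):
        with pytest.raises(ValueError):
            classify_particle_protein_ratio(1e10, 0.0)


class TestNTA:
    def _group_of_clones(self, n_per_group=3, seed=0):
        d = generate_size_distributions(1, seed=seed)[0]
        dists, groups = [], {}
        for i in range(2 * n_per_group):
            c = copy.deepcopy(d)
            c.sample_id = f"S{i}"
            dists.append(c)
            groups[f"S{i}"] = "ctrl" if i < n_per_group else "case"
        return dists, groups

    def test_identical_groups_give_t_zero_p_one(self):
        dists, groups = self._group_of_clones()
        comp = nta_normalize_and_test(dists, groups)
        assert (comp.per_bin["t"] == 0.0).all()
        assert (comp.per_bin["p_value"] == 1.0).all()

    def test_normalization_sums_to_one(self):
        dists = generate_size_distributions(6, seed=1)
        groups = {d.sample_id: ("a" if i < 3 else "b") for i, d in enumerate(dists)}
        comp = nta_normalize_and_test(dists, groups)
        assert np.allclose(comp.normalized.sum(axis=0).values, 1.0, atol=1e-9)

    def test_null_false_positive_rate_near_nominal(self):
        """Independent draws from one generator split into two arbitrary
        groups: the per-bin raw rejection rate stays near 5%."""
        rates = []
        for rep in range(30):
            dists = generate_size_distributions(8, n_particles=20000, seed=rep)
            groups = {
                d.sample_id: ("a" if i % 2 == 0 else "b")
                for i, d in enumerate(dists)
            }
            comp = nta_normalize_and_test(dists, groups)
            # restrict to bins with real mass so the t-test is defined
            pb = comp.per_bin[comp.per_bin[["mean_a", "mean_b"]].max(axis=1) > 1e-5]
            rates.append((pb["p_value"] < 0.05).mean())
        assert 0.03 <= np.mean(rates) <= 0.07

    def test_small_group_rejected(self):
        dists, groups = self._group_of_clones(n_per_group=1)
        with pytest.raises(ValueError, match="fewer than 2"):
            nta_normalize_and_test(dists, groups)

    def test_modal_size_reported(self):
        dists, groups = self._group_of_clones()
        comp = nta_normalize_and_test(dists, groups)
        assert (comp.per_sample["modal_size_nm"] > 50).all()
        assert (comp.per_sample["modal_size_nm"] < 200).all()
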