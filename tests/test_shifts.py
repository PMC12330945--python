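"""Shift statistics: delta-Tm, significance, classification, ranking, DEP."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from meltshift import (
    SimulationConfig,
    UnfoldingFit,
    analyze_shifts,
    benjamini_hochberg,
    classify_and_rank,
    classify_dep,
    compute_shift,
    significance_scores,
    simulate_dataset,
)


def _fit(tm, cond="vehicle"):
    return UnfoldingFit("P", cond, -0.8, 51.0, 0.1, tm, 0.99, 0.01, 18, True)


class TestComputeShift:
    @pytest.mark.parametrize(
        "tm_c, tm_t, expected", [(50.0, 55.0, 5.0), (56.0, 64.0, 8.0), (51.0, 51.0, 0.0)]
    )
    def test_shift_values(self, tm_c, tm_t, expected):
        assert compute_shift(_fit(tm_c), _fit(tm_t, "treated")) == pytest.approx(expected)

    def test_antisymmetric_under_condition_swap(self):
        d = compute_shift(_fit(50.0), _fit(53.5, "treated"))
        assert compute_shift(_fit(53.5), _fit(50.0, "treated")) == pytest.approx(-d)

    def test_undefined_tm_gives_none(self):
        assert compute_shift(_fit(None), _fit(55.0, "treated")) is None


def brute_force_bh(p):
    """Independent step-up BH oracle: q_i = min over j>=i of p_(j) * n / j."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    running = np.inf
    for rank_pos in range(n - 1, -1, -1):
        i = order[rank_pos]
        running = min(running, p[i] * n / (rank_pos + 1))
        q[i] = min(running, 1.0)
    return q


class TestBenjaminiHochberg:
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=20)
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_brute_force(self, pvals):
        np.testing.assert_allclose(benjamini_hochberg(pvals), brute_force_bh(pvals), atol=1e-12)

    def test_nan_passthrough(self):
        q = benjamini_hochberg([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and np.isfinite(q[0])


class TestSignificanceScores:
    def test_proteome_null_flags_single_large_shift(self):
        rng = np.random.default_rng(8)
        deltas = np.concatenate([rng.normal(0, 0.5, 999), [6.0]])
        scores = significance_scores(deltas, mode="proteome_null")
        assert int(np.argmax(np.abs(scores["z_score"]))) == 999
        assert scores["q_value"].iloc[999] < 0.05

    def test_degenerate_null_all_zero_z(self):
        scores = significance_scores(np.full(10, 1.5), mode="proteome_null")
        np.testing.assert_allclose(scores["z_score"], 0.0)

    def test_too_few_proteins_raises(self):
        with pytest.raises(ValueError, match="at least 3"):
            significance_scores([1.0, np.nan, np.nan], mode="proteome_null")

    def test_replicate_mode_matches_closed_form_t(self):
        vals = np.array([5.0, 5.1, 4.9])
        # closed form: t = mean / (sd / sqrt(3))
        t_expected = vals.mean() / (vals.std(ddof=1) / np.sqrt(3))
        p_expected = 2 * stats.t.sf(abs(t_expected), df=2)
        scores = significance_scores(
            [5.0], mode="replicate", replicate_deltas={"P1": vals}, protein_ids=["P1"]
        )
        assert scores["z_score"].iloc[0] == pytest.approx(t_expected)
        assert scores["p_value"].iloc[0] == pytest.approx(p_expected)
        assert scores["p_value"].iloc[0] < 0.01


class TestClassifyAndRank:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["protein_id", "delta_tm", "q_value", "qc_pass"])

    @pytest.mark.parametrize(
        "delta, q, expected",
        [
            (6.4, 0.001, "stabilized"),
            (1.0, 0.001, "unchanged"),   # below the 2 degC threshold
            (-3.0, 0.01, "destabilized"),
            (2.0, 0.05, "stabilized"),   # boundaries inclusive
            (3.0, 0.2, "unchanged"),     # not significant
        ],
    )
    def test_classification_rules(self, delta, q, expected):
        df = self._frame(
            [("P1", delta, q, True), ("P2", 0.1, 0.9, True), ("P3", -0.2, 0.8, True)]
        )
        out = classify_and_rank(df)
        assert out.loc[out.protein_id == "P1", "stability_class"].iloc[0] == expected

    def test_rank_by_abs_delta_with_tiebreaks(self):
        df = self._frame(
            [
                ("P_b", 5.0, 0.01, True),
                ("P_a", -5.0, 0.01, True),   # tie on |d| and q -> lexicographic
                ("P_c", 6.0, 0.5, True),
                ("P_f", 1.0, 0.9, False),    # qc_failed, no rank
            ]
        )
        out = classify_and_rank(df).set_index("protein_id")
        assert out.loc["P_c", "rank"] == 1
        assert out.loc["P_a", "rank"] == 2
        assert out.loc["P_b", "rank"] == 3
        assert np.isnan(out.loc["P_f", "rank"])
        assert out.loc["P_f", "stability_class"] == "qc_failed"

    def test_partition_sums_to_total(self):
        rng = np.random.default_rng(4)
        df = self._frame(
            [(f"P{i}", rng.normal(0, 3), rng.random(), rng.random() > 0.2) for i in range(50)]
        )
        out = classify_and_rank(df)
        counts = out["stability_class"].value_counts()
        assert counts.sum() == 50

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            classify_and_rank(self._frame([]))


class TestAntisymmetry:
    def test_condition_swap_negates_shifts_and_swaps_classes(self, small_dataset):
        _, table, _ = small_dataset
        swapped = table.copy()
        swapped["condition"] = swapped["condition"].map(
            {"treated": "vehicle", "vehicle": "treated"}
        )
        a = analyze_shifts(table)
        b = analyze_shifts(swapped)
        m = a.merge(b, on="protein_id", suffixes=("_fwd", "_rev"))
        both = m[m.qc_pass_fwd & m.qc_pass_rev]
        np.testing.assert_allclose(
            both["delta_tm_fwd"], -both["delta_tm_rev"], atol=1e-6
        )
        fwd = a["stability_class"].value_counts()
        rev = b["stability_class"].value_counts()
        assert fwd.get("stabilized", 0) == rev.get("destabilized", 0)
        assert fwd.get("destabilized", 0) == rev.get("stabilized", 0)


class TestClassifyDep:
    def _table(self, ratios, n_rep=3, seed=0):
        # build lowest-temperature intensities with given treated/control ratios
        rows = []
        rng = np.random.default_rng(seed)
        for i, ratio in enumerate(ratios):
            base = 1e6
            for rep in range(1, n_rep + 1):
                jitter = 1 + rng.normal(0, 1e-4)
                rows.append((f"P{i}", "vehicle", rep, 43.0, base * jitter))
                rows.append((f"P{i}", "treated", rep, 43.0, base * ratio * jitter))
        return pd.DataFrame(
            rows, columns=["protein_id", "condition", "replicate", "temperature_c", "intensity"]
        )

    def test_twofold_rule_boundaries(self):
        dep = classify_dep(self._table([2.0, 1.99, 0.5, 1.0])).set_index("protein_id")
        assert dep.loc["P0", "dep_class"] == "up"        # twice or more is inclusive
        assert dep.loc["P1", "dep_class"] == "unchanged"
        assert dep.loc["P2", "dep_class"] == "down"
        assert dep.loc["P3", "dep_class"] == "unchanged"

    def test_log2_fold_change_values(self):
        dep = classify_dep(self._table([4.0, 0.25])).set_index("protein_id")
        assert dep.loc["P0", "log2_fold_change"] == pytest.approx(2.0, abs=1e-3)
        assert dep.loc["P1", "log2_fold_change"] == pytest.approx(-2.0, abs=1e-3)

    def test_zero_control_flagged(self):
        df = self._table([2.0])
        df.loc[df.condition == "vehicle", "intensity"] = 0.0
        dep = classify_dep(df)
        assert dep["dep_class"].iloc[0] == "flagged"
        assert dep["flag"].iloc[0] == "zero_control"


class TestEndToEndRecovery:
    def test_spiked_targets_found_and_partition_holds(self, small_dataset):
        _, table, truths = small_dataset
        out = analyze_shifts(table)
        counts = out["stability_class"].value_counts()
        assert counts.sum() == len(out) == 100
        spiked_up = {t.protein_id for t in truths if t.true_class == "stabilized"}
        called_up = set(out.loc[out.stability_class == "stabilized", "protein_id"])
        # at 6 degC spikes and 8% noise nearly all spiked targets are called
        assert len(spiked_up & called_up) >= 8
        # estimated shifts close to the spiked truth
        est = out.set_index("protein_id").loc[sorted(spiked_up & called_up), "delta_tm"]
        assert np.median(np.abs(est - 6.0)) < 1.0
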