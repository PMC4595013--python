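"""Fold-change computation, Z-transformation, testing and cycling filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tests.conftest import toy_dataset
from triomic.containers import LAYERS, TRANSITIONS, FoldChangeMatrix
from triomic.cycle_stats import (
    bh_adjust,
    fc_threshold_filter,
    fold_changes,
    gobp_subset,
    one_sample_test,
    select_highest_fold_change,
    significant_union_filter,
    zscore_columns,
)


def _single_layer_ds(phase_values: dict[str, list[float]], genes=("g1",)):
    """Dataset with identical values in all layers; phase_values[phase] = per-rep."""
    arr = np.array(
        [[v for p in ("G1", "S", "G2M") for v in phase_values[p]] for _ in genes]
    )
    return toy_dataset({l: arr for l in LAYERS}, list(genes))


class TestFoldChanges:
    def test_transition_arithmetic(self):
        ds = _single_layer_ds({"G1": [1, 1, 1], "S": [3, 3, 3], "G2M": [2, 2, 2]})
        fcm = fold_changes(ds)
        row = fcm.mean_fc.loc["g1"]
        assert row[("protein", "S_FC")] == pytest.approx(2.0)  # G1 -> S
        assert row[("protein", "G2M_FC")] == pytest.approx(-1.0)  # S -> G2M
        assert row[("protein", "G1_FC")] == pytest.approx(-1.0)  # G2M -> G1

    def test_cyclic_sum_is_zero_for_complete_genes(self, fcm):
        sums = fcm.mean_fc.T.groupby(level=["layer"]).sum().T
        complete = fcm.mean_fc.notna().all(axis=1)
        assert np.abs(sums[complete].to_numpy()).max() < 1e-9

    def test_min_reps_rule_blanks_dependent_transitions(self):
        arr = np.array([[1.0, 1, 1, 3, np.nan, np.nan, 2, 2, 2]])
        ds = toy_dataset({l: arr for l in LAYERS}, ["g1"])
        fcm = fold_changes(ds, min_reps=2)
        row = fcm.mean_fc.loc["g1"]
        assert np.isnan(row[("protein", "S_FC")])  # one S replicate only
        assert np.isnan(row[("protein", "G2M_FC")])  # S mean unavailable
        assert np.isfinite(row[("protein", "G1_FC")])

    def test_unknown_phase_label_errors(self):
        with pytest.raises(ValueError):
            toy_dataset({"protein": np.ones((1, 9))}, ["g1"]).layers["protein"].samples[
                0
            ].__class__("protein", "M", 1)


class TestZscore:
    def test_unit_normalization(self):
        # phase means per gene: G1 = 0 / 0.5 / 1.5, S adds (1, 2, 3), G2M adds more,
        # so every fold-change column varies across genes
        g1 = np.array([0.0, 0.5, 1.5])
        s = g1 + np.array([1.0, 2.0, 3.0])
        g2m = s + np.array([2.0, 1.0, 0.5])
        arr = np.column_stack([np.repeat(g1, 3).reshape(3, 3),
                               np.repeat(s, 3).reshape(3, 3),
                               np.repeat(g2m, 3).reshape(3, 3)])
        ds = toy_dataset({l: arr for l in LAYERS}, ["g1", "g2", "g3"])
        fcm = zscore_columns(fold_changes(ds))
        # every z column has mean 0 and sd 1 over non-missing genes
        assert np.allclose(fcm.z.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(fcm.z.std(axis=0, ddof=1).dropna(), 1.0, atol=1e-9)
        # the S_FC column (1, 2, 3) standardizes to (-1, 0, 1)
        assert np.allclose(fcm.z[("protein", "S_FC", 1)], [-1.0, 0.0, 1.0])

    def test_missing_entries_stay_missing(self, fcm):
        assert fcm.z.isna().equals(fcm.fc.isna())

    def test_zero_spread_column_errors(self):
        ds = _single_layer_ds({"G1": [1, 1, 1], "S": [2, 2, 2], "G2M": [3, 3, 3]},
                              genes=("g1", "g2"))
        with pytest.raises(ValueError, match="spread"):
            zscore_columns(fold_changes(ds))


def _fcm_from_z(z_by_gene: dict[str, list[float]]) -> FoldChangeMatrix:
    """FoldChangeMatrix with given replicate z-values in one (layer, transition)."""
    cols = pd.MultiIndex.from_tuples(
        [("protein", "S_FC", r) for r in (1, 2, 3)], names=["layer", "transition", "replicate"]
    )
    z = pd.DataFrame.from_dict(z_by_gene, orient="index")
    z.columns = cols
    fcm = FoldChangeMatrix(fc=z.copy(), mean_fc=z.T.groupby(level=[0, 1]).mean().T, n=z.notna()
                           .T.groupby(level=[0, 1]).sum().T)
    fcm.z = z
    fcm.mean_z = fcm.mean_fc
    return fcm


class TestOneSampleTest:
    def test_t_statistic_and_p_match_closed_form(self):
        res = one_sample_test(_fcm_from_z({"g1": [0.9, 1.0, 1.1]}))
        row = res.iloc[0]
        assert row["t"] == pytest.approx(17.3205, abs=1e-3)
        # closed-form survival of Student t with df=2: p = 1 - t/sqrt(t^2+2)
        t = 17.3205080757
        p_closed = 1.0 - t / np.sqrt(t**2 + 2.0)
        assert row["p"] == pytest.approx(p_closed, rel=1e-6)
        assert row["p"] == pytest.approx(3.3e-3, abs=2e-4)

    def test_zero_variance_is_degenerate_without_p(self):
        res = one_sample_test(_fcm_from_z({"g1": [1.0, 1.0, 1.0]}))
        assert bool(res.iloc[0]["degenerate"])
        assert np.isnan(res.iloc[0]["p"])

    def test_bh_within_family(self):
        rng = np.random.default_rng(0)
        z = {f"g{i}": list(rng.normal(size=3)) for i in range(20)}
        res = one_sample_test(_fcm_from_z(z))
        valid = res.dropna(subset=["p"])
        assert (valid["q"] >= valid["p"] - 1e-12).all()


class TestBH:
    def test_identity_cases(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_textbook_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_brute_force_step_up_oracle(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=100)
        # independent step-up enumeration
        order = np.argsort(p)
        m = len(p)
        q_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(q_sorted, 1.0)
        assert np.allclose(bh_adjust(p), expected)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_q_dominates_p_and_stays_in_unit_interval(self, p):
        q = bh_adjust(p)
        assert (q >= np.asarray(p) - 1e-12).all() and (q <= 1.0 + 1e-12).all()


class TestFilters:
    def test_union_semantics(self):
        res = pd.DataFrame(
            {
                "gene": ["g1", "g1", "g2"],
                "layer": ["protein"] * 3,
                "transition": ["G2M_FC", "S_FC", "S_FC"],
                "q": [0.01, 0.9, 0.9],
            }
        )
        assert list(significant_union_filter(res)) == ["g1"]

    def test_fc_threshold_two_of_three_layers(self):
        cols = pd.MultiIndex.from_product([LAYERS, TRANSITIONS], names=["layer", "transition"])
        mean_fc = pd.DataFrame(0.0, index=["gin", "gone", "gout"], columns=cols)
        # gin: two layers reach |fc| >= log2(1.5) = 0.585 at one transition
        mean_fc.loc["gin", ("mRNA", "S_FC")] = 0.7
        mean_fc.loc["gin", ("translation", "S_FC")] = 0.9
        mean_fc.loc["gin", ("protein", "S_FC")] = 0.1
        # gone: only a single layer crosses the threshold
        mean_fc.loc["gone", ("protein", "G2M_FC")] = 0.8
        # gout: 0.5 everywhere (below log2(1.5) = 0.585)
        mean_fc.loc["gout"] = 0.5
        fcm = FoldChangeMatrix(fc=pd.DataFrame(), mean_fc=mean_fc, n=mean_fc.notna())
        assert list(fc_threshold_filter(fcm, fold=1.5, min_layers=2)) == ["gin"]
        assert list(fc_threshold_filter(fcm, fold=1.5, min_layers=1)) == ["gin", "gone"]

    def test_threshold_filter_monotone_in_fold(self, fcm):
        sizes = [len(fc_threshold_filter(fcm, fold=f)) for f in (1.2, 1.5, 2.0, 4.0)]
        assert sizes == sorted(sizes, reverse=True)

    def test_gobp_mask(self):
        ann = pd.DataFrame(
            {"gene": ["g1", "g2"], "term": ["Cell division", "Glycolysis"]}
        )
        mask = gobp_subset(ann, pd.Index(["g1", "g2", "g3"]))
        assert mask.tolist() == [True, False, False]
        empty = gobp_subset(ann.iloc[:0], pd.Index(["g1"]))
        assert not empty.any()

    def test_histone_paralogs_deduplicated_by_max_fold_change(self):
        cols = pd.MultiIndex.from_product([LAYERS, TRANSITIONS], names=["layer", "transition"])
        mean_fc = pd.DataFrame(0.1, index=["h1", "h2", "x1"], columns=cols)
        mean_fc.loc["h2", ("mRNA", "S_FC")] = 3.0
        fcm = FoldChangeMatrix(fc=pd.DataFrame(), mean_fc=mean_fc, n=mean_fc.notna())
        groups = pd.Series({"h1": "H3", "h2": "H3"})
        kept = select_highest_fold_change(fcm, groups)
        assert set(kept) == {"h2", "x1"}


class TestNullCalibration:
    def test_flagged_fraction_decreases_with_alpha(self):
        from tests.conftest import NO_DETECTION
        from triomic.synthetic_data import SimulationConfig, as_multiomic, simulate

        cfg = SimulationConfig(
            n_genes=300, archetype_mix={"flat": 1.0}, detection_quantile=NO_DETECTION, seed=5
        )
        sd, _ = simulate(cfg)
        fcm = zscore_columns(fold_changes(as_multiomic(sd)))
        res = one_sample_test(fcm)
        fracs = [
            len(significant_union_filter(res, alpha=a)) / 300 for a in (0.01, 0.05, 0.1)
        ]
        assert fracs == sorted(fracs)
        assert fracs[1] <= 0.05
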