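import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phosphopipe import kinome
from phosphopipe.io import AMINO_ACIDS
from phosphopipe.kinome import (
    ContingencyTable,
    define_regulated_sets,
    fisher_one_sided,
    haldane_frequency_factor,
    percentile_score,
    predict_kinases,
    score_site,
)


def _uniform_pssm(positions):
    return pd.DataFrame(
        np.full((len(positions), 20), 0.05), index=positions, columns=list(AMINO_ACIDS)
    )


class TestScoreSite:
    def test_uniform_pssm_six_flanks(self):
        pssm = _uniform_pssm([-3, -2, -1, 1, 2, 3])
        score = score_site(pssm, "AAASAAA")
        assert score == pytest.approx(6 * math.log2(0.05))

    def test_probability_one_contributes_zero(self):
        pssm = _uniform_pssm([-1, 1])
        pssm.loc[1] = 0.0
        pssm.loc[1, "A"] = 1.0
        assert score_site(pssm, "ASA") == pytest.approx(math.log2(0.05))

    def test_short_window_missing_positions_contribute_zero(self):
        pssm = _uniform_pssm([-5, -1, 1])
        # window of length 3: position -5 falls outside
        assert score_site(pssm, "ASA") == pytest.approx(2 * math.log2(0.05))

    def test_nonstandard_residue_contributes_zero(self):
        pssm = _uniform_pssm([-1, 1])
        assert score_site(pssm, "XSA") == pytest.approx(math.log2(0.05))

    def test_tyrosine_center_rejected(self):
        pssm = _uniform_pssm([-1, 1])
        with pytest.raises(ValueError, match="S/T"):
            score_site(pssm, "AYA")

    def test_probability_floor_applied(self):
        pssm = _uniform_pssm([-1, 1])
        pssm.loc[1] = 0.0
        pssm.loc[1, "C"] = 1.0  # residue A has probability 0 -> floored
        assert score_site(pssm, "ASA") == pytest.approx(
            math.log2(0.05) + math.log2(1e-4)
        )


class TestPercentile:
    def test_conventions(self):
        bg = np.array([-3.0, -1.0, 2.0, 5.0])
        assert percentile_score(5.0, bg) == 100.0
        assert percentile_score(2.0, bg) == 75.0
        assert percentile_score(-10.0, bg) == 0.0

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            percentile_score(1.0, np.array([]))


class TestPredict:
    def test_small_atlas_returns_all_kinases(self):
        names = [f"K{i}" for i in range(10)]
        raw = pd.Series(np.arange(10.0), index=names)
        pct = pd.Series(np.linspace(0, 100, 10), index=names)
        assert set(predict_kinases(raw, pct, top_k=15)) == set(names)

    def test_deterministic_under_reordering(self):
        rng = np.random.default_rng(0)
        names = [f"K{i}" for i in range(30)]
        raw = pd.Series(rng.normal(size=30), index=names)
        pct = pd.Series(rng.uniform(0, 100, size=30).round(0), index=names)
        a = predict_kinases(raw, pct, top_k=15)
        perm = rng.permutation(30)
        b = predict_kinases(raw.iloc[perm], pct.iloc[perm], top_k=15)
        assert a == b

    def test_boundary_ties_break_by_raw_then_name(self):
        names = ["B", "A", "C"]
        pct = pd.Series([50.0, 50.0, 50.0], index=names)
        raw = pd.Series([1.0, 1.0, 2.0], index=names)
        assert predict_kinases(raw, pct, top_k=2) == ("C", "A")


class TestRegulatedSets:
    def _diff(self, fdrs, lfcs):
        return pd.DataFrame(
            {"fdr": fdrs, "log2fc": lfcs},
            index=[f"s{i}" for i in range(len(fdrs))],
        )

    def test_boundary_value_falls_in_neither_set(self):
        diff = self._diff([0.5, 0.4, 0.6], [1.0, -1.0, 1.0])
        up, down, unreg = define_regulated_sets(diff, 0.5)
        assert list(up) == []
        assert list(down) == ["s1"]
        assert list(unreg) == ["s2"]

    def test_all_fdr_one_gives_empty_regulated(self):
        diff = self._diff([1.0, 1.0], [1.0, -1.0])
        up, down, unreg = define_regulated_sets(diff, 0.25)
        assert len(up) == len(down) == 0
        assert len(unreg) == 2

    def test_partition_covers_non_boundary_sites(self):
        rng = np.random.default_rng(1)
        diff = self._diff(rng.uniform(0, 1, 100), rng.normal(size=100))
        up, down, unreg = define_regulated_sets(diff, 0.5)
        covered = set(up) | set(down) | set(unreg)
        boundary = set(diff.index[diff["fdr"] == 0.5])
        assert covered == set(diff.index) - boundary


class TestHaldane:
    def test_forced_arithmetic(self):
        ff = haldane_frequency_factor(ContingencyTable(3, 7, 0, 10))
        assert ff == pytest.approx(math.log2(7))

    def test_equal_proportions_give_zero(self):
        assert haldane_frequency_factor(ContingencyTable(3, 7, 3, 7)) == pytest.approx(0.0)

    def test_antisymmetric_under_row_swap(self):
        t = ContingencyTable(5, 2, 1, 9)
        swapped = ContingencyTable(1, 9, 5, 2)
        assert haldane_frequency_factor(t) == pytest.approx(
            -haldane_frequency_factor(swapped)
        )

    def test_scaling_counts_converges_to_uncorrected_ratio(self):
        # Haldane's +0.5 washes out as counts grow: the FF of a k-fold
        # scaled table approaches the uncorrected log2 proportion ratio,
        # which is itself scale-invariant
        a, b, c, d = 6, 14, 3, 17
        uncorrected = math.log2((a / (a + b)) / (c / (c + d)))
        errs = [
            abs(
                haldane_frequency_factor(
                    ContingencyTable(k * a, k * b, k * c, k * d)
                )
                - uncorrected
            )
            for k in (1, 2, 4, 8)
        ]
        assert all(np.diff(errs) < 0)
        assert errs[-1] < 0.02


def tail_enumeration(row1, col1, n, threshold):
    """Exact P(first cell >= threshold) over all 2x2 tables with the given
    margins, by direct combinatorial enumeration."""
    denom = math.comb(n, col1)
    total = 0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        if x >= threshold:
            total += math.comb(row1, x) * math.comb(n - row1, col1 - x)
    return total / denom


def fisher_enumeration(a, b, c, d):
    """Exact one-sided p by summing the hypergeometric mass of every table
    with the same margins and first cell >= a."""
    return tail_enumeration(a + b, a + c, a + b + c + d, a)


class TestFisher:
    def test_minimum_feasible_cell_gives_p_one(self):
        assert fisher_one_sided(ContingencyTable(0, 5, 0, 5)) == pytest.approx(1.0)

    def test_small_table_by_hand(self):
        assert fisher_one_sided(ContingencyTable(2, 0, 0, 2)) == pytest.approx(1 / 6)

    def test_agrees_with_enumeration_for_small_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 8, size=4)
            p = fisher_one_sided(ContingencyTable(int(a), int(b), int(c), int(d)))
            assert p == pytest.approx(fisher_enumeration(a, b, c, d), abs=1e-12)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)

    @given(st.integers(0, 10), st.integers(0, 10), st.integers(0, 10), st.integers(0, 10))
    @settings(max_examples=100, deadline=None)
    def test_column_swap_mirror_symmetry(self, a, b, c, d):
        """P(A >= a) equals the depletion tail P(X <= b) of the table with
        the predicted/not-predicted columns swapped."""
        p_greater = fisher_one_sided(ContingencyTable(a, b, c, d))
        # swapped table has first cell b, margins (a+b, b+d); X <= b there
        n = a + b + c + d
        p_less_swapped = 1.0 - tail_enumeration(a + b, b + d, n, b + 1)
        assert p_greater == pytest.approx(p_less_swapped, abs=1e-12)

    def test_doubling_counts_does_not_increase_p(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 6, size=4)
            if a * d <= b * c:  # only enrichment-direction tables
                continue
            p1 = fisher_one_sided(ContingencyTable(int(a), int(b), int(c), int(d)))
            p2 = fisher_one_sided(ContingencyTable(int(2 * a), int(2 * b), int(2 * c), int(2 * d)))
            assert p2 <= p1 + 1e-12


class TestEnrichment:
    def test_never_predicted_kinase_has_p_one_and_finite_ff(self):
        pred = pd.DataFrame(
            {"K1": [True] * 4 + [False] * 6, "K2": [False] * 10},
            index=[f"s{i}" for i in range(10)],
        )
        up = pd.Index(["s0", "s1", "s2", "s3"])
        unreg = pd.Index([f"s{i}" for i in range(4, 10)])
        res = kinome.kinome_enrichment(pred, up, pd.Index([]), unreg)
        assert res.loc["K2", "p"] == pytest.approx(1.0)
        assert np.isfinite(res.loc["K2", "frequency_factor"])
        assert res.loc["K1", "p"] < 0.05

    def test_empty_unregulated_rejected(self):
        pred = pd.DataFrame({"K1": [True, False]}, index=["a", "b"])
        with pytest.raises(ValueError):
            kinome.kinome_enrichment(pred, pd.Index(["a"]), pd.Index([]), pd.Index([]))


def test_percentiles_of_background_windows_are_uniform(default_sim):
    """Scoring fresh background windows against the atlas backgrounds gives
    percentile scores indistinguishable from Uniform(0, 100)."""
    from scipy import stats as ss

    from phosphopipe import syndata

    cfg = default_sim.config
    rng = np.random.default_rng(999)
    centers = rng.choice(["S", "T"], size=5000)
    windows = syndata._background_windows(cfg, centers, rng=rng)
    raw = kinome.raw_scores(windows, {"KIN000": default_sim.atlas.matrices["KIN000"]})
    bg = default_sim.atlas.backgrounds["KIN000"]
    pct = 100.0 * np.searchsorted(bg, raw["KIN000"].to_numpy(), side="right") / len(bg)
    d = ss.kstest(pct / 100.0, "uniform").statistic
    assert d < 0.05
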