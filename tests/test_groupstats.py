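import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ovistereo.groupstats import (
    choose_branch,
    compact_letters,
    compare_all,
    compare_variable,
    dunn_posthoc,
    nonparametric_compare,
    parametric_compare,
)


class TestBranchChoice:
    def test_constant_data_is_untestable(self):
        branch, p = choose_branch({g: [1.0, 1.0, 1.0] for g in "abc"})
        assert branch == "nonparametric"
        assert np.isnan(p)

    def test_normal_null_keeps_parametric_branch(self):
        rng = np.random.default_rng(11)
        hits = sum(
            choose_branch({g: rng.normal(0, 1, 10) for g in "abc"})[0] == "parametric"
            for _ in range(300)
        )
        # Shapiro at alpha 0.05 keeps ~95% of normal samples
        assert 0.90 <= hits / 300 <= 0.99

    def test_replicated_outliers_force_nonparametric(self):
        rng = np.random.default_rng(3)
        values = {}
        for g in "abc":
            v = rng.normal(10, 1, 10)
            v[:3] += 10  # 10-SD outlier pattern in every group
            values[g] = v
        assert choose_branch(values)[0] == "nonparametric"

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError):
            choose_branch({"a": [1, 2], "b": [1, 2, 3], "c": [1, 2, 3]})


class TestOmnibus:
    def test_parametric_separation_limit(self):
        rng = np.random.default_rng(0)
        vals = {"a": rng.normal(0, 1e-6, 10), "b": rng.normal(10, 1e-6, 10), "c": rng.normal(20, 1e-6, 10)}
        f, p, pmat = parametric_compare(vals)
        assert p < 1e-12
        off = pmat.to_numpy()[~np.eye(3, dtype=bool)]
        assert (off < 0.001).all()

    def test_disjoint_ranges_all_pairs_significant(self):
        vals = {"a": np.arange(10.0), "b": np.arange(20.0, 30), "c": np.arange(40.0, 50)}
        h, p, pmat = nonparametric_compare(vals)
        assert p < 0.001
        off = pmat.to_numpy()[~np.eye(3, dtype=bool)]
        assert (off < 0.05).all()

    def test_two_group_minimum(self):
        with pytest.raises(ValueError):
            parametric_compare({"a": [1, 2, 3]})


class TestAlternativeChecks:
    def test_per_group_normality_option(self):
        rng = np.random.default_rng(21)
        vals = {g: rng.normal(0, 1, 10) for g in "abc"}
        branch_pooled, _ = choose_branch(vals)
        branch_per_group, p = choose_branch(vals, per_group=True)
        assert branch_per_group in ("parametric", "nonparametric")
        assert 0 <= p <= 1
        assert branch_pooled == "parametric"

    def test_mannwhitney_posthoc_agrees_on_clear_separation(self):
        from ovistereo.groupstats import mannwhitney_posthoc

        vals = {"a": np.arange(10.0), "b": np.arange(20.0, 30), "c": np.arange(40.0, 50)}
        pmat = mannwhitney_posthoc(vals)
        off = pmat.to_numpy()[~np.eye(3, dtype=bool)]
        assert (off < 0.05).all()
        _, _, dunn = nonparametric_compare(vals, posthoc="mannwhitney")
        assert (dunn.to_numpy() == pmat.to_numpy()).all()


class TestDunn:
    def test_hand_computed_fixture(self):
        """No-ties fixture: mean ranks 2/5/8, SE = sqrt(7.5 * 2/3)."""
        pmat = dunn_posthoc({"x": [1, 2, 3], "y": [4, 5, 6], "z": [7, 8, 9]}, adjust=None)
        assert pmat.loc["x", "y"] == pytest.approx(0.179712, abs=1e-6)
        assert pmat.loc["x", "z"] == pytest.approx(0.0072904, abs=1e-6)
        assert pmat.loc["y", "z"] == pytest.approx(0.179712, abs=1e-6)

    def test_holm_adjustment(self):
        pmat = dunn_posthoc({"x": [1, 2, 3], "y": [4, 5, 6], "z": [7, 8, 9]})
        assert pmat.loc["x", "z"] == pytest.approx(3 * 0.0072904, abs=1e-5)
        assert pmat.loc["x", "y"] == pytest.approx(2 * 0.179712, abs=1e-5)

    def test_fully_tied_data(self):
        pmat = dunn_posthoc({"x": [1, 1, 1], "y": [1, 1, 1], "z": [1, 1, 1]})
        assert (pmat.to_numpy() == 1.0).all()


class TestCompactLetters:
    def test_no_differences(self):
        pmat = np.ones((3, 3))
        assert compact_letters(pmat) == ["a", "a", "a"]

    def test_control_separated_from_both_treatments(self):
        pmat = np.array([[1.0, 0.001, 0.001], [0.001, 1.0, 0.8], [0.001, 0.8, 1.0]])
        assert compact_letters(pmat) == ["a", "b", "b"]

    def test_all_pairs_different(self):
        pmat = np.array([[1.0, 0.01, 0.01], [0.01, 1.0, 0.01], [0.01, 0.01, 1.0]])
        assert compact_letters(pmat) == ["a", "b", "c"]

    def test_nonsquare_rejected(self):
        with pytest.raises(ValueError):
            compact_letters(np.ones((2, 3)))

    @given(
        st.integers(2, 5).flatmap(
            lambda k: st.lists(
                st.floats(0, 1), min_size=k * (k - 1) // 2, max_size=k * (k - 1) // 2
            )
        )
    )
    @settings(deadline=None)
    def test_letters_share_iff_not_significant(self, offdiag):
        k = int((1 + np.sqrt(1 + 8 * len(offdiag))) / 2)
        pmat = np.ones((k, k))
        idx = np.triu_indices(k, 1)
        pmat[idx] = offdiag
        pmat[idx[::-1]] = offdiag
        letters = compact_letters(pmat, alpha=0.05)
        for i in range(k):
            for j in range(i + 1, k):
                share = bool(set(letters[i]) & set(letters[j]))
                assert share == (pmat[i, j] >= 0.05)


class TestCompareVariable:
    def test_identical_groups_all_a(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = compare_variable("v", {"a": base, "b": base, "c": base})
        assert list(res.letters.values()) == ["a", "a", "a"]

    def test_degenerate_constant_groups(self):
        res = compare_variable("v", {"a": [0.0] * 5, "b": [0.0] * 5, "c": [0.0] * 5})
        assert res.branch == "degenerate"
        assert list(res.letters.values()) == ["a", "a", "a"]
        assert np.isnan(res.pvalue)

    def test_degenerate_distinct_constants_lettered_by_ties(self):
        res = compare_variable("v", {"a": [5.0] * 5, "b": [0.0] * 5, "c": [0.0] * 5})
        assert res.branch == "degenerate"
        assert list(res.letters.values()) == ["a", "b", "b"]

    def test_summaries_match_branch(self):
        rng = np.random.default_rng(5)
        vals = {g: rng.normal(10, 2, 10) for g in "abc"}
        res = compare_variable("v", vals)
        if res.branch == "parametric":
            assert res.summaries["a"][0] == pytest.approx(np.mean(vals["a"]))
        else:
            assert res.summaries["a"][0] == pytest.approx(np.median(vals["a"]))

    def test_letters_match_pairwise_significance(self):
        rng = np.random.default_rng(8)
        vals = {"a": rng.normal(0, 1, 10), "b": rng.normal(5, 1, 10), "c": rng.normal(5.2, 1, 10)}
        res = compare_variable("v", vals, alpha=0.05)
        labels = list(res.letters)
        for i, gi in enumerate(labels):
            for gj in labels[i + 1:]:
                share = bool(set(res.letters[gi]) & set(res.letters[gj]))
                assert share == (res.pairwise.loc[gi, gj] >= 0.05)


class TestCompareAll:
    def test_untested_variable_gets_blank_letters(self):
        frame = pd.DataFrame(
            {
                "group": ["a"] * 4 + ["b"] * 4 + ["c"] * 4,
                "ok": np.arange(12.0),
                "mostly_nan": [1.0, np.nan, np.nan, np.nan] * 3,
            }
        )
        results = {r.variable: r for r in compare_all(frame, ["ok", "mostly_nan"])}
        assert results["mostly_nan"].branch == "untested"
        assert all(letter == "" for letter in results["mostly_nan"].letters.values())
        assert results["ok"].branch in ("parametric", "nonparametric")
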