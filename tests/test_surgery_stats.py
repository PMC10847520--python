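"""Exact Wilcoxon signed-rank and replicate concordance."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from nasalair.errors import ValidationError
from nasalair.profile_io import load_fixture
from nasalair.standardize import average_scenarios
from nasalair.surgery_stats import (
    pooled_average_theta,
    replicate_concordance,
    state_comparison_report,
    wilcoxon_signed_rank,
)
from oracles import brute_force_wilcoxon


class TestWilcoxon:
    def test_all_positive_differences_one_sided(self):
        """Five concordant pairs give the classic exact p = 1/32."""
        x = [1, 2, 3, 4, 5]
        y = [0.5, 1.0, 2.2, 3.1, 4.4]
        res = wilcoxon_signed_rank(x, y, alternative="greater")
        assert res.p_value == pytest.approx(1 / 32)
        assert res.n_effective == 5

    def test_identical_pairs_degenerate(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate and res.p_value == 1.0 and res.n_zero == 3

    def test_too_few_nonzero_pairs_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_signed_rank([1, 2, 3], [1, 2, 2.5])

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(5, 15))
            x = rng.normal(size=n)
            y = x - rng.normal(0.3, 1.0, n)
            ours = wilcoxon_signed_rank(x, y)
            ref = scipy.stats.wilcoxon(x, y, alternative="two-sided", method="exact")
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)
            assert ours.statistic == pytest.approx(ref.statistic)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60)
    def test_matches_brute_force_enumeration(self, seed):
        """DP distribution equals explicit 2^n enumeration, ties included."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 11))
        x = rng.normal(size=n)
        y = x - np.round(rng.normal(0.2, 1.0, n), 1)  # rounding induces ties/zeros
        alt = ["two-sided", "greater", "less"][seed % 3]
        try:
            ours = wilcoxon_signed_rank(x, y, alternative=alt)
        except ValidationError:
            return  # fewer than 3 nonzero differences
        assert ours.p_value == pytest.approx(brute_force_wilcoxon(x, y, alt), abs=1e-12)


class TestConcordance:
    def test_identity_and_reflection(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        out = replicate_concordance(x, x)
        assert out["slope"] == pytest.approx(1.0) and out["pearson_r"] == pytest.approx(1.0)
        out = replicate_concordance(x, -x)
        assert out["slope"] == pytest.approx(-1.0) and out["pearson_r"] == pytest.approx(-1.0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40)
    def test_r_symmetric_and_slope_product_bounded(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=10)
        y = 0.5 * x + rng.normal(size=10)
        ab = replicate_concordance(x, y)
        ba = replicate_concordance(y, x)
        assert ab["pearson_r"] == pytest.approx(ba["pearson_r"], abs=1e-12)
        assert ab["slope"] * ba["slope"] == pytest.approx(ab["pearson_r"] ** 2, abs=1e-9)
        assert ab["slope"] * ba["slope"] <= 1.0 + 1e-12

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            replicate_concordance([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestStateComparisonReport:
    @staticmethod
    def _profiles(table_id):
        return [
            average_scenarios(load_fixture(table_id, q))
            for q in ("temperature", "humidity")
        ]

    def test_three_way_report_on_adult_specimen(self):
        """Obstruction shifts theta hardest in the anterior slices (2-4)."""
        report = state_comparison_report(
            {
                "original": self._profiles("T3"),
                "obstructed": self._profiles("T4"),
                "operated": self._profiles("T5"),
            }
        )
        assert set(report["pairwise"]) == {
            "original_vs_obstructed",
            "original_vs_operated",
            "obstructed_vs_operated",
        }
        orig = pooled_average_theta(self._profiles("T3"))
        obst = pooled_average_theta(self._profiles("T4"))
        shift = np.abs(orig - obst)
        # the largest mean shifts sit at slices 2-4 of each 9-slice block
        anterior = np.concatenate([shift[1:4], shift[10:13]])
        posterior = np.concatenate([shift[4:9], shift[13:18]])
        assert anterior.mean() > posterior.mean()

    def test_single_state_rejected(self):
        with pytest.raises(ValidationError):
            state_comparison_report({"original": self._profiles("T3")})

    def test_identical_states_give_null_report(self):
        report = state_comparison_report(
            {"a": self._profiles("T3"), "b": self._profiles("T3")}
        )
        pair = report["pairwise"]["a_vs_b"]
        assert pair["wilcoxon"]["p_value"] == 1.0
        assert pair["wilcoxon"]["degenerate"]
        assert pair["concordance"]["slope"] == pytest.approx(1.0)
        for rec in pair["curves"].values():
            assert rec["verdict"] == "coincident"
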