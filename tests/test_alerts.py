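"""Gene-wise alert derivation: model evaluation, MCP testing, ALEC."""

import math

import numpy as np
import pytest

from alertgs.alerts import (
    ResponseProfile,
    compute_alec,
    derive_gene_alert,
    filter_genes,
    mcp_test,
    nonzero_threshold,
    select_winner,
)
from alertgs.models import (
    CandidateModel,
    default_candidates,
    evaluate_model,
    fit_model,
)

LOG2_15 = math.log2(1.5)


class TestEvaluateModel:
    @pytest.mark.parametrize(
        "name, params, x, expected",
        [
            ("linear", (1.0, 0.5), 4.0, 3.0),
            ("emax", (0.0, 2.0, 10.0), 10.0, 1.0),  # half-maximal at ET50
            ("emax", (0.0, 2.0, 10.0), 0.0, 0.0),
            ("quadratic", (1.0, 2.0, -0.5), 2.0, 3.0),
            ("exponential", (0.0, 1.0, 5.0), 0.0, 0.0),
            ("sigEmax", (0.0, 2.0, 10.0, 3.0), 10.0, 1.0),
        ],
    )
    def test_pointwise_values(self, name, params, x, expected):
        assert evaluate_model(name, x, params) == pytest.approx(expected)

    def test_betamod_peak_equals_emax(self):
        # normalization makes the kernel max equal Emax at the mode
        params = (0.5, 2.0, 2.0, 2.0, 48.0)
        mode = 48.0 * 2.0 / 4.0
        assert evaluate_model("betaMod", mode, params) == pytest.approx(2.5)
        x = np.linspace(0, 60, 500)
        assert np.max(evaluate_model("betaMod", x, params)) <= 2.5 + 1e-12

    def test_unknown_model_and_arity_errors(self):
        with pytest.raises(ValueError):
            evaluate_model("cubic", 1.0, (0, 1))
        with pytest.raises(ValueError):
            evaluate_model("emax", 1.0, (0, 1))

    def test_continuity_at_betamod_boundary(self):
        params = (1.0, 2.0, 1.5, 2.5, 40.0)
        left = evaluate_model("betaMod", 40.0 - 1e-9, params)
        right = evaluate_model("betaMod", 40.0 + 1e-9, params)
        assert left == pytest.approx(1.0, abs=1e-6)
        assert right == pytest.approx(1.0)


class TestMCP:
    conditions = np.array([0.0, 3.0, 6.0, 12.0, 24.0, 48.0])

    def _profile(self, mean_fun, sigma, rng, reps=3):
        responses = [
            mean_fun(c) + rng.normal(0, sigma, size=reps) for c in self.conditions
        ]
        return ResponseProfile("g", self.conditions, responses)

    def test_flat_constant_profile_not_significant(self):
        # exactly constant responses: no dose-response evidence at all
        prof = ResponseProfile("g", self.conditions,
                               [[1.0, 1.0, 1.0]] * len(self.conditions))
        res = mcp_test(prof, alpha=0.05)
        assert not any(flag for _, _, flag in res.values())
        assert all(t == 0.0 for t, _, _ in res.values())

    def test_steep_emax_flagged(self):
        rng = np.random.default_rng(1)
        prof = self._profile(
            lambda c: evaluate_model("emax", c, (0.0, 2.0, 4.0)), 0.01, rng
        )
        res = mcp_test(prof, alpha=0.05)
        assert res["emax"][2]

    def test_too_few_conditions_error(self):
        prof = ResponseProfile("g", [0.0, 1.0], [[0.0, 0.1], [1.0, 1.1]])
        with pytest.raises(ValueError):
            mcp_test(prof)

    def test_null_calibration(self):
        """Flat-truth noise: the any-candidate rejection rate tracks alpha."""
        rng = np.random.default_rng(42)
        n_genes, alpha = 1000, 0.05
        hits = 0
        for _ in range(n_genes):
            prof = self._profile(lambda c: 0.0, 1.0, rng)
            res = mcp_test(prof, alpha=alpha)
            hits += any(flag for _, _, flag in res.values())
        rate = hits / n_genes
        se = math.sqrt(alpha * (1 - alpha) / n_genes)
        assert abs(rate - alpha) < 3 * se


class TestWinnerSelection:
    def test_single_candidate_wins(self):
        rng = np.random.default_rng(3)
        x = np.array([0.0, 4.0, 8.0, 16.0, 32.0, 48.0])
        prof = ResponseProfile(
            "g", x, [0.1 * c + rng.normal(0, 0.05, 3) for c in x]
        )
        w = select_winner(prof, ["linear"])
        assert w.name == "linear"

    def test_no_candidate_returns_none(self):
        prof = ResponseProfile("g", [0, 1, 2], [[0.0], [0.1], [0.2]])
        assert select_winner(prof, []) is None

    def test_generating_family_usually_wins(self):
        """Linear-truth data: AIC prefers linear over emax in most genes."""
        rng = np.random.default_rng(7)
        x = np.array([0.0, 4.0, 8.0, 16.0, 32.0, 48.0])
        wins = 0
        n = 50
        for _ in range(n):
            prof = ResponseProfile(
                "g", x, [0.05 * c + rng.normal(0, 0.1, 3) for c in x]
            )
            w = select_winner(prof, ["linear", "emax"])
            wins += w.name == "linear"
        assert wins > n / 2


class TestALEC:
    def test_emax_closed_form(self):
        m = CandidateModel("emax", fitted_parameters=np.array([0.0, 2.0, 10.0]))
        expected = 10 * LOG2_15 / (2 - LOG2_15)
        alec = compute_alec(m, 0.0, 48.0, "up")
        assert alec == pytest.approx(expected, abs=48.0 / 10000)

    def test_range_too_small_gives_none(self):
        m = CandidateModel("linear", fitted_parameters=np.array([0.0, 0.01]))
        assert compute_alec(m, 0.0, 48.0, "up") is None

    def test_linear_down_closed_form(self):
        m = CandidateModel("linear", fitted_parameters=np.array([5.0, -0.1]))
        alec = compute_alec(m, 0.0, 48.0, "down")
        assert alec == pytest.approx(LOG2_15 / 0.1, abs=48.0 / 10000)

    @pytest.mark.parametrize("seed", range(5))
    def test_bounds_invariant(self, seed):
        rng = np.random.default_rng(seed)
        m = CandidateModel(
            "emax",
            fitted_parameters=np.array(
                [rng.normal(), rng.uniform(0.7, 3.0), rng.uniform(1, 30)]
            ),
        )
        alec = compute_alec(m, 0.0, 48.0, "up")
        if alec is not None:
            assert 0.0 <= alec <= 48.0

    def test_monotone_in_effect_level(self):
        m = CandidateModel("emax", fitted_parameters=np.array([0.0, 3.0, 10.0]))
        a1 = compute_alec(m, 0.0, 48.0, "up", effect=0.3)
        a2 = compute_alec(m, 0.0, 48.0, "up", effect=0.9)
        assert a1 is not None and a2 is not None and a2 >= a1


class TestDeriveGeneAlert:
    @pytest.mark.parametrize(
        "up, down, expected",
        [
            (12.0, 30.0, (12.0, "up")),
            (None, 7.5, (7.5, "down")),
            (9.0, None, (9.0, "up")),
            (None, None, (None, "none")),
            (30.0, 12.0, (12.0, "down")),
        ],
    )
    def test_minimum_rule(self, up, down, expected):
        assert derive_gene_alert(up, down) == expected


class TestFilterGenes:
    def test_threshold_more_than_half_of_45(self):
        assert nonzero_threshold(45, 0.5) == 23

    def test_strict_inequality_at_even_count(self):
        import pandas as pd

        counts = pd.DataFrame(
            {
                "s1": [1, 1, 0],
                "s2": [2, 1, 0],
                "s3": [0, 1, 0],
                "s4": [0, 1, 0],
            },
            index=["gA", "gB", "gC"],
        )
        kept = filter_genes(counts, 0.5)
        # gA nonzero in exactly 2 of 4: 2 is not > 2 -> removed; all-zero removed
        assert kept == ["gB"]

    def test_empty_matrix_error(self):
        import pandas as pd

        with pytest.raises(ValueError):
            filter_genes(pd.DataFrame(), 0.5)


def test_fit_recovers_linear_parameters():
    x = np.array([0.0, 4.0, 8.0, 16.0, 32.0, 48.0])
    y = 1.0 + 0.2 * x
    m = fit_model("linear", x, y)
    assert m.fitted_parameters == pytest.approx([1.0, 0.2], abs=1e-8)


def test_default_candidates_cover_the_six_families():
    names = [c.name for c in default_candidates(0.0, 48.0)]
    assert names == [
        "linear", "quadratic", "exponential", "emax", "sigEmax", "betaMod"
    ]
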