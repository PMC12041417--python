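"""Running-sum statistic, permutation null, rectified-Gumbel inference."""

import itertools

import numpy as np
import pytest
from scipy.stats import gumbel_r, kstest

from alertgs.alerts import GeneAlert
from alertgs.enrichment import (
    enrichment_score,
    fit_rectified_gumbel,
    gumbel_pvalue,
    permutation_null,
    permutation_pvalue,
    running_sum,
    step_weights,
)
from alertgs.prep import PreparedAlerts, prepare_alerts


def make_prepared(values, cmax=100.0):
    values = np.asarray(values, float)
    order = np.argsort(values)
    return PreparedAlerts(
        gene_ids=np.array([f"g{i}" for i in order], dtype=object),
        prepared_values=values[order],
        origin=np.array(["correct"] * len(values), dtype=object),
        cmax=cmax,
        epsilon=0.01 * cmax,
    )


class TestRunningSum:
    def test_half_membership_hand_example(self):
        prep = make_prepared([1.0, 2.0, 3.0, 4.0])
        rs = running_sum(prep, {"g0", "g1"})
        assert np.allclose(rs.values, [1.0, 2.0, 1.0, 0.0])
        es, argmax = enrichment_score(rs, cmax=100.0)
        assert es == 2.0 and argmax == 2.0

    def test_zero_sum_conservation(self):
        rng = np.random.default_rng(0)
        prep = make_prepared(rng.uniform(0, 50, 137))
        rs = running_sum(prep, {f"g{i}" for i in range(23)})
        assert abs(rs.values[-1]) < 1e-9 * 137

    def test_step_weights_balance(self):
        up, down = step_weights(10, 4)
        assert 4 * up == pytest.approx(6 * down)

    def test_degenerate_membership_errors(self):
        prep = make_prepared([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            running_sum(prep, set())
        with pytest.raises(ValueError):
            running_sum(prep, {"g0", "g1", "g2"})


class TestEnrichmentScore:
    def test_maximal_segregation(self):
        prep = make_prepared(np.arange(1.0, 11.0))
        rs = running_sum(prep, {"g0", "g1", "g2"})
        es, argmax = enrichment_score(rs, cmax=100.0)
        up, _ = step_weights(10, 3)
        assert es == pytest.approx(3 * up)
        assert argmax == 3.0

    def test_members_beyond_cmax_floor_at_zero(self):
        prep = make_prepared([1.0, 2.0, 3.0, 60.0, 70.0], cmax=50.0)
        rs = running_sum(prep, {"g3", "g4"})  # the two late genes
        es, _ = enrichment_score(rs, cmax=50.0)
        assert es == 0.0

    def test_brute_force_oracle_all_arrangements(self):
        """Exhaustive cross-check for every N <= 8 and membership pattern:
        the ES equals an independently coded cumulative-max, and the
        permutation-path formula reproduces it from member positions."""
        for N in range(2, 9):
            prep = make_prepared(np.arange(1.0, N + 1.0), cmax=N + 1.0)
            for M in range(1, N):
                up, down = step_weights(N, M)
                for members in itertools.combinations(range(N), M):
                    mem = set(members)
                    # independent oracle: plain python loop
                    cum, best = 0.0, 0.0
                    for i in range(N):
                        cum += up if i in mem else -down
                        best = max(best, cum)
                    rs = running_sum(prep, {f"g{i}" for i in mem})
                    es, _ = enrichment_score(rs, cmax=N + 1.0)
                    assert es == best
                    # position-based path used by the permutation null
                    pos = np.array(sorted(mem))
                    j = np.arange(M)
                    vals = (j + 1) * up - (pos - j) * down
                    assert max(vals.max(), 0.0) == pytest.approx(best, abs=1e-12)


class TestPermutationNull:
    def test_determinism_and_shape(self, exchangeable_prepared):
        n1 = permutation_null(exchangeable_prepared, M=10, P=50, seed=4)
        n2 = permutation_null(exchangeable_prepared, M=10, P=50, seed=4)
        assert np.array_equal(n1.es_values, n2.es_values)
        assert np.array_equal(n1.positions, n2.positions)
        assert n1.es_values.shape == (50,)
        assert np.all(n1.es_values >= 0)

    def test_single_permutation(self, exchangeable_prepared):
        null = permutation_null(exchangeable_prepared, M=5, P=1, seed=0)
        assert null.es_values.size == 1 and null.es_values[0] >= 0

    def test_subsets_are_uniform_positions(self, exchangeable_prepared):
        null = permutation_null(exchangeable_prepared, M=10, P=2000, seed=1)
        # every position appears with frequency ~ M/N
        freq = np.bincount(null.positions.ravel(), minlength=200) / 2000
        assert abs(freq.mean() - 10 / 200) < 1e-12
        assert np.all(np.abs(freq - 0.05) < 0.02)

    def test_empirical_pvalue_uniform_under_exchangeability(self):
        """Random subsets of exchangeable alerts give ~uniform p-values."""
        rng = np.random.default_rng(99)
        table = [GeneAlert(f"g{i}", float(a), "up")
                 for i, a in enumerate(rng.uniform(1, 99, 100))]
        prep = prepare_alerts(table, "up", cmax=100.0, seed=0)
        pvals = []
        for rep in range(300):
            members = rng.choice(prep.gene_ids, size=10, replace=False)
            rs = running_sum(prep, set(members))
            es, _ = enrichment_score(rs, 100.0)
            null = permutation_null(prep, 10, P=200, seed=rep)
            pvals.append(permutation_pvalue(es, null))
        d = kstest(pvals, "uniform").statistic
        assert d < 0.08  # granular grid: modest Kolmogorov distance

    def test_rank_invariance_under_monotone_transform(self):
        """ES permutation distribution depends only on alert ranks."""
        vals = np.sort(np.random.default_rng(5).uniform(1, 40, 50))
        prep1 = make_prepared(vals, cmax=50.0)
        prep2 = make_prepared(np.exp(vals / 10.0), cmax=float(np.exp(5.0)))
        n1 = permutation_null(prep1, M=7, P=100, cmax=50.0, seed=8)
        n2 = permutation_null(prep2, M=7, P=100, cmax=float(np.exp(5.0)), seed=8)
        assert np.allclose(n1.es_values, n2.es_values)


class TestPermutationPvalue:
    def _null_with(self, es_values):
        es = np.asarray(es_values, float)
        return type("N", (), {"es_values": es, "P": es.size})()

    def test_exact_counting(self):
        es_values = np.concatenate([np.full(50, 5.0), np.full(950, 1.0)])
        assert permutation_pvalue(5.0, self._null_with(es_values)) == 0.05

    def test_zero_possible(self):
        assert permutation_pvalue(10.0, self._null_with(np.ones(100))) == 0.0

    def test_es_zero_counts_everything(self):
        assert permutation_pvalue(0.0, self._null_with(np.zeros(100))) == 1.0


class TestRectifiedGumbel:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(2)
        x = np.maximum(0.0, gumbel_r.rvs(loc=2.0, scale=1.0, size=10**5,
                                         random_state=rng))
        mu, beta = fit_rectified_gumbel(x)
        assert abs(mu - 2.0) < 0.05 and abs(beta - 1.0) < 0.05

    def test_no_zeros_matches_plain_gumbel_mle(self):
        rng = np.random.default_rng(3)
        x = gumbel_r.rvs(loc=10.0, scale=2.0, size=20000, random_state=rng)
        assert np.all(x > 0)
        mu, beta = fit_rectified_gumbel(x)
        mu_ref, beta_ref = gumbel_r.fit(x)
        assert mu == pytest.approx(mu_ref, abs=0.02)
        assert beta == pytest.approx(beta_ref, abs=0.02)

    def test_location_equivariance(self):
        rng = np.random.default_rng(4)
        x = gumbel_r.rvs(loc=8.0, scale=1.5, size=20000, random_state=rng)
        mu1, _ = fit_rectified_gumbel(x)
        mu2, _ = fit_rectified_gumbel(x + 3.0)
        assert mu2 - mu1 == pytest.approx(3.0, abs=0.05)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            fit_rectified_gumbel(np.zeros(100))
        with pytest.raises(ValueError):
            fit_rectified_gumbel(np.ones(5))


class TestGumbelPvalue:
    def test_value_at_location(self):
        assert gumbel_pvalue(2.0, 2.0, 1.0) == pytest.approx(1 - np.exp(-1))

    def test_strictly_positive_far_in_tail(self):
        p = gumbel_pvalue(1e3, 0.0, 1.0)
        assert 0 < p < 1e-10  # never exactly zero, unlike the empirical p

    def test_strictly_decreasing(self):
        es = np.linspace(0, 20, 50)
        p = np.array([gumbel_pvalue(e, 3.0, 2.0) for e in es])
        assert np.all(np.diff(p) < 0)

    def test_tracks_permutation_pvalue_centrally(self, exchangeable_prepared):
        """Smooth p-values agree with empirical ones in the null's bulk."""
        null = permutation_null(exchangeable_prepared, M=15, P=1000, seed=21)
        mu, beta = fit_rectified_gumbel(null.es_values)
        lo, hi = np.quantile(null.es_values, [0.05, 0.95])
        for es in np.linspace(lo, hi, 15):
            p_emp = permutation_pvalue(es, null)
            p_gum = gumbel_pvalue(es, mu, beta)
            assert abs(p_emp - p_gum) < 0.05
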