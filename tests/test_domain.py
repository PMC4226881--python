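import numpy as np
import pytest
from scipy import stats

from msea.domain import (
    DomainResult,
    UntestableTranscriptError,
    build_indicators,
    fit_nb_lrt,
    merge_overlapping,
    nb_loglik,
    summarize_transcript,
)
from msea.domain import test_transcript as run_domain_tests
from msea.io_model import DomainAnnotation


def dom(did, start, end):
    return DomainAnnotation(did, did, start, end)


class TestIndicators:
    def test_overlapping_domains_merge_only_in_m2_m3(self, profile_factory):
        profile = profile_factory(
            np.zeros(100, dtype=int), domains=[dom("d1", 10, 50), dom("d2", 40, 80)]
        )
        profile.counts_Y[11] = 1
        indicators = build_indicators(profile)
        by_model = {}
        for ind in indicators:
            by_model.setdefault(ind.model, []).append(ind)
        assert len(by_model["M1"]) == 2
        assert len(by_model["M2"]) == 1
        assert by_model["M2"][0].x.sum() == 71  # [10, 80]
        np.testing.assert_array_equal(by_model["M2"][0].x, by_model["M3"][0].x)

    def test_all_covering_domain_is_unidentifiable(self, profile_factory):
        profile = profile_factory(np.zeros(100, dtype=int), domains=[dom("d", 1, 100)])
        assert build_indicators(profile) == []

    def test_disjoint_domains_stay_separate_in_m2(self, profile_factory):
        profile = profile_factory(
            np.zeros(100, dtype=int), domains=[dom("d1", 10, 20), dom("d2", 60, 70)]
        )
        indicators = build_indicators(profile)
        m2 = [i for i in indicators if i.model == "M2"]
        m3 = [i for i in indicators if i.model == "M3"]
        assert len(m2) == 2
        assert len(m3) == 1 and m3[0].x.sum() == 22

    def test_touching_intervals_are_not_merged(self):
        assert merge_overlapping([(10, 20), (21, 30)]) == [(10, 20), (21, 30)]
        assert merge_overlapping([(10, 20), (20, 30)]) == [(10, 30)]


class TestNbLoglik:
    def test_agrees_with_scipy_nbinom_at_moderate_dispersion(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(2.0, size=50).astype(float)
        mu = np.full(50, 2.3)
        alpha = 0.7
        r = 1 / alpha
        expected = stats.nbinom.logpmf(y.astype(int), r, r / (r + mu)).sum()
        assert nb_loglik(y, mu, alpha) == pytest.approx(expected, abs=1e-9)

    def test_poisson_limit(self):
        y = np.zeros(100)
        y[[2, 5, 11, 17, 23, 31, 40, 47]] = 1
        mu = np.full(100, y.mean())
        ll_pois = stats.poisson.logpmf(y.astype(int), mu).sum()
        assert nb_loglik(y, mu, 1e-8) == pytest.approx(ll_pois, abs=1e-6)


def grid_search_lrt(y, x, alpha=1e-8):
    """Independent oracle: coarse-to-fine 2-D grid over (b0, b1) at fixed
    small dispersion, refining around the best cell three times."""

    def ll(b0, b1):
        return nb_loglik(y, np.exp(b0 + b1 * x), alpha)

    def optimize(f, centers, span):
        best = None
        for _ in range(4):
            g0 = np.linspace(centers[0] - span, centers[0] + span, 41)
            g1 = np.linspace(centers[1] - span, centers[1] + span, 41)
            vals = [(f(a, b), a, b) for a in g0 for b in g1]
            best = max(vals)
            centers, span = (best[1], best[2]), span / 8
        return best[0]

    ll1 = optimize(ll, (np.log(max(y.mean(), 1e-6)), 0.0), 12.0)
    ll0 = optimize(lambda a, b: ll(a, 0.0), (np.log(max(y.mean(), 1e-6)), 0.0), 12.0)
    return ll0, ll1


class TestNbLrt:
    def test_flat_counts_show_no_association(self):
        y = np.ones(100)
        x = np.zeros(100)
        x[:50] = 1
        result = fit_nb_lrt(y, x)
        assert result.lrt_stat == pytest.approx(0.0, abs=1e-6)
        assert result.p_value == pytest.approx(1.0, abs=1e-6)
        assert abs(result.beta1) < 1e-3

    def test_enrichment_inside_region_is_detected(self):
        y = np.zeros(100)
        y[[2, 5, 11, 17, 23, 31, 40, 47]] = 1
        x = np.zeros(100)
        x[:50] = 1
        result = fit_nb_lrt(y, x)
        assert result.converged
        assert result.beta1 > 0
        assert result.p_value < 0.05

    def test_loglikelihood_optima_match_grid_search(self):
        y = np.zeros(100)
        y[[2, 5, 11, 17, 23, 31, 40, 47]] = 1
        x = np.zeros(100)
        x[:50] = 1
        result = fit_nb_lrt(y, x)
        ll0, ll1 = grid_search_lrt(y, x)
        assert result.ll_h0 == pytest.approx(ll0, abs=1e-3)
        assert result.ll_h1 == pytest.approx(ll1, abs=1e-3)

    def test_matches_statsmodels_on_overdispersed_counts(self):
        """Independent cross-check of the ML fit on data where the dispersion
        is interior (away from the Poisson boundary)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        n = 300
        x = np.zeros(n)
        x[: n // 3] = 1
        mu = np.exp(0.3 + 0.9 * x)
        shape = 1 / 0.6  # alpha = 0.6
        y = rng.negative_binomial(shape, shape / (shape + mu)).astype(float)

        ours = fit_nb_lrt(y, x)
        X = sm.add_constant(x)
        ref1 = sm.NegativeBinomial(y, X).fit(disp=0)
        ref0 = sm.NegativeBinomial(y, np.ones((n, 1))).fit(disp=0)
        assert ours.ll_h1 == pytest.approx(ref1.llf, abs=1e-4)
        assert ours.ll_h0 == pytest.approx(ref0.llf, abs=1e-4)
        assert ours.beta1 == pytest.approx(ref1.params[1], abs=1e-3)

    def test_complete_separation_is_bounded(self):
        y = np.zeros(60)
        y[[5, 6, 7, 8]] = 1
        x = np.zeros(60)
        x[:10] = 1
        result = fit_nb_lrt(y, x)
        assert result.converged
        assert result.beta1 <= 20.0 + 1e-9
        assert np.isfinite(result.ll_h1)

    def test_constant_indicator_rejected(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_nb_lrt(np.ones(10), np.ones(10))


def make_result(p, model="M1", region="d1", converged=True):
    return DomainResult(
        transcript_id="T1", gene="G1", model=model, region_label=region,
        beta0=0.0, beta1=0.0, dispersion=0.0, ll_h0=0.0, ll_h1=0.0,
        lrt_stat=0.0, p_value=p, converged=converged,
    )


class TestSummarize:
    def test_minimum_p_with_provenance(self):
        results = [
            make_result(0.3, "M1", "d1"),
            make_result(0.04, "M1", "d2"),
            make_result(0.1, "M3", "all_domains"),
        ]
        p, best = summarize_transcript(results)
        assert p == 0.04
        assert (best.model, best.region_label) == ("M1", "d2")

    def test_single_result_identity(self):
        result = make_result(0.7)
        assert summarize_transcript([result]) == (0.7, result)

    def test_ties_break_by_model_then_region(self):
        results = [
            make_result(0.05, "M3", "all_domains"),
            make_result(0.05, "M1", "d2"),
            make_result(0.05, "M1", "d1"),
        ]
        _, best = summarize_transcript(results)
        assert (best.model, best.region_label) == ("M1", "d1")

    def test_unconverged_results_are_untestable(self):
        with pytest.raises(UntestableTranscriptError):
            summarize_transcript([make_result(0.01, converged=False)])


class TestNullBehaviour:
    def test_per_indicator_p_is_roughly_uniform_under_uniform_mutations(
        self, profile_factory
    ):
        rng = np.random.default_rng(12)
        L, n_mut, reps = 200, 8, 400
        hits = 0
        for _ in range(reps):
            y = np.bincount(rng.integers(0, L, size=n_mut), minlength=L)
            x = np.zeros(L)
            x[40:120] = 1
            hits += fit_nb_lrt(y, x).p_value < 0.05
        assert 0.02 <= hits / reps <= 0.08

    def test_min_selection_is_anticonservative(self, profile_factory):
        rng = np.random.default_rng(13)
        L, n_mut, reps = 200, 8, 200
        domains = [dom("d1", 21, 60), dom("d2", 121, 160)]
        hits_first = hits_min = 0
        for _ in range(reps):
            y = np.bincount(rng.integers(0, L, size=n_mut), minlength=L)
            profile = profile_factory(y, domains=domains)
            results = run_domain_tests(profile)
            first = next(r for r in results if r.model == "M1" and r.region_label == "d1")
            hits_first += first.p_value < 0.05
            p_min, _ = summarize_transcript(results)
            hits_min += p_min < 0.05
        assert hits_min >= hits_first
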