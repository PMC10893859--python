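"""Filters, cell summaries, IRLS logistic regression, cluster bootstrap."""

import numpy as np
import pytest

from facegest.simulate import GeneratorConfig, ObservationRecord, default_config, generate
from facegest.stats import (
    DesignError,
    FilterSpec,
    apply_filters,
    cell_percentages,
    cluster_bootstrap,
    fit_logistic,
    odds_multiplier,
)


def _rec(**kw):
    base = dict(
        initiator_id="A",
        recipient_id="B",
        initiator_sex="M",
        recipient_sex="F",
        dyad_id="DY_A_B",
        group_id="G1",
        year=2016,
        context="positive",
        gesture="BENT",
        face="NEUTRAL",
        recipient_dominant=1,
        response_affiliative=1,
    )
    base.update(kw)
    return ObservationRecord(**base)


class TestFilters:
    def test_negative_context_removed(self):
        recs = [_rec() for _ in range(7)] + [_rec(context="negative") for _ in range(3)]
        out = apply_filters(recs)
        assert len(out) == 7
        assert out.removed == {"context": 3}

    def test_incomplete_removed_with_reason(self):
        recs = [_rec(), _rec(recipient_dominant=None), _rec(face=None)]
        out = apply_filters(recs)
        assert len(out) == 1
        assert out.removed == {"incomplete": 2}

    def test_matches_rowwise_predicate_scan(self):
        rng = np.random.default_rng(0)
        recs = []
        for i in range(300):
            recs.append(
                _rec(
                    context=rng.choice(["positive", "negative", None]),
                    face=rng.choice(["NEUTRAL", "HOOT", None]),
                    recipient_dominant=rng.choice([0, 1, None]),
                    response_affiliative=rng.choice([0, 1, None]),
                    initiator_id=f"I{i}",
                )
            )
        out = apply_filters(recs)
        fields = ("face", "gesture", "recipient_dominant", "response_affiliative")
        expected = [
            r
            for r in recs
            if all(getattr(r, f) is not None for f in fields) and r.context == "positive"
        ]
        assert list(out.records) == expected  # subset, order preserved
        assert sum(out.removed.values()) + len(out) == len(recs)


class TestCellPercentages:
    def test_matches_bruteforce_tally(self):
        recs = generate(default_config(seed=3).scaled(3))
        summaries = cell_percentages(recs)
        for s in summaries:
            sub = [r for r in recs if r.cell() == s.key]
            assert s.n == len(sub)
            assert s.n_affiliative == sum(r.response_affiliative for r in sub)
        assert sum(s.n for s in summaries) == len(recs)  # conservation

    def test_all_affiliative(self):
        recs = [_rec(response_affiliative=1) for _ in range(4)]
        (s,) = cell_percentages(recs)
        assert s.percent == 100.0 and s.percent_rounded == 100

    def test_empty_cells_omitted_and_empty_input(self):
        assert cell_percentages([]) == []
        summaries = cell_percentages([_rec(gesture="BENT")])
        assert {s.key[0] for s in summaries} == {"BENT"}

    def test_marginals_by_aggregation(self):
        recs = [
            _rec(recipient_dominant=1, response_affiliative=1),
            _rec(recipient_dominant=1, response_affiliative=0, gesture="STRETCHED"),
            _rec(recipient_dominant=0, response_affiliative=1),
        ]
        by_dom = {s.key: s for s in cell_percentages(recs, by=("recipient_dominant",))}
        assert by_dom[(1,)].n == 2 and by_dom[(1,)].percent == 50.0
        assert by_dom[(0,)].percent == 100.0


class TestLogisticFit:
    @staticmethod
    def _two_by_two(n11, n10, n01, n00):
        """dominant: affiliative yes/no = n11/n10; non-dominant: n01/n00."""
        recs = []
        for dom, yes, no in ((1, n11, n10), (0, n01, n00)):
            recs += [_rec(recipient_dominant=dom, response_affiliative=1)] * yes
            recs += [_rec(recipient_dominant=dom, response_affiliative=0)] * no
        return recs

    def test_saturated_model_equals_log_odds_ratio(self):
        n11, n10, n01, n00 = 30, 70, 60, 40
        fit = fit_logistic(self._two_by_two(n11, n10, n01, n00), ("intercept", "dominant"))
        beta = fit.params["dominant"]
        assert beta == pytest.approx(np.log((n11 / n10) / (n01 / n00)), abs=1e-8)
        assert fit.converged and not fit.separation
        # Wald machinery is internally consistent
        assert fit.zvalues["dominant"] == pytest.approx(beta / fit.bse["dominant"])
        from scipy import stats as sps

        assert fit.pvalues["dominant"] == pytest.approx(
            2 * sps.norm.sf(abs(fit.zvalues["dominant"]))
        )

    def test_matches_statsmodels_reference(self):
        import statsmodels.api as sm

        from facegest.stats import design_matrix

        recs = generate(default_config(seed=5).scaled(4))
        terms = ("intercept", "dominant", "gesture[STRETCHED]", "face[HOOT]", "face[BARED]",
                 "dominant:gesture[STRETCHED]")
        fit = fit_logistic(recs, terms)
        X, y, _ = design_matrix(recs, terms)
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(
            [fit.params[t] for t in terms], ref.params, atol=1e-6
        )
        np.testing.assert_allclose([fit.bse[t] for t in terms], ref.bse, atol=1e-6)

    def test_separation_flagged_not_converged(self):
        """An all-negative cell drives the intercept to the boundary, as in the
        pathological fit on an extreme cell (huge negative intercept)."""
        recs = [_rec(response_affiliative=0) for _ in range(40)]
        fit = fit_logistic(recs, ("intercept",))
        assert fit.separation
        assert not fit.converged
        assert fit.params["intercept"] < -5

    def test_ridge_gives_finite_estimates_under_separation(self):
        recs = [_rec(response_affiliative=0) for _ in range(40)]
        fit = fit_logistic(recs, ("intercept",), ridge=1.0)
        assert np.isfinite(fit.params["intercept"])

    def test_rank_deficient_names_aliased_terms(self):
        recs = generate(default_config(seed=5))
        with pytest.raises(DesignError, match=r"face\[NEUTRAL\]"):
            # the three face indicators plus intercept are linearly dependent
            fit_logistic(
                recs, ("intercept", "face[HOOT]", "face[BARED]", "face[NEUTRAL]")
            )

    def test_unknown_term(self):
        with pytest.raises(DesignError, match="unknown design term"):
            fit_logistic([_rec()], ("intercept", "rank"))


class TestOddsMultiplier:
    @pytest.mark.parametrize(
        "beta,expected", [(1.37, 3.9), (-1.37, 3.9), (0.0, 1.0), (np.log(2), 2.0)]
    )
    def test_fold_change(self, beta, expected):
        assert odds_multiplier(beta) == expected

    def test_requires_finite(self):
        with pytest.raises(ValueError):
            odds_multiplier(np.inf)


def _percent_dominant(recs):
    sub = [r.response_affiliative for r in recs if r.recipient_dominant == 1]
    return 100.0 * sum(sub) / len(sub)


class TestClusterBootstrap:
    def test_reproducible_and_contains_point(self):
        recs = generate(default_config(seed=7).scaled(5))
        a = cluster_bootstrap(recs, "dyad_id", _percent_dominant, B=100, seed=3)
        b = cluster_bootstrap(recs, "dyad_id", _percent_dominant, B=100, seed=3)
        assert (a.lower, a.upper) == (b.lower, b.upper)
        assert a.lower <= a.point <= a.upper

    def test_single_cluster_degenerate(self):
        recs = [_rec() for _ in range(10)]
        with pytest.raises(ValueError, match="at least two clusters"):
            cluster_bootstrap(recs, "dyad_id", _percent_dominant, B=10, seed=0)

    def test_unknown_cluster_key(self):
        with pytest.raises(ValueError, match="cluster key"):
            cluster_bootstrap([_rec()], "year", _percent_dominant, B=10, seed=0)

    def test_interval_collapses_as_cluster_count_grows(self):
        """Homogeneous clusters: more clusters (at fixed cluster size) tighten
        the interval toward the point estimate."""

        def make(n_ind, n_records):
            cfg = GeneratorConfig(
                cell_probs={("BENT", "NEUTRAL", 1): 0.5},
                cell_counts={("BENT", "NEUTRAL", 1): n_records},
                n_individuals=n_ind,
                n_groups=2,
                seed=1,
            )
            return generate(cfg)

        small = cluster_bootstrap(
            make(8, 120), "dyad_id", _percent_dominant, B=200, seed=2
        )
        large = cluster_bootstrap(
            make(80, 4000), "dyad_id", _percent_dominant, B=200, seed=2
        )
        assert (large.upper - large.lower) < (small.upper - small.lower)

    def test_wider_under_cluster_heterogeneity(self):
        """Random intercepts widen the interval at matched n (paired seeds)."""
        base = default_config(seed=13).scaled(10)
        het = GeneratorConfig.from_dict(
            {**base.to_dict(), "random_intercept_sd": {"dyad_id": 1.5}}
        )
        flat_iv = cluster_bootstrap(
            generate(base), "dyad_id", _percent_dominant, B=200, seed=5
        )
        het_iv = cluster_bootstrap(
            generate(het), "dyad_id", _percent_dominant, B=200, seed=5
        )
        assert (het_iv.upper - het_iv.lower) > (flat_iv.upper - flat_iv.lower)
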