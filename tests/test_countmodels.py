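"""Negative-binomial mixed models, filters and contrasts."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.integrate import quad
from scipy.stats import norm

import florisight as fl
from florisight.count_models import (
    NegativeBinomialGLMM,
    _nb2_loglike,
    filter_eligible,
    normalize_species,
    phenotype_class_of,
)
from florisight.exceptions import DataError


# ---------------------------------------------------------------------------
# filters


def test_small_patch_filter_excludes_large_patch_species():
    roster = pd.DataFrame({"individual_id": ["a", "b", "c"]})
    records = pd.DataFrame(
        {"individual_id": ["a", "a", "b"], "species": ["Luehea speciosa"] * 3}
    )
    counts = fl.small_patch_filter(records, roster=roster)
    assert (counts["n_flpv"] == 0).all()
    assert counts.attrs["n_excluded_visits"] == 3
    assert "luehea speciosa" in counts.attrs["excluded_species"]


def test_small_patch_filter_counts_and_normalises_names():
    roster = pd.DataFrame({"individual_id": ["a", "b"]})
    records = pd.DataFrame(
        {
            "individual_id": ["a", "a", "a", "b"],
            "species": [
                "Malvaviscus arboreus",
                "  malvaviscus   ARBOREUS ",
                "malvaviscus arboreus",
                "Luehea speciosa",
            ],
        }
    )
    counts = fl.small_patch_filter(records, roster=roster).set_index("individual_id")
    assert counts.loc["a", "n_flpv"] == 3
    assert counts.loc["b", "n_flpv"] == 0
    assert counts.attrs["n_retained_visits"] == 3


def test_eligibility_filter_requires_seven_cycles():
    rows = []
    for ind, n in [("x", 7), ("y", 6), ("z", 13)]:
        for c in range(n):
            rows.append({"individual_id": ind, "cycle_id": f"c{c}",
                         "flower_scans": 0, "total_scans": 10})
    out = filter_eligible(pd.DataFrame(rows))
    assert set(out["individual_id"]) == {"x", "z"}
    assert out.attrs["n_dropped"] == 1


def test_phenotype_class_labelling():
    assert phenotype_class_of("561") == "dichromat"
    assert phenotype_class_of("532/561") == "trichromat"
    assert normalize_species(" Bromelia  PINGUIN ") == "bromelia pinguin"


# ---------------------------------------------------------------------------
# the Laplace fit against independent oracles


def _toy_poisson(n=200, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    X = np.column_stack([np.ones(n), x])
    off = np.log(rng.uniform(5, 50, n))
    y = rng.poisson(np.exp(0.3 + 0.5 * x + off))
    return y, X, off


def test_poisson_limit_matches_irls_oracle():
    """With a single covariate, no random effects and the dispersion pinned
    at a huge value, the fit reduces to Poisson regression and must agree
    with the independent IRLS solution."""
    y, X, off = _toy_poisson()
    fit = NegativeBinomialGLMM(y, X, offset=off).fit(fix_theta=1e7)
    oracle = sm.GLM(y, X, offset=off, family=sm.families.Poisson()).fit()
    assert np.abs(fit.params.to_numpy() - np.asarray(oracle.params)).max() < 1e-6


def test_laplace_loglike_matches_adaptive_quadrature():
    """On a tiny two-group mixed model with informative counts the Laplace
    marginal log likelihood agrees with direct adaptive quadrature of the
    random-effect integral to 1e-4 (relative)."""
    rng = np.random.default_rng(42)
    n_per, G = 4, 2
    codes = np.repeat(np.arange(G), n_per)
    X = np.column_stack([np.ones(G * n_per), rng.normal(size=G * n_per)])
    offset = np.log(rng.uniform(20, 60, G * n_per))
    mu = np.exp(X @ [0.0, 0.4] + offset + np.repeat(rng.normal(0, 0.2, G), n_per))
    y = rng.poisson(mu).astype(float)
    m = NegativeBinomialGLMM(y, X, offset=offset, groups={"g": codes})

    def quad_loglike(beta, theta, sigma):
        eta0 = X @ beta + offset
        ll = 0.0
        for g in range(G):
            sel = codes == g

            def f(b):
                return np.exp(_nb2_loglike(y[sel], eta0[sel] + b, theta)) * norm.pdf(
                    b, 0, sigma
                )

            val, _ = quad(f, -8 * sigma, 8 * sigma, limit=200,
                          epsabs=1e-13, epsrel=1e-12)
            ll += np.log(val)
        return ll

    for beta, theta, sigma in [
        (np.array([0.1, 0.3]), 5.0, 0.15),
        (np.array([0.0, 0.4]), 10.0, 0.1),
        (np.array([-0.2, 0.5]), 2.0, 0.25),
    ]:
        lap = m.loglike(beta, theta, [sigma])
        ora = quad_loglike(beta, theta, sigma)
        assert lap == pytest.approx(ora, rel=1e-4)
    # the likelihood at the fitted optimum also matches
    fit = m.fit()
    lap = fit.llf
    ora = quad_loglike(fit.params.to_numpy(), fit.theta,
                       fit.re_sd["g"] if fit.re_sd["g"] > 1e-3 else 1e-3)
    if fit.re_sd["g"] > 1e-3:
        assert lap == pytest.approx(ora, rel=1e-4)


def test_offset_identities():
    y, X, off = _toy_poisson(seed=3)
    base = NegativeBinomialGLMM(y, X, offset=off).fit()
    # adding a constant to the log offset shifts only the intercept, by -c
    shifted = NegativeBinomialGLMM(y, X, offset=off + 3.0).fit()
    assert shifted.params.iloc[0] - base.params.iloc[0] == pytest.approx(-3.0, abs=1e-4)
    assert shifted.params.iloc[1] == pytest.approx(base.params.iloc[1], abs=1e-5)
    # doubling every exposure and every count leaves the slope unchanged
    # (exact in the Poisson limit)
    a = NegativeBinomialGLMM(y, X, offset=off).fit(fix_theta=1e7)
    b = NegativeBinomialGLMM(2 * y, X, offset=off + np.log(2.0)).fit(fix_theta=1e7)
    assert b.params.iloc[1] == pytest.approx(a.params.iloc[1], abs=1e-6)
    assert b.params.iloc[0] == pytest.approx(a.params.iloc[0], abs=1e-6)


def test_z_and_p_satisfy_their_defining_identities():
    y, X, off = _toy_poisson(seed=4)
    fit = NegativeBinomialGLMM(y, X, offset=off).fit()
    z = fit.params / fit.bse
    assert np.allclose(fit.zvalues, z)
    assert np.allclose(fit.pvalues, 2 * (1 - norm.cdf(np.abs(z))))


def test_input_validation():
    with pytest.raises(DataError):
        NegativeBinomialGLMM([-1, 2], np.ones((2, 1)))
    with pytest.raises(DataError):
        NegativeBinomialGLMM([0.5, 1], np.ones((2, 1)))
    with pytest.raises(DataError):
        NegativeBinomialGLMM([1, 2], np.ones((3, 1)))


# ---------------------------------------------------------------------------
# the study models


@pytest.fixture(scope="module")
def behaviour():
    return fl.generate_behavior(fl.BehaviorScenario(), seed=7)


def test_scan_model_fits_and_filters(behaviour):
    fit = fl.scan_model(behaviour["scans"])
    assert set(fit.params.index) == {"intercept", "trichromat"}
    assert set(fit.re_sd) == {"individual", "cycle"}
    assert fit.converged
    # the nested structure is selectable and also converges (on a subset:
    # the per-cell intercepts make the latent field large)
    sub_ids = behaviour["scans"]["individual_id"].unique()[:12]
    sub = behaviour["scans"][behaviour["scans"]["individual_id"].isin(sub_ids)]
    fit_nested = fl.scan_model(sub, re_structure="nested")
    assert set(fit_nested.re_sd) == {"individual", "individual:cycle"}


def test_flpv_model_symmetric_counts_give_zero_estimate():
    roster = pd.DataFrame(
        {
            "individual_id": [f"i{k}" for k in range(8)],
            "phenotype": ["561"] * 4 + ["532/561"] * 4,
            "group": ["G1", "G1", "G2", "G2"] * 2,
            "sex": ["F"] * 8,
        }
    )
    counts = pd.DataFrame(
        {"individual_id": roster["individual_id"], "n_flpv": [3, 1, 2, 4] * 2}
    )
    hours = pd.DataFrame({"group": ["G1", "G2"], "hours": [400.0, 400.0]})
    fit = fl.flpv_model(counts, roster, hours)
    assert fit.params["trichromat"] == pytest.approx(0.0, abs=1e-3)


def test_flpv_model_recovers_planted_effect(behaviour):
    counts = fl.small_patch_filter(behaviour["flpv"], roster=behaviour["roster"])
    fit = fl.flpv_model(counts, behaviour["roster"], behaviour["hours"])
    b, se = fit.params["trichromat"], fit.bse["trichromat"]
    assert abs(b - 0.6882) < 3 * se  # single realisation, wide check


def test_control_contrast_subsets(behaviour):
    scans = behaviour["scans"]
    fit = fl.control_contrasts(scans, "sex_within_561_dichromats")
    assert "male" in fit.params.index
    fit_f = fl.control_contrasts(scans, "females_only")
    assert "trichromat" in fit_f.params.index
    fit_m = fl.control_contrasts(scans, "532_vs_561_males")
    assert "allele_561" in fit_m.params.index
    with pytest.raises(DataError):
        fl.control_contrasts(scans, "no_such_contrast")


def test_female_dichromats_only_from_phenotypes_with_female_carriers(behaviour):
    """In the study population no female carries the 532 dichromat phenotype,
    so a females-only subset contains dichromats of the 543 and 561 classes
    only; the generator reproduces that roster structure."""
    roster = fl.generate_behavior(fl.BehaviorScenario(n_individuals=400), seed=8)[
        "roster"
    ]
    fem_di = roster[(roster["sex"] == "F") & (roster["phenotype_class"] == "dichromat")]
    assert len(fem_di) > 0
    assert set(fem_di["phenotype"]) <= {"543", "561"}


def test_flpv_contrast_on_records(behaviour):
    fit = fl.control_contrasts(
        behaviour["flpv"], "females_only", kind="flpv",
        roster=behaviour["roster"], group_hours=behaviour["hours"],
    )
    assert "trichromat" in fit.params.index
    assert fit.n_obs == (behaviour["roster"]["sex"] == "F").sum()
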