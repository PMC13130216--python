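"""2x2 statistics against hand oracles, Monte-Carlo posteriors, quadrature."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, special, stats

from faerspv.disproportionality import (
    BCPNNHyperParams,
    ContingencyTable,
    MGPSModel,
    MGPSResults,
    bcpnn_ic,
    compute_signal_stats,
    contingency,
    mgps_cells_from_records,
    prr,
    ror,
)

cells = st.integers(min_value=1, max_value=5000)


def test_ror_hand_arithmetic():
    r = ror(ContingencyTable(10, 90, 100, 9900))
    assert r.ror == pytest.approx(11.0, rel=1e-12)


def test_ror_paper_style_two_by_two():
    """Printed univariable 2x2 (894, 5053, 715, 8579) gives 2.12 (1.91-2.36)."""
    r = ror(ContingencyTable(894, 5053, 715, 8579))
    assert r.ror == pytest.approx(2.12, abs=0.005)
    assert r.lo == pytest.approx(1.91, abs=0.005)
    assert r.hi == pytest.approx(2.36, abs=0.005)


def test_prr_and_chi2_hand_arithmetic():
    p = prr(ContingencyTable(10, 90, 100, 9900))
    assert p.prr == pytest.approx(10.0, rel=1e-12)
    # N(ad-bc)^2 / [(a+b)(c+d)(a+c)(b+d)] by hand
    assert p.chi2 == pytest.approx(10100 * 90000**2 / (100 * 10000 * 110 * 9990),
                                   rel=1e-12)


def test_proportional_table_is_null():
    t = ContingencyTable(10, 90, 100, 900)  # a/b == c/d
    assert ror(t).ror == pytest.approx(1.0, rel=1e-12)
    p = prr(t)
    assert p.prr == pytest.approx(1.0, rel=1e-12)
    assert p.chi2 == pytest.approx(0.0, abs=1e-12)
    ic, _ = bcpnn_ic(ContingencyTable(10000, 90000, 100000, 900000))
    assert abs(ic) < 0.01  # independence limit, priors wash out


def test_zero_cells_flagged_undefined_not_corrected():
    r = ror(ContingencyTable(0, 90, 100, 9900))
    assert np.isnan(r.ror) or r.ror == 0.0
    assert np.isnan(r.lo) and np.isnan(r.hi)
    p = prr(ContingencyTable(5, 0, 0, 9900))
    assert np.isnan(p.prr)


@settings(max_examples=200, deadline=None)
@given(a=cells, b=cells, c=cells, d=cells)
def test_ror_prr_algebraic_identity(a, b, c, d):
    """ror/prr == (1 + a/b) / (1 + c/d) on any positive table, to 1e-12."""
    t = ContingencyTable(a, b, c, d)
    lhs = ror(t).ror / prr(t).prr
    rhs = (1 + a / b) / (1 + c / d)
    assert lhs == pytest.approx(rhs, rel=1e-12)


def test_bcpnn_z_linearity():
    t = ContingencyTable(10, 90, 100, 9900)
    ic196 = bcpnn_ic(t, BCPNNHyperParams(z=1.96))
    ic200 = bcpnn_ic(t, BCPNNHyperParams(z=2.0))
    assert ic196.ic == ic200.ic
    v = ((ic196.ic - ic196.ic025) / 1.96) ** 2
    assert ic196.ic025 - ic200.ic025 == pytest.approx((2.0 - 1.96) * np.sqrt(v), rel=1e-9)


def test_bcpnn_matches_posterior_sampling_oracle():
    """Closed-form IC equals the Beta-posterior MC estimate within 0.05 bits."""
    t = ContingencyTable(10, 90, 100, 9900)
    h = BCPNNHyperParams()
    rng = np.random.default_rng(1234)
    n, n1, n_1 = t.n, t.n_drug, t.n_event
    gamma = h.gamma11 * (n + h.alpha) * (n + h.beta) / ((n1 + h.alpha1) * (n_1 + h.beta1))
    m = 10**6
    p11 = rng.beta(t.a + h.gamma11, n - t.a + gamma - h.gamma11, m).mean()
    p1 = rng.beta(n1 + h.alpha1, n - n1 + h.alpha - h.alpha1, m).mean()
    p_1 = rng.beta(n_1 + h.beta1, n - n_1 + h.beta - h.beta1, m).mean()
    ic_mc = np.log2(p11 / (p1 * p_1))
    assert bcpnn_ic(t).ic == pytest.approx(ic_mc, abs=0.05)


def test_contingency_from_cohort_counts_report_level(small_cohort):
    t = contingency(small_cohort, "tacrolimus", "smq")
    exp = small_cohort["exp_tacrolimus"]
    ev = small_cohort["event"]
    assert (t.a, t.b, t.c, t.d) == (
        int((exp & ev).sum()), int((exp & ~ev).sum()),
        int((~exp & ev).sum()), int((~exp & ~ev).sum()))
    assert t.n == len(small_cohort)


def test_multi_exposed_report_counts_in_each_drug_margin():
    import pandas as pd

    cohort = pd.DataFrame({
        "exp_a": [True, True, False, False],
        "exp_b": [True, False, False, False],
        "event": [True, False, True, False],
        "reactions": [frozenset()] * 4,
    })
    ta = contingency(cohort, "a", "smq")
    tb = contingency(cohort, "b", "smq")
    assert ta.n_drug == 2 and tb.n_drug == 1


DUMOUCHEL = MGPSResults(alpha1=0.2, beta1=0.1, alpha2=2.0, beta2=4.0, w=1 / 3,
                        loglik=0.0, converged=True, n_cells=1)


def test_ebgm_digamma_single_component():
    """w=1, Gamma(1,1), a=0, E=1: E[ln lambda] = psi(1) - ln 2."""
    prior = MGPSResults(1.0, 1.0, 1.0, 1.0, 0.5, 0.0, True, 1)
    expected = np.exp(special.digamma(1.0) - np.log(2.0))
    assert float(prior.ebgm(0, 1.0)) == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(0.281, abs=5e-4)


@pytest.mark.parametrize("a,E", [(0, 1.0), (3, 0.5), (10, 1.2), (50, 20.0)])
def test_ebgm_matches_numerical_posterior_integration(a, E):
    q = float(DUMOUCHEL.posterior_weight(a, E))
    g1 = stats.gamma(DUMOUCHEL.alpha1 + a, scale=1 / (DUMOUCHEL.beta1 + E))
    g2 = stats.gamma(DUMOUCHEL.alpha2 + a, scale=1 / (DUMOUCHEL.beta2 + E))
    val, _ = integrate.quad(
        lambda lam: (q * g1.pdf(lam) + (1 - q) * g2.pdf(lam)) * np.log(lam),
        0, np.inf, limit=200)
    assert float(DUMOUCHEL.ebgm(a, E)) == pytest.approx(np.exp(val), abs=1e-6)
    assert DUMOUCHEL.eb05(a, E) < float(DUMOUCHEL.ebgm(a, E))


def test_eb05_is_posterior_fifth_percentile():
    a, E = 10, 1.2
    x = DUMOUCHEL.eb05(a, E)
    q = float(DUMOUCHEL.posterior_weight(a, E))
    g1 = stats.gamma(DUMOUCHEL.alpha1 + a, scale=1 / (DUMOUCHEL.beta1 + E))
    g2 = stats.gamma(DUMOUCHEL.alpha2 + a, scale=1 / (DUMOUCHEL.beta2 + E))
    assert q * g1.cdf(x) + (1 - q) * g2.cdf(x) == pytest.approx(0.05, abs=1e-8)


def test_ebgm_monotone_in_count_and_large_sample_limit():
    vals = [float(DUMOUCHEL.ebgm(a, 2.0)) for a in range(0, 40)]
    assert all(x < y for x, y in zip(vals, vals[1:]))
    # a, E -> inf at fixed ratio r: ebgm -> r
    for r in (0.5, 2.0, 5.0):
        assert float(DUMOUCHEL.ebgm(10_000, 10_000 / r)) == pytest.approx(r, rel=1e-3)


def test_mgps_fit_dominates_true_parameters():
    """On cells simulated from a known two-gamma mixture, the fitted
    loglik is at least the loglik at the truth (minus numerical slack)."""
    rng = np.random.default_rng(8)
    n_cells = 5000
    truth = (0.8, 0.8, 3.0, 1.0, 0.75)
    comp = rng.random(n_cells) < truth[4]
    lam = np.where(comp, rng.gamma(truth[0], 1 / truth[1], n_cells),
                   rng.gamma(truth[2], 1 / truth[3], n_cells))
    E = rng.uniform(0.2, 20.0, n_cells)
    a = rng.poisson(lam * E)
    model = MGPSModel(a, E)
    fitted = model.fit()
    assert fitted.loglik >= model.loglik(*truth) - 1e-6 * n_cells
    # shrinkage sanity on the same data: posterior mean tracks the ensemble
    assert 0.5 < float(np.median(fitted.ebgm(a, E))) < 4.0


def test_mgps_null_simulation_posterior_near_one():
    rng = np.random.default_rng(21)
    E = rng.uniform(0.5, 30.0, 2000)
    a = rng.poisson(E)  # lambda = 1 everywhere
    fitted = MGPSModel(a, E).fit()
    ebgms = fitted.ebgm(a, E)
    assert float(np.median(ebgms)) == pytest.approx(1.0, abs=0.1)


def test_mgps_degenerate_all_zero_cells_flagged():
    fitted = MGPSModel(np.zeros(60), np.full(60, 1e-4)).fit()
    assert fitted.degenerate


def test_mgps_cells_pool_lexicon_names(small_records, small_config):
    from faerspv import deduplicate

    deduped = deduplicate(small_records)
    counts, expected, idx = mgps_cells_from_records(deduped, lexicon=small_config.lexicon())
    assert any(k[0] == "tacrolimus" for k in idx)
    assert not any(k[0] == "prograf" for k in idx)
    assert np.all(expected >= 0) and counts.sum() > 0


def test_ror_ci_coverage_on_synthetic_replicates():
    """95% CI covers a true OR of 3 in 93-97% of 500 replicates."""
    from faerspv import synthetic as syn

    cfg = syn.default_config(n_reports=20_000)
    cfg.drugs = (syn.DrugSpec(key="drugx", exposure_prob=0.05, names=("Drugx",),
                              onset_scale=225.0, onset_shape=0.47),)
    b = 0.03
    odds = 3 * b / (1 - b)
    cfg.events = (("Event a", b),)
    cfg.background_events = ()
    cfg.effect = {("drugx", "Event a"): (odds / (1 + odds)) / b}
    assert syn.true_ror(cfg, "drugx", "Event a") == pytest.approx(3.0, rel=1e-12)
    cover = 0
    reps = 500
    for i in range(reps):
        r = ror(syn.simulate_contingency(cfg, "drugx", seed=3000 + i))
        cover += r.lo <= 3.0 <= r.hi
    assert 0.93 <= cover / reps <= 0.97


def test_compute_signal_stats_bundle(small_cohort):
    st_ = compute_signal_stats(contingency(small_cohort, "tacrolimus", "smq"),
                               prior=DUMOUCHEL)
    assert st_.ror_lo <= st_.ror <= st_.ror_hi
    assert st_.ic025 <= st_.ic
    assert st_.eb05 <= st_.ebgm
    assert np.isfinite(st_.chi2)
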