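"""Forward AIC selection, probability screening, and goodness of fit."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from tpnmrds import compare_pooled, fit_mr, mcds_gof, mr_gof, screen_probs
from tpnmrds.detection_tpn import TPNFit, TPNParams
from tpnmrds.mark_resight import MRFit, MRParams, history_probs
from tpnmrds.model_selection_gof import forward_select, tpn_partial_integral


# ---------------------------------------------------------------------------
# screening

def test_screen_passes_on_moderate_probabilities():
    assert screen_probs(np.full(50, 0.5)).passed


def test_screen_fails_on_any_probability_below_floor():
    p = np.full(50, 0.5)
    p[3] = 0.09
    res = screen_probs(p)
    assert not res.passed and "0.1" in res.reason


def test_screen_fails_when_soft_fraction_exceeded():
    p = np.full(100, 0.5)
    p[:6] = 0.15  # 6% below 0.2 > 5%
    res = screen_probs(p)
    assert not res.passed and res.n_below_02 == 6
    p[5] = 0.5   # exactly 5% is allowed
    assert screen_probs(p).passed


# ---------------------------------------------------------------------------
# forward selection

class _StubFit:
    def __init__(self, aic):
        self.aic = aic


def test_selection_stops_when_no_candidate_improves_enough():
    aics = {(): 100.0, ("a",): 98.5, ("b",): 99.0, ("c",): 98.1}
    fitter = lambda data, f: _StubFit(aics[tuple(sorted(f))])
    trace = forward_select(None, ["a", "b", "c"], fitter)
    assert trace.final_formula == []
    assert trace.final_aic == 100.0


def test_selection_adds_best_candidate_first_and_respects_threshold():
    aics = {(): 100.0, ("a",): 95.0, ("b",): 90.0, ("c",): 99.0,
            ("a", "b"): 87.9, ("b", "c"): 89.5,
            ("a", "b", "c"): 86.5}
    fitter = lambda data, f: _StubFit(aics[tuple(sorted(f))])
    trace = forward_select(None, ["a", "b", "c"], fitter)
    # b first (-10), then a (-2.1); c's further drop (-1.4) is rejected
    assert trace.final_formula == ["b", "a"]
    assert trace.final_aic == 87.9


def test_selection_falls_back_when_final_fails_gof():
    aics = {(): 100.0, ("a",): 90.0, ("a", "b"): 85.0, ("b",): 99.0}
    fitter = lambda data, f: _StubFit(aics[tuple(sorted(f))])

    class _Rep:
        def __init__(self, p):
            self.p_value = p

    gof = lambda fit: _Rep(0.01 if fit.aic == 85.0 else 0.5)
    trace = forward_select(None, ["a", "b"], fitter, gof_fn=gof)
    assert trace.final_formula == ["a"]


def _mr_data(rng, n, gamma):
    z = pd.DataFrame({
        "distance": rng.uniform(22, 1000, n),
        "bed": (rng.random(n) < 0.3).astype(int),
        "pcvr5": rng.integers(0, 6, n).astype(float),
        "pilot_group": 0, "observer_group": 0, "stratum_indicator": 0})
    pp, pb, _ = history_probs(z, MRParams(gamma=gamma))
    r = rng.random(n)
    z["history"] = np.where(r < pp, "pilot", np.where(r < pp + pb, "backseat", "both"))
    return z


def test_forward_selection_matches_exhaustive_on_one_dataset():
    """Sanity check on a single dataset; the full 100-replicate comparison
    against the exhaustive-search oracle runs with the acceptance suite."""
    truth = {"intercept": 0.6, "bed": -1.2, "distance": -0.002, "pcvr5": 0.0}
    candidates = ["bed", "distance", "pcvr5"]
    z = _mr_data(np.random.default_rng(3_000), 200, truth)
    trace = forward_select(z, candidates, lambda data, f: fit_mr(data, f))
    best = min(fit_mr(z, list(sub)).aic
               for k in range(len(candidates) + 1)
               for sub in itertools.combinations(candidates, k))
    assert trace.final_aic <= best + 2.0


# ---------------------------------------------------------------------------
# goodness of fit

REF = TPNParams(theta=np.log(110.5), beta={"intercept": np.log(36.0),
                                           "igrmew": np.log(236.6 / 36.0)})


def _fixed_fit(params, w_b, w, n, formula=()):
    k = len(params.beta) + 1
    return TPNFit(params=params, vcov=np.eye(k), loglik=0.0, aic=0.0,
                  formula=list(formula), w_b=w_b, w=w, n=n)


def test_mcds_gof_perfect_fit_is_zero():
    """Observations placed at the model's bin-quantile structure give an
    exactly zero chi-square statistic."""
    w_b, w = 22.0, 1000.0
    fit = _fixed_fit(REF, w_b, w, n=40)
    one = pd.DataFrame(index=[0])
    total = tpn_partial_integral(one, REF, w_b, w)[0]

    def cdf_inv(q):
        return brentq(lambda x: tpn_partial_integral(one, REF, w_b, x)[0] / total - q,
                      w_b, w)

    B = 4
    edges = np.array([w_b] + [cdf_inv(k / B) for k in range(1, B)] + [w])
    # 10 observations per bin, placed at interior cdf levels of that bin
    xs = [cdf_inv((b + (j + 0.5) / 10) / B) for b in range(B) for j in range(10)]
    coded = pd.DataFrame({"distance": xs})
    rep = mcds_gof(coded, fit, edges=edges, n_params=0)
    assert rep.chi2 == pytest.approx(0.0, abs=1e-9)
    assert rep.df == B - 1
    assert rep.p_value == pytest.approx(1.0)


def test_mcds_gof_bookkeeping(sim_coded, sim_tpn):
    rep = mcds_gof(sim_coded, sim_tpn)
    assert rep.df >= 1
    assert rep.df == rep.n_bins - 1 - sim_tpn.n_params or rep.df == 1
    assert rep.contributions.sum() == pytest.approx(rep.chi2)
    assert 0 <= rep.p_value <= 1 and 0 <= rep.ks_p <= 1
    assert rep.apex_bin_chi2 is not None
    # QQ pairs are the sorted probability-integral transform vs uniform grid
    assert rep.qq.shape == (len(sim_coded), 2)
    assert np.all(np.diff(rep.qq[:, 1]) >= 0)


def test_mcds_gof_rebins_sparse_expected_counts():
    w_b, w = 22.0, 1000.0
    rng = np.random.default_rng(0)
    coded = pd.DataFrame({"distance": rng.uniform(60, 400, 25)})
    fit = _fixed_fit(REF, w_b, w, n=25)
    # fine bins force expected < 1 in the tails and automatic merging
    edges = np.linspace(w_b, w, 21)
    rep = mcds_gof(coded, fit, edges=edges, n_params=0)
    assert rep.rebinned
    assert rep.df >= 1


def test_mr_gof_perfect_fit_is_zero():
    """Equal history counts under even odds give chi-square exactly zero."""
    params = MRParams(gamma={"intercept": 0.0})  # each history prob = 1/3
    rows = []
    for d in (100.0, 300.0, 500.0):
        for h in ("pilot", "backseat", "both"):
            for _ in range(4):
                rows.append({"distance": d, "history": h, "bed": 0,
                             "pcvr5": 0.0, "pilot_group": 0,
                             "observer_group": 0, "stratum_indicator": 0})
    z = pd.DataFrame(rows)
    fit = MRFit(params=params, vcov=np.eye(1), loglik=0.0, aic=0.0,
                formula=[], n=len(z))
    rep = mr_gof(z, fit, n_bins=3, n_params=0)
    assert rep.chi2 == pytest.approx(0.0, abs=1e-9)


def test_mr_gof_df_bookkeeping(sim_coded, sim_mr):
    rep = mr_gof(sim_coded, sim_mr)
    assert rep.df == 2 * rep.n_bins - sim_mr.n_params
    assert 0 <= rep.p_value <= 1


def test_gof_default_bin_counts_recover_published_dfs():
    """With the default bin heuristics, the study sample sizes yield the
    published degrees of freedom for both stages."""
    # distance model: bins = round(sqrt(n)); df = bins - 1 - params
    for n, k, df in [(359, 5, 13), (253, 5, 10), (106, 5, 4)]:
        assert round(np.sqrt(n)) - 1 - k == df
    # mark-resight: bins = round(0.75 sqrt(n)); df = 2 bins - params
    for n, k, df in [(359, 7, 21), (253, 3, 21), (106, 3, 13)]:
        assert 2 * round(0.75 * np.sqrt(n)) - k == df


# ---------------------------------------------------------------------------
# pooled vs separate

def test_compare_pooled_reproduces_published_deltas():
    d_mcds, verdict = compare_pooled(3262.41, 1388.85, 4644.75)
    assert d_mcds == pytest.approx(-6.51, abs=0.005)
    assert verdict == "pooled"
    d_mr, verdict = compare_pooled(502.96, 197.18, 692.14)
    assert d_mr == pytest.approx(-8.00, abs=0.005)
    assert verdict == "pooled"


def test_compare_pooled_partition_check():
    with pytest.raises(ValueError, match="partition"):
        compare_pooled(100.0, 100.0, 190.0, n_a=50, n_b=49, n_pooled=100)


def test_compare_pooled_accepts_fit_objects():
    d, verdict = compare_pooled(_StubFit(50.0), _StubFit(60.0), _StubFit(115.0))
    assert d == pytest.approx(5.0)
    assert verdict == "separate"
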