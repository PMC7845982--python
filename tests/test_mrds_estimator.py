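"""Horvitz-Thompson abundance, variance components, and intervals."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.special import expit

from tpnmrds import (build_design, detection_prob, encounter_rates,
                     estimate_abundance, ht_abundance, lognormal_ci, tpn_g)
from tpnmrds.detection_tpn import TPNFit, TPNParams
from tpnmrds.mark_resight import MRFit, MRParams
from tpnmrds.mrds_estimator import _r2_var


def _unit_fits(w_b, w, sigma=1e9, logit_p=50.0):
    """Fits representing perfect detection: g ~ 1 everywhere, p_union ~ 1."""
    tpn = TPNFit(params=TPNParams(theta=np.log((w_b + w) / 2),
                                  beta={"intercept": np.log(sigma)}),
                 vcov=np.zeros((2, 2)), loglik=0.0, aic=0.0, formula=[],
                 w_b=w_b, w=w, n=1)
    mr = MRFit(params=MRParams(gamma={"intercept": logit_p}),
               vcov=np.zeros((1, 1)), loglik=0.0, aic=0.0, formula=[], n=1)
    return tpn, mr


def _toy_detections(sizes, transects, stratum="A", distance=300.0):
    n = len(sizes)
    return pd.DataFrame({
        "distance": distance, "group_size": sizes, "stratum": stratum,
        "transect_id": transects, "bed": 0, "pcvr5": 0.0, "pilot_group": 0,
        "observer_group": 0, "stratum_indicator": 0, "history": "both"})[:n]


def _toy_design(lengths, area, stratum="A", w=1000.0, w_b=22.0):
    rows = [{"stratum": stratum, "transect_id": f"T{i+1}", "length": l}
            for i, l in enumerate(lengths)]
    return build_design(pd.DataFrame(rows), {stratum: area}, w=w, w_b=w_b)


def test_census_limit():
    """With p = 1 everywhere and habitat equal to the covered strip, the
    estimate is exactly the count of individuals seen."""
    w_b, w = 22.0, 1000.0
    lengths = [20.0] * 5
    area = 2 * (w - w_b) / 1000.0 * sum(lengths)
    design = _toy_design(lengths, area, w=w, w_b=w_b)
    det = _toy_detections(sizes=[2, 1, 3, 1], transects=["T1", "T2", "T2", "T4"])
    tpn, mr = _unit_fits(w_b, w)
    n_hat, dens = ht_abundance(det, design, tpn, mr, "A")
    assert n_hat == pytest.approx(7.0, rel=1e-9)
    assert dens == pytest.approx(7.0 / area * 1000.0, rel=1e-9)


def test_detection_prob_composition_oracle():
    """p̂(z) must equal the quadrature integral of g times the inverse-logit
    union at the apex, over the strip width."""
    w_b, w = 22.0, 1000.0
    tpn = TPNFit(params=TPNParams(theta=np.log(110.5),
                                  beta={"intercept": 3.5823, "igrmew": 1.8844,
                                        "bin2sd1000": 0.6620, "tranflat": 0.3724}),
                 vcov=np.zeros((5, 5)), loglik=0.0, aic=0.0,
                 formula=["bin2sd1000", "tranflat"], w_b=w_b, w=w, n=1)
    mr = MRFit(params=MRParams(gamma={"intercept": 0.7711, "bed": -1.1194,
                                      "distance": -0.0013}),
               vcov=np.zeros((3, 3)), loglik=0.0, aic=0.0, formula=[], n=1)
    z = pd.DataFrame({"distance": [300.0], "group_size": 1, "stratum": "A",
                      "bed": [0], "pcvr5": 0.0, "pilot_group": 0,
                      "observer_group": 0, "stratum_indicator": 0,
                      "bin2sd1000": [0], "tranflat": [0]})
    p = detection_prob(z, tpn, mr)[0]
    # oracle: independent composition of the two stages
    p_obs = expit(0.7711 - 0.0013 * 110.5)
    pdot = p_obs + p_obs - p_obs * p_obs
    integral, _ = quad(lambda u: float(tpn_g(u, z, tpn.params)[0]), w_b, w,
                       limit=400)
    assert p == pytest.approx(pdot * integral / (w - w_b), rel=1e-8)


def test_half_union_with_flat_shape_gives_half():
    w_b, w = 0.0, 1000.0
    tpn, mr = _unit_fits(w_b, w, logit_p=0.0)  # p1 = p2 = 0.5 -> union 0.75
    z = _toy_detections([1], ["T1"])
    p = detection_prob(z, tpn, mr, warn_low=False)[0]
    assert p == pytest.approx(0.75, abs=1e-6)


def test_encounter_rates_from_printed_counts():
    """Point encounter rates recompute the published per-km rates from the
    published counts and efforts."""
    lengths = [7436.4 / 363] * 363
    design = _toy_design(lengths, 8648.2, stratum="9D")
    rng = np.random.default_rng(1)
    tids = rng.choice([f"T{i+1}" for i in range(363)], size=253)
    sizes = np.ones(253, dtype=int)
    extra = rng.choice(253, size=458 - 253)  # distribute 458 bears over 253 groups
    for i in extra:
        sizes[i] += 1
    det = _toy_detections(sizes=list(sizes), transects=list(tids), stratum="9D")
    er = encounter_rates(det, design, "9D")
    assert round(er.individuals, 4) == 0.0616
    assert round(er.groups, 4) == 0.0340
    assert er.groups <= er.individuals
    assert er.individuals_se > 0


def test_r2_variance_equal_length_reduction():
    rng = np.random.default_rng(2)
    counts = rng.poisson(2.0, 100).astype(float)
    lengths = np.full(100, 15.0)
    v = _r2_var(counts, lengths)
    assert v == pytest.approx(100 * counts.var(ddof=1) / (100 * 15.0) ** 2,
                              rel=1e-12)


def test_lognormal_ci_closed_form():
    lo, hi = lognormal_ci(1682.9, 0.1036)
    c = np.exp(1.959963984540054 * np.sqrt(np.log(1 + 0.1036**2)))
    assert lo == pytest.approx(1682.9 / c, rel=1e-12)
    assert hi == pytest.approx(1682.9 * c, rel=1e-12)
    assert lo <= 1682.9 <= hi


def test_ht_sum_never_below_count(sim_coded, sim_design, sim_tpn, sim_mr):
    p = detection_prob(sim_coded, sim_tpn, sim_mr, warn_low=False)
    assert np.all(p <= 1.0 + 1e-12)
    assert np.sum(sim_coded["group_size"] / p) >= sim_coded["group_size"].sum()


def test_estimate_invariant_to_transect_split(sim_coded, sim_design, scenario,
                                              sim_tpn, sim_mr):
    """Splitting one transect into two contiguous halves (tallies preserved)
    leaves the abundance point estimate unchanged."""
    est = estimate_abundance(sim_coded, sim_design, sim_tpn, sim_mr)
    # split the first transect of the first stratum
    import copy
    design2 = copy.deepcopy(sim_design)
    label = list(design2.strata)[0]
    s = design2.strata[label]
    tid = s.transect_lengths.index[0]
    half = s.transect_lengths.iloc[0] / 2
    lengths = s.transect_lengths.drop(tid)
    lengths = pd.concat([lengths, pd.Series([half, half], index=[f"{tid}a", f"{tid}b"])])
    s.transect_lengths = lengths
    coded2 = sim_coded.copy()
    coded2.loc[coded2["transect_id"] == tid, "transect_id"] = f"{tid}a"
    est2 = estimate_abundance(coded2, design2, sim_tpn, sim_mr)
    assert est2.total.abundance == pytest.approx(est.total.abundance, rel=1e-12)
    assert est2.total.cv != est.total.cv  # the ER variance responds to the split


def test_forcing_perfect_apex_detection_decreases_estimate(
        sim_coded, sim_design, sim_tpn, sim_mr):
    """Assuming perfect detection at the apex (p_union = 1) must shrink the
    estimate whenever the fitted apex detection is below 1."""
    est = estimate_abundance(sim_coded, sim_design, sim_tpn, sim_mr)
    _, mr_perfect = _unit_fits(sim_design.w_b, sim_design.w)
    est_perfect = estimate_abundance(sim_coded, sim_design, sim_tpn, mr_perfect)
    assert est_perfect.total.abundance < est.total.abundance


def test_stratified_total_adds_up(sim_coded, sim_design, sim_tpn, sim_mr):
    est = estimate_abundance(sim_coded, sim_design, sim_tpn, sim_mr)
    assert est.total.abundance == pytest.approx(
        sum(s.abundance for s in est.strata.values()), rel=1e-12)
    for s in (*est.strata.values(), est.total):
        assert s.lower95 <= s.abundance <= s.upper95
        assert s.cv == pytest.approx(np.hypot(s.cv_encounter, s.cv_model), rel=1e-9)
        assert s.density_per_1000km2 == pytest.approx(
            s.abundance / s.area * 1000.0, rel=1e-12)


def test_single_stratum_total_equals_stratum(scenario, sim_tpn, sim_mr, sim_coded):
    label = list(scenario.design().strata)[0]
    sub = sim_coded[sim_coded["stratum"] == label]
    rows = [{"stratum": label, "transect_id": t, "length": l}
            for t, l in scenario.design().strata[label].transect_lengths.items()]
    design1 = build_design(pd.DataFrame(rows),
                           {label: scenario.design().strata[label].habitat_area},
                           w=scenario.w, w_b=scenario.w_b)
    est = estimate_abundance(sub, design1, sim_tpn, sim_mr)
    assert est.total.abundance == pytest.approx(
        est.strata[label].abundance, rel=1e-12)


def test_variance_requires_two_transects():
    design = _toy_design([20.0], 100.0)
    det = _toy_detections([1], ["T1"])
    from tpnmrds import SurveyDataError
    with pytest.raises(SurveyDataError, match="2 transects"):
        encounter_rates(det, design, "A")
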