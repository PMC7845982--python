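"""Shared fixtures: one simulated study-scale survey with its fits.

The expensive objects (a full simulated survey and both model fits) are
session-scoped so that estimator, GOF, and CLI tests reuse them.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr
from scipy.stats import truncnorm

from tpnmrds import code_covariates, fit_mcds, fit_mr, simulate_survey, study_scenario

MR_FORMULA = ["bed", "observer", "pilot_group", "distance", "pcvr5", "observer_group"]
MCDS_FORMULA = ["bin2sd1000", "tranflat"]


def sample_two_piece(rng, n, mu, sigma_l, sigma_r, w_b, w):
    """Independent sampler for the two-piece normal density on [w_b, w]:
    choose the side by its piece mass, then draw a truncated normal.
    (Deliberately a different route from the package's own generator.)"""
    mass_l = sigma_l * np.sqrt(2 * np.pi) * (ndtr((mu - w_b) / sigma_l) - 0.5)
    mass_r = sigma_r * np.sqrt(2 * np.pi) * (ndtr((w - mu) / sigma_r) - 0.5)
    left = rng.random(n) < mass_l / (mass_l + mass_r)
    out = np.empty(n)
    out[left] = truncnorm.rvs((w_b - mu) / sigma_l, 0, loc=mu, scale=sigma_l,
                              size=int(left.sum()), random_state=rng)
    out[~left] = truncnorm.rvs(0, (w - mu) / sigma_r, loc=mu, scale=sigma_r,
                               size=int(n - left.sum()), random_state=rng)
    return out


@pytest.fixture(scope="session")
def scenario():
    return study_scenario()


@pytest.fixture(scope="session")
def sim_survey(scenario):
    """(detections, transects, truth) for one study-scale survey."""
    return simulate_survey(scenario, seed=7)


@pytest.fixture(scope="session")
def sim_coded(scenario, sim_survey):
    detections, _, _ = sim_survey
    return code_covariates(detections, scenario.crew_groups())


@pytest.fixture(scope="session")
def sim_design(scenario):
    return scenario.design()


@pytest.fixture(scope="session")
def sim_tpn(scenario, sim_coded):
    return fit_mcds(sim_coded, MCDS_FORMULA, w_b=scenario.w_b, w=scenario.w)


@pytest.fixture(scope="session")
def sim_mr(sim_coded):
    return fit_mr(sim_coded, MR_FORMULA)


@pytest.fixture()
def detections_csv(tmp_path):
    """Small, hand-written detections table in the default CSV dialect."""
    path = tmp_path / "detections.csv"
    path.write_text(
        "distance,search_distance,group_size,activity,percent_cover,"
        "transect_type,pilot,observer,stratum,history,transect_id\n"
        "150,800,1,bedded,20,contour,p1,o1,A,both,T1\n"
        "420,1200,3,feeding,0,straight,p1,o2,A,pilot,T1\n"
        "75,500,2,walking,40,contour,p2,o1,B,backseat,T2\n")
    return path
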