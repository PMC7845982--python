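"""Dual-observer mark-resight model (MR stage).

The pilot and the backseat observer search the same strip, separated by a
screen, and each sighting is credited independently; every detected group
therefore carries a capture history in {pilot-only, backseat-only, both}.
Conditional on a group being detected at all, the history is multinomial

    P(pilot only)    = p1 (1 - p2) / u
    P(backseat only) = (1 - p1) p2 / u          u = p1 + p2 - p1 p2,
    P(both)          = p1 p2 / u

with per-observer detection probabilities modelled on the logit scale,

    logit p_j = gamma . z_j ,

where the design row z_j carries the observer role (0 pilot / 1 backseat),
the sighting covariates (distance in metres, bedded flag, scaled percent
cover, stratum), and the seat-specific crew-group covariate: the pilot row
carries the pilot group and the backseat row the observer group, so the two
seats never share a crew effect.  Maximising this conditional (Huggins-type)
likelihood uses only detected groups — no knowledge of the number missed.

Under point independence the two observers are treated as independent *at
the detection apex* mu of the distance model; the union probability there,
p•(mu, z) = p1 + p2 - p1 p2, rescales the distance model into absolute
detection probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit
from statsmodels.tools.numdiff import approx_fprime, approx_hess

from .detection_tpn import FitError

__all__ = ["MRParams", "MRFit", "conditional_p", "fit_mr", "apex_detection"]

#: covariates shared by both seats (value taken from the detection record)
_SHARED = {"distance": "distance", "bed": "bed", "pcvr5": "pcvr5",
           "stratum": "stratum_indicator"}
_HISTORY_CODES = {"pilot": 0, "backseat": 1, "both": 2}


class SeparationError(FitError):
    """Complete separation: some covariate perfectly predicts a history."""


@dataclass
class MRParams:
    """Logit-scale coefficients, keyed by covariate name plus ``intercept``."""

    gamma: dict[str, float]

    @property
    def names(self) -> list[str]:
        return list(self.gamma)

    def to_vector(self) -> np.ndarray:
        return np.array(list(self.gamma.values()), dtype=float)

    @classmethod
    def from_vector(cls, names, vec) -> "MRParams":
        return cls(gamma=dict(zip(names, map(float, vec))))


def _design_rows(coded: pd.DataFrame, names: list[str], role: int,
                 distance=None) -> np.ndarray:
    """Design matrix for one seat; ``distance`` overrides the observed
    distances (used when evaluating at the apex)."""
    n = len(coded)
    cols = []
    for nm in names:
        if nm == "intercept":
            col = np.ones(n)
        elif nm == "observer":
            col = np.full(n, float(role))
        elif nm == "pilot_group":
            col = np.asarray(coded["pilot_group"], float) if role == 0 else np.zeros(n)
        elif nm == "observer_group":
            col = np.asarray(coded["observer_group"], float) if role == 1 else np.zeros(n)
        elif nm == "distance":
            col = (np.full(n, float(distance)) if distance is not None
                   else np.asarray(coded["distance"], float))
        elif nm in _SHARED:
            col = np.asarray(coded[_SHARED[nm]], float)
        else:
            raise FitError(f"unknown MR covariate {nm!r}")
        cols.append(col)
    return np.column_stack(cols)


def conditional_p(role, x, coded: pd.DataFrame, params: MRParams,
                  n: int | None = None) -> np.ndarray:
    """Per-observer conditional detection probability at distance ``x``.

    ``role`` is ``"pilot"``/0 or ``"backseat"``/1.  ``x`` scalar or array.
    """
    role = {"pilot": 0, "backseat": 1}.get(role, role)
    names = params.names
    if coded is None:
        coded = pd.DataFrame(index=range(n or np.size(x)))
        for nm in names:
            if nm not in ("intercept", "observer", "distance"):
                raise FitError(f"covariate {nm!r} needs coded data")
    X = _design_rows(coded, names, int(role))
    if "distance" in names:
        X[:, names.index("distance")] = np.broadcast_to(
            np.asarray(x, float), (len(coded),))
    return expit(X @ params.to_vector())


def _validate_formula(formula: list[str]):
    if ("pilot_group" in formula or "observer_group" in formula) and "observer" not in formula:
        raise FitError("crew-group covariates require 'observer' in the MR formula "
                       "(the seats must not share a baseline)")


@dataclass
class MRFit:
    """Fitted conditional mark-resight model."""

    params: MRParams
    vcov: np.ndarray
    loglik: float
    aic: float
    formula: list[str]
    n: int
    apex_p: float | None = None
    apex_p_se: float | None = None
    n_params: int = field(init=False)

    def __post_init__(self):
        self.n_params = len(self.params.gamma)

    @property
    def param_names(self) -> list[str]:
        return self.params.names

    def se(self) -> dict[str, float]:
        return dict(zip(self.param_names, np.sqrt(np.diag(self.vcov))))

    def to_dict(self) -> dict:
        d = {
            "model": "conditional dual-observer logistic MR",
            "formula": self.formula,
            "coefficients": dict(self.params.gamma),
            "se": self.se(),
            "vcov": self.vcov.tolist(),
            "loglik": self.loglik,
            "aic": self.aic,
            "n": self.n,
        }
        if self.apex_p is not None:
            d["apex_p"] = {"estimate": self.apex_p, "se": self.apex_p_se}
        return d


def history_probs(coded: pd.DataFrame, params: MRParams):
    """(P[pilot only], P[backseat only], P[both]) per record, conditional on
    detection by at least one observer."""
    names = params.names
    g = params.to_vector()
    p1 = expit(_design_rows(coded, names, 0) @ g)
    p2 = expit(_design_rows(coded, names, 1) @ g)
    u = p1 + p2 - p1 * p2
    return p1 * (1 - p2) / u, (1 - p1) * p2 / u, p1 * p2 / u


def _neg_loglik(coded, names, hist_code):
    X1 = _design_rows(coded, names, 0)
    X2 = _design_rows(coded, names, 1)

    def nll(vec):
        with np.errstate(divide="ignore", invalid="ignore"):
            p1 = expit(X1 @ vec)
            p2 = expit(X2 @ vec)
            u = p1 + p2 - p1 * p2
            lp = np.where(
                hist_code == 0, np.log(p1) + np.log1p(-p2),
                np.where(hist_code == 1, np.log1p(-p1) + np.log(p2),
                         np.log(p1) + np.log(p2)))
            out = -(np.sum(lp) - np.sum(np.log(u)))
        return out if np.isfinite(out) else 1e12

    return nll


def fit_mr(coded: pd.DataFrame, formula: list[str], start: MRParams | None = None) -> MRFit:
    """Maximum-likelihood fit of the conditional mark-resight model.

    ``formula`` lists covariates from {observer, distance, bed, pcvr5,
    pilot_group, observer_group, stratum}; an intercept is always included.
    """
    _validate_formula(formula)
    hist = coded["history"].map(_HISTORY_CODES)
    if hist.isna().any():
        bad = coded.loc[hist.isna(), "history"].unique()
        raise FitError(f"inadmissible capture history value(s): {list(bad)}")
    hist_code = hist.to_numpy()

    names = ["intercept"] + [f for f in formula if f != "intercept"]
    nll = _neg_loglik(coded, names, hist_code)

    v0 = np.zeros(len(names))
    if start is not None:
        v0 = np.array([start.gamma.get(nm, 0.0) for nm in names])
    else:
        # both-fraction pins a sensible intercept start
        frac_both = max(np.mean(hist_code == 2), 0.05)
        v0[0] = np.log(np.sqrt(frac_both) / (1 - np.sqrt(frac_both) + 1e-9))

    res = optimize.minimize(nll, v0, method="BFGS",
                            options={"maxiter": 1000, "gtol": 1e-8})
    vec = res.x
    if not np.isfinite(res.fun) or res.fun >= 1e11:
        raise FitError(f"MR optimization failed: {res.message}")
    if (np.abs(vec) > 30).any():
        culprit = names[int(np.argmax(np.abs(vec)))]
        raise SeparationError(f"complete separation suspected on covariate {culprit!r}")

    H = approx_hess(vec, nll)
    try:
        vcov = np.linalg.inv(H)
    except np.linalg.LinAlgError as e:
        raise FitError("observed information is singular: ill-conditioned MR model") from e
    se = np.sqrt(np.abs(np.diag(vcov)))
    if (se > 100).any():
        culprit = names[int(np.argmax(se))]
        raise SeparationError(f"complete separation suspected on covariate {culprit!r} "
                              "(unbounded standard error)")

    ll = -float(res.fun)
    k = len(names)
    return MRFit(params=MRParams.from_vector(names, vec), vcov=vcov,
                 loglik=ll, aic=-2 * ll + 2 * k, formula=list(formula), n=len(coded))


def pdot_at(coded: pd.DataFrame, params: MRParams, x) -> np.ndarray:
    """Union detection probability p• = p1 + p2 - p1 p2 at distance x."""
    names = params.names
    g = params.to_vector()
    X1 = _design_rows(coded, names, 0, distance=0.0)
    X2 = _design_rows(coded, names, 1, distance=0.0)
    if "distance" in names:
        j = names.index("distance")
        X1[:, j] = X2[:, j] = np.broadcast_to(np.asarray(x, float), (len(coded),))
    p1, p2 = expit(X1 @ g), expit(X2 @ g)
    return p1 + p2 - p1 * p2


def apex_detection(fit: MRFit, mu: float, coded: pd.DataFrame,
                   weights: np.ndarray | str | None = "unit"):
    """Average apex detection p̂•(mu) over the detections, with delta-method SE.

    ``weights`` may be an array (e.g. Horvitz-Thompson weights 1/p̂ from the
    combined estimator), ``"unit"`` for an unweighted mean, or None (unit).
    Updates ``fit.apex_p`` in place and returns ``(estimate, se)``.
    """
    if weights is None or (isinstance(weights, str) and weights == "unit"):
        wts = np.ones(len(coded))
    else:
        wts = np.asarray(weights, dtype=float)
    wts = wts / wts.sum()
    names = fit.param_names

    def avg(vec):
        p = pdot_at(coded, MRParams.from_vector(names, vec), mu)
        return float(wts @ p)

    vec = fit.params.to_vector()
    est = avg(vec)
    grad = np.asarray(approx_fprime(vec, avg)).ravel()
    se = float(np.sqrt(grad @ fit.vcov @ grad))
    fit.apex_p, fit.apex_p_se = est, se
    return est, se
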