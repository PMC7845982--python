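"""Two-piece normal detection function with covariates (MCDS stage).

Aerial surveys flown with flat side-windows cannot see the strip directly
under the aircraft, so detection probability peaks not on the transect line
but at an apex distance ``mu`` off the line.  The detection shape used here
is a two-piece (split) normal:

    g(x) = exp(-(x - mu)^2 / (2 sigma(x, z)^2)),        g(mu) = 1,

with a log-linear scale model

    ln sigma(x, z) = b0 + b_A * 1[x > mu] + sum_c b_c z_c
                        + sum_c b_{A:c} * 1[x > mu] * z_c.

The indicator ``1[x > mu]`` (the asymmetry term) lets the scale differ left
and right of the apex; interactions with it let a covariate act on one side
only.  The conditional multiple-covariate distance-sampling likelihood for
perpendicular distances x_i truncated to [w_b, w] is

    L = prod_i g(x_i, z_i) / int_{w_b}^{w} g(u, z_i) du,

and the normalizing integral has a closed form in the Gaussian CDF.
Maximisation is by quasi-Newton search from several deterministic starts
(the likelihood surface is only piecewise-smooth in mu).  Covariates are
affinely rescaled to [-5, 5] internally for optimisation and the
coefficients mapped back, so reported values are on the data scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr  # Gaussian CDF, vectorized
from statsmodels.tools.numdiff import approx_fprime

__all__ = [
    "TPNParams",
    "TPNFit",
    "FitError",
    "tpn_g",
    "tpn_normalizer",
    "fit_mcds",
    "average_detection_curve",
]

_SQRT2PI = np.sqrt(2.0 * np.pi)
ASYM = "igrmew"  # asymmetry indicator: 1 if distance exceeds the fitted apex


class FitError(RuntimeError):
    """Optimizer failure or ill-conditioned information matrix."""


@dataclass
class TPNParams:
    """Two-piece normal parameters: ``theta`` = ln(apex distance in m),
    ``beta`` = named log-scale coefficients (keys: ``intercept``, ``igrmew``,
    covariate names, and ``igrmew:<name>`` interactions)."""

    theta: float
    beta: dict[str, float]

    @property
    def mu(self) -> float:
        """Apex (modal) detection distance, metres."""
        return float(np.exp(self.theta))

    @property
    def names(self) -> list[str]:
        return ["ln_mu"] + list(self.beta)

    def to_vector(self) -> np.ndarray:
        return np.array([self.theta, *self.beta.values()], dtype=float)

    @classmethod
    def from_vector(cls, names: list[str], vec: np.ndarray) -> "TPNParams":
        assert names[0] == "ln_mu"
        return cls(theta=float(vec[0]), beta=dict(zip(names[1:], map(float, vec[1:]))))


def _covariate_terms(beta: dict[str, float]):
    plain = [(k, v) for k, v in beta.items()
             if k not in ("intercept", ASYM) and not k.startswith(ASYM + ":")]
    inter = [(k.split(":", 1)[1], v) for k, v in beta.items() if k.startswith(ASYM + ":")]
    return plain, inter


def _column(Z, name, n):
    if Z is None:
        return np.zeros(n)
    if isinstance(Z, pd.DataFrame):
        return np.asarray(Z[name], dtype=float)
    return np.broadcast_to(np.asarray(Z[name], dtype=float), (n,))


def log_sigma_sides(params: TPNParams, Z, n: int):
    """(ln sigma_left, ln sigma_right) arrays of length n for covariates Z."""
    beta = params.beta
    base = np.full(n, beta.get("intercept", 0.0))
    plain, inter = _covariate_terms(beta)
    for name, coef in plain:
        base = base + coef * _column(Z, name, n)
    right = base + beta.get(ASYM, 0.0)
    for name, coef in inter:
        right = right + coef * _column(Z, name, n)
    # overflow guard for extreme optimizer proposals
    return np.clip(base, -80, 80), np.clip(right, -80, 80)


def tpn_g(x, Z, params: TPNParams) -> np.ndarray:
    """Detection shape g(x | z) in (0, 1]; g(mu) = 1 exactly.

    ``x`` may be scalar or array; ``Z`` a DataFrame aligned with x (or None
    for an intercept-only scale).  Distances at exactly the apex use the
    left-side scale (the indicator requires the distance to *exceed* mu).
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    n = x.size
    mu = params.mu
    ls_left, ls_right = log_sigma_sides(params, Z, n)
    sigma = np.where(x > mu, np.exp(ls_right), np.exp(ls_left))
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _piece_integral(mu, sigma, lo, hi):
    # integral of exp(-(u-mu)^2/(2 sigma^2)) over [lo, hi], hi >= lo
    return sigma * _SQRT2PI * (ndtr((hi - mu) / sigma) - ndtr((lo - mu) / sigma))


def tpn_normalizer(Z, params: TPNParams, w_b: float, w: float, n: int | None = None) -> np.ndarray:
    """Closed-form ``int_{w_b}^{w} g(u, z) du`` (metres), per row of Z.

    Splits the integral at the apex; each side is a Gaussian integral.  Works
    for any apex position, including degenerate apexes outside [w_b, w].
    """
    if n is None:
        n = len(Z) if Z is not None else 1
    mu = params.mu
    ls_left, ls_right = log_sigma_sides(params, Z, n)
    sig_l, sig_r = np.exp(ls_left), np.exp(ls_right)
    split = min(max(mu, w_b), w)
    return _piece_integral(mu, sig_l, w_b, split) + _piece_integral(mu, sig_r, split, w)


@dataclass
class TPNFit:
    """Fitted MCDS model: MLE, covariance (inverse observed information),
    log-likelihood and AIC."""

    params: TPNParams
    vcov: np.ndarray
    loglik: float
    aic: float
    formula: list[str]
    w_b: float
    w: float
    n: int
    converged: bool = True
    n_params: int = field(init=False)

    def __post_init__(self):
        self.n_params = len(self.params.beta) + 1

    @property
    def mu(self) -> float:
        return self.params.mu

    @property
    def param_names(self) -> list[str]:
        return self.params.names

    def se(self) -> dict[str, float]:
        return dict(zip(self.param_names, np.sqrt(np.diag(self.vcov))))

    def to_dict(self) -> dict:
        return {
            "model": "two-piece-normal MCDS",
            "formula": self.formula,
            "truncation": {"w_b": self.w_b, "w": self.w},
            "coefficients": {"ln_mu": self.params.theta, **self.params.beta},
            "se": self.se(),
            "vcov": self.vcov.tolist(),
            "loglik": self.loglik,
            "aic": self.aic,
            "n": self.n,
        }


def _neg_loglik_factory(x, Z, names, w_b, w):
    n = x.size
    # plausibility window on the scale: below ~1 m the split model can chase a
    # degenerate spike solution (all mass on one side of the apex); above 100
    # strip-widths the scale is unidentified.  A smooth barrier keeps the
    # search interior without altering the optimum for any reasonable fit.
    ls_lo, ls_hi = np.log(1.0), np.log(100.0 * (w - w_b))

    def nll(vec):
        params = TPNParams.from_vector(names, vec)
        if not np.isfinite(params.theta) or abs(params.theta) > 50:
            return 1e12
        ls_l, ls_r = log_sigma_sides(params, Z, n)
        pen = (np.sum(np.square(np.maximum(ls_lo - ls_l, 0)))
               + np.sum(np.square(np.maximum(ls_l - ls_hi, 0)))
               + np.sum(np.square(np.maximum(ls_lo - ls_r, 0)))
               + np.sum(np.square(np.maximum(ls_r - ls_hi, 0))))
        g = tpn_g(x, Z, params)
        nu = tpn_normalizer(Z, params, w_b, w, n=n)
        if np.any(nu <= 0) or np.any(g <= 0):
            return 1e12
        out = float(-(np.sum(np.log(g)) - np.sum(np.log(nu))))
        return out + 1e4 * pen

    return nll


def _rescale_transform(Z: pd.DataFrame | None, formula: list[str]):
    """Affine maps z -> (z - min)/range * 10 - 5 per covariate column.

    Returns (scaled Z, matrix T with beta_unscaled = T @ beta_scaled) over
    the packed parameter order.  Constant columns are left untouched.
    """
    plain_cols = sorted({f.split(":", 1)[1] if ":" in f else f for f in formula})
    a, b = {}, {}
    Zs = Z.copy() if Z is not None else None
    for c in plain_cols:
        col = np.asarray(Z[c], dtype=float)
        rng = col.max() - col.min()
        if rng > 0:
            a[c] = 10.0 / rng
            b[c] = -5.0 - 10.0 * col.min() / rng
            Zs[c] = a[c] * col + b[c]
        else:
            a[c], b[c] = 1.0, 0.0
    return Zs, a, b


def _unscale_matrix(names: list[str], a: dict, b: dict) -> np.ndarray:
    """Linear map T: packed scaled parameter vector -> unscaled vector."""
    k = len(names)
    T = np.eye(k)
    idx = {nm: i for i, nm in enumerate(names)}
    for nm in names:
        if nm in ("ln_mu", "intercept", ASYM):
            continue
        if nm.startswith(ASYM + ":"):
            c = nm.split(":", 1)[1]
            T[idx[nm], idx[nm]] = a[c]
            T[idx[ASYM], idx[nm]] = b[c]
        else:
            T[idx[nm], idx[nm]] = a[nm]
            T[idx["intercept"], idx[nm]] = b[nm]
    return T


def _starts(x, include_asym):
    """Deterministic multi-start seeds: apex at low quantiles of the observed
    distances, spread-based scale inits."""
    x = np.asarray(x, float)
    seeds = []
    s = max(np.std(x), 1.0)
    for q in (0.1, 0.2, 0.3):
        mu0 = max(np.quantile(x, q), 1.0)
        left = x[x <= mu0]
        right = x[x > mu0]
        s_l = max(np.std(left), s / 4) if left.size > 2 else s / 2
        s_r = max(np.std(right), s / 4) if right.size > 2 else s
        seeds.append((np.log(mu0), np.log(s_l), np.log(s_r / s_l) if include_asym else None))
    mu0 = max(np.quantile(x, 0.2), 1.0)
    for fac in (0.5, 2.0):
        seeds.append((np.log(mu0), np.log(s * fac / 2), np.log(2.0) if include_asym else None))
    return seeds


def fit_mcds(
    coded: pd.DataFrame,
    formula: list[str],
    w_b: float,
    w: float,
    start: TPNParams | None = None,
    include_asymmetry: bool = True,
    fix_mu: float | None = None,
    multi_start: bool = True,
    gtol: float = 1e-8,
) -> TPNFit:
    """Maximum-likelihood fit of the two-piece normal MCDS model.

    ``formula`` lists scale covariates by coded name; ``igrmew:<name>``
    denotes an interaction with the asymmetry indicator.  ``fix_mu`` pins the
    apex (used for degenerate/diagnostic fits); ``include_asymmetry=False``
    drops the asymmetry term, giving a symmetric (half-)normal scale.
    """
    x = np.asarray(coded["distance"], dtype=float)
    if np.unique(x).size < 2:
        raise FitError("need at least 2 distinct distances to fit a detection function")
    n = x.size

    names = ["ln_mu", "intercept"]
    if include_asymmetry:
        names.append(ASYM)
    names += [f for f in formula if f not in names]
    for f in formula:
        if f.startswith(ASYM + ":") and not include_asymmetry:
            raise FitError(f"interaction {f!r} requires the asymmetry term")

    Z = None
    if formula:
        Zs, a, b = _rescale_transform(coded, formula)
        Z = Zs
        T = _unscale_matrix(names, a, b)
    else:
        T = np.eye(len(names))

    nll_full = _neg_loglik_factory(x, Z, names, w_b, w)

    theta_fixed = np.log(fix_mu) if fix_mu is not None else None
    if theta_fixed is not None:
        def nll(v):
            return nll_full(np.concatenate([[theta_fixed], v]))
    else:
        nll = nll_full

    lo_mu = np.log(max(w_b, 1e-3)) if w_b > 0 else np.log(1e-3)
    hi_mu = np.log(w) - 1e-9
    bounds = [(lo_mu, hi_mu)] + [(None, None)] * (len(names) - 1)

    def _pack_start(seed):
        th0, ls0, asym0 = seed
        v = np.zeros(len(names))
        v[0] = np.clip(th0, lo_mu, hi_mu)
        v[names.index("intercept")] = ls0
        if include_asymmetry and asym0 is not None:
            v[names.index(ASYM)] = asym0
        return v

    start_vecs = []
    if start is not None:
        sv = np.zeros(len(names))
        sv[0] = start.theta
        for i, nm in enumerate(names[1:], 1):
            sv[i] = start.beta.get(nm, 0.0)
        # starts are given on the data scale; map into the scaled space
        start_vecs.append(np.linalg.solve(T, sv))
    seeds = _starts(x, include_asymmetry)
    if not multi_start:
        seeds = seeds[1:2]
    if start is None or multi_start:
        start_vecs += [_pack_start(s) for s in seeds]

    best = None
    for v0 in start_vecs:
        if theta_fixed is not None:
            res = optimize.minimize(nll, v0[1:], method="L-BFGS-B",
                                    options={"maxiter": 500, "ftol": 1e-12, "gtol": gtol})
            vec = np.concatenate([[theta_fixed], res.x])
        else:
            res = optimize.minimize(nll, v0, method="L-BFGS-B", bounds=bounds,
                                    options={"maxiter": 500, "ftol": 1e-12, "gtol": gtol})
            vec = res.x
        if best is None or res.fun < best[0] - 1e-12:
            best = (res.fun, vec, res)
    fun, vec, res = best
    if not np.isfinite(fun) or fun >= 1e11:
        raise FitError(f"MCDS optimization failed: {res.message}")

    # information from the outer product of per-observation scores (BHHH) on
    # the scaled surface, mapped back to the data scale.  The likelihood is
    # only piecewise-smooth in ln(mu) — kinks where the apex crosses a data
    # point — so a small-step numeric Hessian understates the curvature; the
    # score outer product does not, and is always positive semidefinite.
    free = np.arange(len(names)) if theta_fixed is None else np.arange(1, len(names))

    def obs_loglik(vf):
        v = vec.copy()
        v[free] = vf
        params_v = TPNParams.from_vector(names, v)
        g = tpn_g(x, Z, params_v)
        nu = tpn_normalizer(Z, params_v, w_b, w, n=n)
        return np.log(g) - np.log(nu)

    S = approx_fprime(vec[free], obs_loglik)
    B = S.T @ S
    vcov_scaled = np.zeros((len(names), len(names)))
    try:
        Binv = np.linalg.inv(B)
    except np.linalg.LinAlgError as e:
        raise FitError("observed information is singular: ill-conditioned model") from e
    vcov_scaled[np.ix_(free, free)] = Binv

    vec_unscaled = T @ vec
    vcov = T @ np.nan_to_num(vcov_scaled) @ T.T
    params = TPNParams.from_vector(names, vec_unscaled)
    ll = -fun
    k = len(names) - (1 if theta_fixed is not None else 0)
    return TPNFit(params=params, vcov=vcov, loglik=ll, aic=-2 * ll + 2 * k,
                  formula=list(formula), w_b=w_b, w=w, n=n, converged=bool(res.success))


def loglik_at(coded: pd.DataFrame, params: TPNParams, w_b: float, w: float) -> float:
    """Conditional MCDS log-likelihood of the data at arbitrary parameters."""
    x = np.asarray(coded["distance"], dtype=float)
    g = tpn_g(x, coded, params)
    nu = tpn_normalizer(coded, params, w_b, w, n=x.size)
    return float(np.sum(np.log(g)) - np.sum(np.log(nu)))


def average_detection_curve(fit: TPNFit, coded: pd.DataFrame, grid: np.ndarray | None = None):
    """Mean-covariate detection curve for plotting/QQ overlays.

    Evaluates g over a distance grid with every scale covariate held at its
    observed mean, so the curve's apex is at the fitted mu with value 1.
    """
    if grid is None:
        grid = np.linspace(fit.w_b, fit.w, 512)
    plain, inter = _covariate_terms(fit.params.beta)
    cols = {name for name, _ in plain} | {name for name, _ in inter}
    means = {c: np.full(grid.size, float(np.mean(coded[c]))) for c in cols}
    Zbar = pd.DataFrame(means) if means else None
    return grid, tpn_g(grid, Zbar, fit.params)
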