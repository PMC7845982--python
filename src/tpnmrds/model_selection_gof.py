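"""AIC forward selection, probability screening, and goodness of fit.

Model selection is greedy forward AIC: starting from the mandatory terms,
the candidate giving the largest AIC drop is added while the drop is below
-2; a final model must additionally pass a chi-square goodness-of-fit test
(p > 0.05) and the low-detection-probability screen (no p̂ < 0.1, and at
most 5% of p̂ below 0.2).

Distance-model GOF bins the distances (equal-count bins by default; the
default bin count is round(sqrt(n)) and is configurable, as is an explicit
edge list) and compares observed counts with expected counts obtained by
integrating each record's own fitted density over the bin.  The
Kolmogorov-Smirnov test and the QQ pairs use the per-record probability
integral transform F(x_i | z_i), which is uniform under a correct model.
Mark-resight GOF crosses capture history with distance bin (default bin
count round(0.75 sqrt(n))); within each bin the three history cells are
constrained to the bin total, so df = 2*bins - n_params.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr

from .detection_tpn import FitError, TPNFit, TPNParams, log_sigma_sides
from .mark_resight import MRFit, history_probs

__all__ = [
    "SelectionTrace",
    "GofReport",
    "ScreenResult",
    "forward_select",
    "screen_probs",
    "mcds_gof",
    "mr_gof",
    "compare_pooled",
    "tpn_partial_integral",
]

_SQRT2PI = np.sqrt(2.0 * np.pi)


# ---------------------------------------------------------------------------
# screening

@dataclass
class ScreenResult:
    passed: bool
    n: int
    n_below_01: int
    n_below_02: int
    reason: str = ""


def screen_probs(p_hat: np.ndarray, floor: float = 0.1, soft: float = 0.2,
                 soft_frac: float = 0.05) -> ScreenResult:
    """Low-detection-probability screen: fail if any p̂ < 0.1 or more than
    5% of the p̂ are below 0.2."""
    p = np.asarray(p_hat, dtype=float)
    n = p.size
    n01 = int(np.sum(p < floor))
    n02 = int(np.sum(p < soft))
    if n01 > 0:
        return ScreenResult(False, n, n01, n02, f"{n01} detection probabilities < {floor}")
    if n and n02 / n > soft_frac:
        return ScreenResult(False, n, n01, n02,
                            f"{n02}/{n} = {n02 / n:.1%} of probabilities < {soft}")
    return ScreenResult(True, n, n01, n02)


# ---------------------------------------------------------------------------
# forward selection

@dataclass
class SelectionTrace:
    steps: list[dict] = field(default_factory=list)
    final_formula: list[str] = field(default_factory=list)
    final_fit: object | None = None

    @property
    def final_aic(self) -> float:
        return self.final_fit.aic if self.final_fit is not None else np.nan

    def to_dict(self) -> dict:
        return {"steps": self.steps, "final_formula": self.final_formula,
                "final_aic": self.final_aic}


def forward_select(data, candidates: list[str], fit_fn, gof_fn=None,
                   screen_fn=None, threshold: float = -2.0) -> SelectionTrace:
    """Greedy forward AIC selection.

    ``fit_fn(data, formula)`` fits a model (adding any mandatory terms
    itself) and returns an object with ``.aic``; candidates are tried in
    list order, ties in AIC drop broken by that order.  ``gof_fn(fit)`` and
    ``screen_fn(fit)`` (optional) gate the *final* model: if the selected
    model fails either, the trace walks back to the last accepted model that
    passes.
    """
    trace = SelectionTrace()
    incumbent = fit_fn(data, [])
    trace.steps.append({"formula": [], "aic": incumbent.aic, "accepted": True,
                        "reason": "base model"})
    path = [([], incumbent)]
    current: list[str] = []

    remaining = list(candidates)
    while remaining:
        best = None
        for cand in remaining:
            formula = current + [cand]
            try:
                fit = fit_fn(data, formula)
            except FitError as e:
                trace.steps.append({"formula": formula, "aic": None,
                                    "accepted": False, "reason": f"fit failed: {e}"})
                continue
            d_aic = fit.aic - incumbent.aic
            if best is None or d_aic < best[0] - 1e-12:
                best = (d_aic, cand, fit)
        if best is None:
            break
        d_aic, cand, fit = best
        if d_aic < threshold:
            current = current + [cand]
            incumbent = fit
            remaining.remove(cand)
            path.append((current, fit))
            trace.steps.append({"formula": list(current), "aic": fit.aic,
                                "accepted": True, "reason": f"dAIC = {d_aic:.2f}"})
        else:
            trace.steps.append({"formula": current + [cand], "aic": fit.aic,
                                "accepted": False,
                                "reason": f"best dAIC = {d_aic:.2f} >= {threshold}"})
            break

    # final-model eligibility: GOF and probability screening
    for formula, fit in reversed(path):
        ok, why = True, []
        if gof_fn is not None:
            rep = gof_fn(fit)
            if rep.p_value <= 0.05:
                ok, why = False, why + [f"GOF p = {rep.p_value:.3f} <= 0.05"]
        if ok and screen_fn is not None:
            scr = screen_fn(fit)
            if not scr.passed:
                ok, why = False, why + [scr.reason]
        if ok:
            trace.final_formula, trace.final_fit = list(formula), fit
            if (formula, fit) != path[-1]:
                trace.steps.append({"formula": list(formula), "aic": fit.aic,
                                    "accepted": True,
                                    "reason": "fell back: larger models failed eligibility"})
            return trace
        trace.steps.append({"formula": list(formula), "aic": fit.aic,
                            "accepted": False, "reason": "; ".join(why)})
    trace.final_formula, trace.final_fit = path[-1]
    return trace


# ---------------------------------------------------------------------------
# goodness of fit

@dataclass
class GofReport:
    chi2: float
    df: int
    p_value: float
    ks_stat: float | None = None
    ks_p: float | None = None
    qq: np.ndarray | None = None
    apex_bin_chi2: float | None = None
    n_bins: int = 0
    contributions: np.ndarray | None = None
    rebinned: bool = False

    def to_dict(self) -> dict:
        d = {"chi2": self.chi2, "df": self.df, "p": self.p_value,
             "n_bins": self.n_bins, "rebinned": self.rebinned}
        if self.ks_stat is not None:
            d["ks"] = {"stat": self.ks_stat, "p": self.ks_p}
        if self.apex_bin_chi2 is not None:
            d["apex_bin_chi2"] = self.apex_bin_chi2
        return d


def tpn_partial_integral(coded: pd.DataFrame, params: TPNParams, w_b: float,
                         hi) -> np.ndarray:
    """Per-record ``int_{w_b}^{hi_i} g(u, z_i) du`` with row-wise upper limits."""
    n = len(coded)
    hi = np.broadcast_to(np.asarray(hi, dtype=float), (n,))
    mu = params.mu
    ls_l, ls_r = log_sigma_sides(params, coded, n)
    sig_l, sig_r = np.exp(ls_l), np.exp(ls_r)
    split = np.clip(np.full(n, mu), w_b, hi)
    left = sig_l * _SQRT2PI * (ndtr((split - mu) / sig_l) - ndtr((w_b - mu) / sig_l))
    right = sig_r * _SQRT2PI * (ndtr((hi - mu) / sig_r) - ndtr((split - mu) / sig_r))
    return left + right


def _pit(coded: pd.DataFrame, fit: TPNFit) -> np.ndarray:
    x = np.asarray(coded["distance"], dtype=float)
    num = tpn_partial_integral(coded, fit.params, fit.w_b, x)
    den = tpn_partial_integral(coded, fit.params, fit.w_b, np.full(x.size, fit.w))
    return num / den


def _quantile_edges(x: np.ndarray, n_bins: int, lo: float, hi: float) -> np.ndarray:
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1))
    qs[0], qs[-1] = lo, hi
    return np.unique(qs)


def _merge_small(observed, expected, extra=None, min_expected=1.0):
    """Merge adjacent bins until every expected count is >= min_expected."""
    obs, exp = list(observed), list(expected)
    ext = [list(e) for e in (extra or [])]
    merged = False
    i = 0
    while i < len(exp):
        if exp[i] < min_expected and len(exp) > 1:
            j = i + 1 if i + 1 < len(exp) else i - 1
            lo_, hi_ = min(i, j), max(i, j)
            obs[lo_] += obs[hi_]; exp[lo_] += exp[hi_]
            for e in ext:
                e[lo_] = e[lo_] or e[hi_]
            del obs[hi_]; del exp[hi_]
            for e in ext:
                del e[hi_]
            merged = True
            i = 0
        else:
            i += 1
    out = (np.array(obs), np.array(exp), merged)
    return out + tuple(np.array(e) for e in ext) if ext else out


def mcds_gof(coded: pd.DataFrame, fit: TPNFit, n_bins: int | None = None,
             edges: np.ndarray | None = None,
             n_params: int | None = None) -> GofReport:
    """Chi-square, Kolmogorov-Smirnov, and QQ goodness of fit for the
    distance model.

    ``n_params`` overrides the degrees-of-freedom correction (pass 0 when
    assessing a fully specified model that was not fitted to these data).
    The default correction ``bins - 1 - n_params`` follows the convention
    for ML-fitted models; note the resulting test is mildly anticonservative
    (the true null distribution lies between chi2 with and without the
    parameter correction when parameters are estimated by ML rather than
    from the grouped counts).
    """
    x = np.asarray(coded["distance"], dtype=float)
    n = x.size
    if n_bins is None:
        n_bins = max(4, int(round(np.sqrt(n))))
    if edges is None:
        edges = _quantile_edges(x, n_bins, fit.w_b, fit.w)
    edges = np.asarray(edges, dtype=float)
    if n < len(edges) - 1:
        raise FitError("fewer observations than bins")

    den = tpn_partial_integral(coded, fit.params, fit.w_b, np.full(n, fit.w))
    cdf_at = [tpn_partial_integral(coded, fit.params, fit.w_b, np.full(n, e)) / den
              for e in edges]
    expected = np.array([np.sum(cdf_at[b + 1] - cdf_at[b]) for b in range(len(edges) - 1)])
    observed = np.histogram(x, bins=edges)[0].astype(float)
    has_apex = [(edges[b] <= fit.mu < edges[b + 1]) for b in range(len(edges) - 1)]

    observed, expected, merged, has_apex = _merge_small(observed, expected, [has_apex])
    contrib = (observed - expected) ** 2 / expected
    chi2 = float(contrib.sum())
    k = fit.n_params if n_params is None else n_params
    df = max(int(len(observed) - 1 - k), 1)
    p = float(stats.chi2.sf(chi2, df))

    u = np.sort(_pit(coded, fit))
    ks = stats.kstest(u, "uniform")
    qq = np.column_stack([(np.arange(1, n + 1) - 0.5) / n, u])
    apex = float(contrib[np.argmax(has_apex)]) if np.any(has_apex) else None
    return GofReport(chi2=chi2, df=df, p_value=p, ks_stat=float(ks.statistic),
                     ks_p=float(ks.pvalue), qq=qq, apex_bin_chi2=apex,
                     n_bins=len(observed), contributions=contrib, rebinned=merged)


def mr_gof(coded: pd.DataFrame, fit: MRFit, n_bins: int | None = None,
           edges: np.ndarray | None = None,
           n_params: int | None = None) -> GofReport:
    """Chi-square GOF for the mark-resight model over history x distance-bin
    cells; per-bin totals are fixed, so df = 2*bins - n_params."""
    x = np.asarray(coded["distance"], dtype=float)
    n = x.size
    if n_bins is None:
        n_bins = max(3, int(round(0.75 * np.sqrt(n))))
    if edges is None:
        edges = _quantile_edges(x, n_bins, x.min(), x.max() + 1e-9)
    edges = np.asarray(edges, dtype=float)
    bin_of = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(edges) - 2)

    pp, pb, pboth = history_probs(coded, fit.params)
    probs = np.column_stack([pp, pb, pboth])
    hist_idx = coded["history"].map({"pilot": 0, "backseat": 1, "both": 2}).to_numpy()

    B = len(edges) - 1
    observed = np.zeros((B, 3))
    expected = np.zeros((B, 3))
    for b in range(B):
        sel = bin_of == b
        for h in range(3):
            observed[b, h] = np.sum(hist_idx[sel] == h)
            expected[b, h] = probs[sel, h].sum()

    # merge adjacent distance bins until all 3 cells have expected >= 1
    merged = False
    b = 0
    while b < expected.shape[0]:
        if expected.shape[0] > 1 and expected[b].min() < 1.0:
            j = b + 1 if b + 1 < expected.shape[0] else b - 1
            lo_, hi_ = min(b, j), max(b, j)
            expected[lo_] += expected[hi_]
            observed[lo_] += observed[hi_]
            expected = np.delete(expected, hi_, axis=0)
            observed = np.delete(observed, hi_, axis=0)
            merged = True
            b = 0
        else:
            b += 1

    contrib = (observed - expected) ** 2 / expected
    chi2 = float(contrib.sum())
    k = fit.n_params if n_params is None else n_params
    df = max(int(2 * expected.shape[0] - k), 1)
    p = float(stats.chi2.sf(chi2, df))
    return GofReport(chi2=chi2, df=df, p_value=p, n_bins=expected.shape[0],
                     contributions=contrib.ravel(), rebinned=merged)


# ---------------------------------------------------------------------------
# pooled vs stratified comparison

def _aic(x) -> float:
    return float(x.aic) if hasattr(x, "aic") else float(x)


def compare_pooled(fit_a, fit_b, fit_pooled, n_a: int | None = None,
                   n_b: int | None = None, n_pooled: int | None = None):
    """Compare one pooled model against two stratum-specific models.

    Because the strata partition the pooled data (exhaustive and mutually
    exclusive), the stratum AICs add; the pooled model is superior when
    dAIC = AIC_pooled - (AIC_a + AIC_b) < 0.  Accepts fitted models or bare
    AIC values; optional sample sizes enable the partition check.
    """
    if n_a is not None and n_b is not None and n_pooled is not None:
        if n_a + n_b != n_pooled:
            raise ValueError(f"strata do not partition the pooled data: {n_a} + {n_b} != {n_pooled}")
    d_aic = _aic(fit_pooled) - (_aic(fit_a) + _aic(fit_b))
    return d_aic, ("pooled" if d_aic < 0 else "separate")
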