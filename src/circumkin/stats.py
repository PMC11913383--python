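"""Mixed-model condition comparisons for kinematic records.

Fits, per kinematic metric, the linear mixed-effects model

    metric ~ condition + (1 | plant)

by REML (condition treatment-coded, US as reference), and derives:

* type-III Wald χ² tests of the intercept and the 3-df condition term,
* Nakagawa–Schielzeth marginal and conditional R²,
* all six pairwise contrasts of the estimated marginal condition means,
  with Satterthwaite (default) or Kenward–Roger-adjusted denominator
  degrees of freedom and Tukey multiplicity adjustment over the
  six-contrast family.

The REML fit itself is delegated to statsmodels' MixedLM; the Wald table,
R² decomposition, degrees-of-freedom approximations and contrasts are
computed here from the estimated variance components and design matrix.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "LMMFit",
    "fit_lmm",
    "wald_type3",
    "r2_nakagawa",
    "pairwise_contrasts",
    "ALPHA",
]

#: Significance threshold used throughout the analysis.
ALPHA = 0.05


@dataclass
class LMMFit:
    """A fitted random-intercept model for one kinematic response."""

    response: str
    levels: list[str]  # condition levels, reference first
    beta: pd.Series  # fixed effects: intercept + treatment dummies
    cov_beta: np.ndarray  # GLS covariance of the fixed effects
    sigma2_plant: float  # random-intercept variance
    sigma2_resid: float  # residual variance
    n_obs: int
    n_plants: int
    singular: bool  # random-intercept variance at (or near) zero
    converged: bool
    X: np.ndarray = field(repr=False)  # design matrix (n × p)
    groups: np.ndarray = field(repr=False)  # plant label per row
    y: np.ndarray = field(repr=False, default=None)  # response vector

    def __post_init__(self) -> None:
        if self.sigma2_plant < 0 or self.sigma2_resid < 0:
            raise ValueError("variance components must be non-negative")
        if not np.allclose(self.cov_beta, self.cov_beta.T, atol=1e-8):
            raise ValueError("coefficient covariance must be symmetric")

    def emmeans(self) -> pd.Series:
        """Model-based (estimated marginal) mean per condition level."""
        means = {}
        for lv in self.levels:
            c = self._mean_vector(lv)
            means[lv] = float(c @ self.beta.to_numpy())
        return pd.Series(means)

    def _mean_vector(self, level: str) -> np.ndarray:
        c = np.zeros(len(self.beta))
        c[0] = 1.0
        if level != self.levels[0]:
            c[1 + self.levels[1:].index(level)] = 1.0
        return c


def _design(records: pd.DataFrame, response: str, reference: str = "US"):
    levels = sorted(records["condition"].unique())
    if reference in levels:
        levels = [reference] + [l for l in levels if l != reference]
    n = len(records)
    X = np.ones((n, len(levels)))
    for j, lv in enumerate(levels[1:], start=1):
        X[:, j] = (records["condition"] == lv).astype(float)
    return X, levels


def fit_lmm(records: pd.DataFrame, response: str, reml: bool = True) -> LMMFit:
    """REML fit of ``response ~ condition + (1 | plant_id)``.

    A boundary fit (plant variance estimated at zero) is returned with
    ``singular=True`` rather than raised.
    """
    from statsmodels.regression.mixed_linear_model import MixedLM

    for col in ("plant_id", "condition", response):
        if col not in records.columns:
            raise ValueError(f"records table lacks column {col!r}")
    data = records.dropna(subset=[response, "plant_id", "condition"])
    if data["condition"].nunique() < 2:
        raise ValueError("need at least 2 conditions")
    if data["plant_id"].nunique() < 2:
        raise ValueError("need at least 2 plants")

    X, levels = _design(data, response)
    y = data[response].to_numpy(dtype=float)
    groups = data["plant_id"].to_numpy()

    model = MixedLM(y, X, groups=groups)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            result = model.fit(reml=reml)
        except np.linalg.LinAlgError:
            result = model.fit(reml=reml, method="powell")
    converged = bool(result.converged)
    s2_plant = float(np.asarray(result.cov_re)[0, 0])
    s2_resid = float(result.scale)
    singular = s2_plant <= 1e-10 * max(s2_resid, 1.0) or any(
        "singular" in str(w.message).lower() for w in caught
    )
    s2_plant = max(s2_plant, 0.0)

    beta = pd.Series(np.asarray(result.fe_params, dtype=float), index=_coef_names(levels))
    cov_beta = _gls_cov(X, groups, s2_plant, s2_resid)
    return LMMFit(
        response=response,
        levels=levels,
        beta=beta,
        cov_beta=cov_beta,
        sigma2_plant=s2_plant,
        sigma2_resid=s2_resid,
        n_obs=len(y),
        n_plants=int(pd.unique(groups).size),
        singular=singular,
        converged=converged,
        X=X,
        groups=groups,
        y=y,
    )


def _coef_names(levels: list[str]) -> list[str]:
    return ["(Intercept)"] + [f"condition[{lv}]" for lv in levels[1:]]


def _block_V(groups: np.ndarray, s2_plant: float, s2_resid: float) -> np.ndarray:
    """Marginal covariance V = σ²_plant·ZZᵀ + σ²_resid·I (dense; n is small)."""
    Z = _group_indicator(groups)
    return s2_plant * (Z @ Z.T) + s2_resid * np.eye(len(groups))


def _group_indicator(groups: np.ndarray) -> np.ndarray:
    labels, inv = np.unique(groups, return_inverse=True)
    Z = np.zeros((len(groups), len(labels)))
    Z[np.arange(len(groups)), inv] = 1.0
    return Z


def _gls_cov(X: np.ndarray, groups: np.ndarray, s2_plant: float, s2_resid: float) -> np.ndarray:
    V = _block_V(groups, s2_plant, s2_resid)
    Vinv = np.linalg.inv(V)
    return np.linalg.inv(X.T @ Vinv @ X)


def wald_type3(fit: LMMFit) -> pd.DataFrame:
    """Type-III Wald χ² tests plus Nakagawa R², one row per model term.

    The condition term tests all treatment dummies jointly (3 df for four
    levels); with treatment coding in the balanced case this is invariant
    to the factor coding.
    """
    if len(fit.levels) < 2:
        raise ValueError("condition term not estimable with a single level")
    b = fit.beta.to_numpy()
    C = fit.cov_beta
    rows = []
    # intercept (reference-level mean)
    chi2_int = b[0] ** 2 / C[0, 0]
    rows.append(("(Intercept)", chi2_int, 1, sps.chi2.sf(chi2_int, 1)))
    idx = np.arange(1, len(b))
    sub = C[np.ix_(idx, idx)]
    try:
        chi2_cond = float(b[idx] @ np.linalg.solve(sub, b[idx]))
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("singular coefficient covariance") from err
    rows.append(("Condition", chi2_cond, len(idx), sps.chi2.sf(chi2_cond, len(idx))))
    r2m, r2c = r2_nakagawa(fit)
    out = pd.DataFrame(rows, columns=["term", "chisq", "df", "p"])
    out["R2m"] = r2m
    out["R2c"] = r2c
    return out


def r2_nakagawa(fit: LMMFit) -> tuple[float, float]:
    """Nakagawa–Schielzeth marginal and conditional R².

    marginal = varF / (varF + varPlant + varResid);
    conditional = (varF + varPlant) / (same denominator), with varF the
    variance of the fixed-effect fitted values.
    """
    fitted = fit.X @ fit.beta.to_numpy()
    var_f = float(np.var(fitted, ddof=1))
    denom = var_f + fit.sigma2_plant + fit.sigma2_resid
    if denom <= 0:
        raise ValueError("all variance components are zero")
    return var_f / denom, (var_f + fit.sigma2_plant) / denom


def _reml_loglik(y: np.ndarray, X: np.ndarray, Vj: list[np.ndarray], theta: np.ndarray) -> float:
    """Restricted log-likelihood at variance components θ (up to a constant)."""
    V = theta[0] * Vj[0] + theta[1] * Vj[1]
    sign, logdetV = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    Vinv = np.linalg.inv(V)
    M = X.T @ Vinv @ X
    signM, logdetM = np.linalg.slogdet(M)
    if signM <= 0:
        return -np.inf
    beta = np.linalg.solve(M, X.T @ Vinv @ y)
    r = y - X @ beta
    return -0.5 * (logdetV + logdetM + float(r @ Vinv @ r))


def _numeric_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian with relative steps."""
    k = len(x)
    h = rel_step * np.maximum(np.abs(x), 1e-8)
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            if i == j:
                fp = f(x + h[i] * _unit(k, i))
                fm = f(x - h[i] * _unit(k, i))
                H[i, i] = (fp - 2.0 * f(x) + fm) / h[i] ** 2
            else:
                e_i, e_j = _unit(k, i), _unit(k, j)
                fpp = f(x + h[i] * e_i + h[j] * e_j)
                fpm = f(x + h[i] * e_i - h[j] * e_j)
                fmp = f(x - h[i] * e_i + h[j] * e_j)
                fmm = f(x - h[i] * e_i - h[j] * e_j)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def _unit(k: int, i: int) -> np.ndarray:
    e = np.zeros(k)
    e[i] = 1.0
    return e


class _DfMachinery:
    """Shared pieces for Satterthwaite / Kenward–Roger df computations.

    For the random-intercept model, V(θ) = θ₁·ZZᵀ + θ₂·I is linear in
    θ = (σ²_plant, σ²_resid); W is the asymptotic covariance of θ̂, taken
    as the inverse of the observed information (negative Hessian of the
    restricted log-likelihood at the REML estimate, by central
    differences), falling back to the expected information
    I_jk = ½·tr(P·V_j·P·V_k) when the observed Hessian is not positive
    definite (e.g. boundary fits).
    """

    def __init__(self, fit: LMMFit):
        X, groups = fit.X, fit.groups
        n = len(groups)
        Z = _group_indicator(groups)
        self.Vj = [Z @ Z.T, np.eye(n)]
        V = fit.sigma2_plant * self.Vj[0] + fit.sigma2_resid * self.Vj[1]
        self.Vinv = np.linalg.inv(V)
        self.X = X
        M = X.T @ self.Vinv @ X
        self.Phi = np.linalg.inv(M)
        VinvX = self.Vinv @ X
        self.P = self.Vinv - VinvX @ self.Phi @ VinvX.T
        # P_j = Xᵀ V⁻¹ V_j V⁻¹ X  (= −∂(XᵀV⁻¹X)/∂θ_j)
        self.Pj = [VinvX.T @ self.Vj[j] @ VinvX for j in range(2)]
        self.VinvX = VinvX
        self.W = self._varpar_cov(fit)

    def _expected_info(self) -> np.ndarray:
        info = np.zeros((2, 2))
        for j in range(2):
            for k in range(2):
                info[j, k] = 0.5 * np.trace(self.P @ self.Vj[j] @ self.P @ self.Vj[k])
        return info

    def _varpar_cov(self, fit: LMMFit) -> np.ndarray:
        theta = np.array([fit.sigma2_plant, fit.sigma2_resid])
        if fit.y is not None and theta[0] > 0 and theta[1] > 0:
            try:
                H = _numeric_hessian(
                    lambda th: _reml_loglik(fit.y, self.X, self.Vj, th), theta
                )
                W = np.linalg.inv(-H)
                if np.all(np.linalg.eigvalsh(W) > 0):
                    return W
            except np.linalg.LinAlgError:
                pass
        return np.linalg.pinv(self._expected_info())

    def satterthwaite_df(self, c: np.ndarray, Phi: np.ndarray | None = None) -> float:
        Phi = self.Phi if Phi is None else Phi
        g = float(c @ Phi @ c)
        grad = np.array([float(c @ Phi @ self.Pj[j] @ Phi @ c) for j in range(2)])
        denom = float(grad @ self.W @ grad)
        if denom <= 0:
            return float(len(self.X) - self.Phi.shape[0])
        return 2.0 * g * g / denom

    def kr_adjusted_cov(self) -> np.ndarray:
        """Kenward–Roger small-sample adjusted covariance of β̂ (the
        variance structure is linear in θ, so second-derivative terms
        vanish)."""
        Q = {}
        for j in range(2):
            for k in range(2):
                Q[j, k] = (
                    self.VinvX.T @ self.Vj[j] @ self.Vinv @ self.Vj[k] @ self.VinvX
                )
        inner = np.zeros_like(self.Phi)
        for j in range(2):
            for k in range(2):
                inner += self.W[j, k] * (Q[j, k] - self.Pj[j] @ self.Phi @ self.Pj[k])
        return self.Phi + 2.0 * self.Phi @ inner @ self.Phi


def pairwise_contrasts(
    fit: LMMFit,
    df_method: str = "satterthwaite",
    adjust: str = "tukey",
) -> pd.DataFrame:
    """All pairwise differences of the estimated marginal condition means.

    Standard errors come from the GLS coefficient covariance (Kenward–Roger
    uses the small-sample adjusted covariance), degrees of freedom from the
    chosen approximation, and p-values from the t distribution, Tukey
    (studentized-range) adjusted over the six-contrast family by default.
    """
    if df_method not in {"satterthwaite", "kenward_roger"}:
        raise ValueError(f"unknown df_method {df_method!r}")
    if adjust not in {"tukey", "none"}:
        raise ValueError(f"unknown adjustment {adjust!r}")
    if len(fit.levels) < 2:
        raise ValueError("need at least 2 condition levels")

    mach = _DfMachinery(fit)
    Phi = mach.kr_adjusted_cov() if df_method == "kenward_roger" else mach.Phi
    beta = fit.beta.to_numpy()
    k = len(fit.levels)
    rows = []
    for a, b in itertools.combinations(fit.levels, 2):
        c = fit._mean_vector(a) - fit._mean_vector(b)
        est = float(c @ beta)
        se = float(np.sqrt(c @ Phi @ c))
        df = mach.satterthwaite_df(c, Phi=Phi)
        t = est / se
        if adjust == "tukey":
            p = float(sps.studentized_range.sf(abs(t) * np.sqrt(2.0), k, df))
        else:
            p = float(2.0 * sps.t.sf(abs(t), df))
        rows.append((f"{a} - {b}", est, se, df, t, p))
    return pd.DataFrame(rows, columns=["contrast", "estimate", "SE", "df", "t", "p_adj"])
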