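"""Quantal (dichotomous) concentration-response models and benchmark concentrations.

Well-level differentiation outcomes are binary (an embryoid body either
contains contracting cardiomyocytes or it does not), so per-concentration
counts of affected wells are modelled with the standard suite of quantal
dose-response forms fit by binomial maximum likelihood:

    logistic        p(d) = 1 / (1 + exp(-(a + b d)))
    probit          p(d) = Phi(a + b d)
    log-logistic    p(d) = g + (1-g) / (1 + exp(-(a + b ln d)))
    log-probit      p(d) = g + (1-g) Phi(a + b ln d)
    Weibull         p(d) = g + (1-g) (1 - exp(-b d^a))
    gamma           p(d) = g + (1-g) GammaCDF(b d; alpha)
    quantal-linear  p(d) = g + (1-g) (1 - exp(-b d))
    multistage      p(d) = g + (1-g) (1 - exp(-sum_i beta_i d^i))

g is the background response, b > 0 a slope/rate, a (or alpha) a shape
or intercept.  The log-dose models return g at d = 0 by definition.

The benchmark concentration BMC is the concentration producing a given
benchmark response (BMR) in *extra risk*,

    (p(d) - p(0)) / (1 - p(0)) = BMR,

solved in closed form where one exists and otherwise by bracketed root
search.  With BMR = 0.5 and a near-zero background this is the
concentration halving the fraction of differentiating embryoid bodies
relative to control (BMC_d50).  A fit is accepted when the Pearson
chi-square goodness-of-fit p-value is at least ``p_min`` and no scaled
residual exceeds ``residual_max`` in magnitude; the reported BMC_d50 is
the lowest BMC among accepted models, following benchmark-dose practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator

__all__ = [
    "MODEL_NAMES",
    "DRModelSpec",
    "QuantalDataset",
    "FitResult",
    "GofReport",
    "BMCEstimate",
    "model_response",
    "binomial_loglik",
    "fit_model",
    "bmc_from_fit",
    "goodness_of_fit",
    "fit_all_models",
    "select_bmc",
    "QuantalDoseResponse",
    "BenchmarkDoseSelector",
]

MODEL_NAMES = (
    "gamma",
    "logistic",
    "loglogistic",
    "probit",
    "logprobit",
    "multistage",
    "weibull",
    "quantal_linear",
)

_P_EPS = 1e-9  # probability clamp for the log likelihood


@dataclass(frozen=True)
class DRModelSpec:
    """A quantal model choice: name, polynomial degree (multistage only),
    and whether shape/slope parameters are restricted (>= 1)."""

    name: str
    degree: int | None = None
    restricted: bool = True

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; choose from {MODEL_NAMES}")
        if self.name == "multistage":
            if self.degree is None or self.degree < 1:
                raise ValueError("multistage needs degree >= 1")
        elif self.degree is not None:
            raise ValueError("degree applies to the multistage model only")


@dataclass
class QuantalDataset:
    """Per-concentration affected-well counts for one compound.

    ``affected`` counts non-differentiating (non-contracting) wells, so
    the response increases with concentration.  Must include a
    zero-concentration (solvent control) group; concentrations are
    stored sorted and must be distinct.
    """

    compound_id: str
    concentrations_um: np.ndarray
    n_wells: np.ndarray
    affected: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.concentrations_um, dtype=float)
        n = np.asarray(self.n_wells, dtype=int)
        y = np.asarray(self.affected, dtype=int)
        if not (d.size == n.size == y.size) or d.size == 0:
            raise ValueError("concentrations, n and affected must be equal-length, non-empty")
        if np.any(d < 0):
            raise ValueError("concentrations must be non-negative")
        if np.unique(d).size != d.size:
            raise ValueError("concentrations must be distinct")
        if np.any(y < 0) or np.any(y > n):
            raise ValueError("affected counts must satisfy 0 <= affected <= n")
        if not np.any(d == 0):
            raise ValueError("a zero-concentration (solvent control) group is required")
        order = np.argsort(d)
        self.concentrations_um = d[order]
        self.n_wells = n[order]
        self.affected = y[order]

    @property
    def n_groups(self) -> int:
        return int(self.concentrations_um.size)

    @property
    def max_dose(self) -> float:
        return float(self.concentrations_um.max())


# ---------------------------------------------------------------------------
# model forms

def _poly(betas: np.ndarray, d: np.ndarray) -> np.ndarray:
    out = np.zeros_like(d)
    for i, b in enumerate(betas, start=1):
        out = out + b * d**i
    return out


def _response(name: str, params: np.ndarray, d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if name == "logistic":
        a, b = params
        return special.expit(a + b * d)
    if name == "probit":
        a, b = params
        return special.ndtr(a + b * d)
    if name in ("loglogistic", "logprobit"):
        g, a, b = params
        out = np.full(d.shape, g, dtype=float)
        pos = d > 0
        z = a + b * np.log(d[pos])
        core = special.expit(z) if name == "loglogistic" else special.ndtr(z)
        out[pos] = g + (1.0 - g) * core
        return out
    if name == "weibull":
        g, a, b = params
        return g + (1.0 - g) * -np.expm1(-b * np.where(d > 0, d, 0.0) ** a)
    if name == "gamma":
        g, alpha, b = params
        return g + (1.0 - g) * special.gammainc(alpha, b * d)
    if name == "quantal_linear":
        g, b = params
        return g + (1.0 - g) * -np.expm1(-b * d)
    if name == "multistage":
        g = params[0]
        return g + (1.0 - g) * -np.expm1(-_poly(params[1:], d))
    raise ValueError(f"unknown model {name!r}")


def _param_names(spec: DRModelSpec) -> list[str]:
    if spec.name in ("logistic", "probit"):
        return ["a", "b"]
    if spec.name == "quantal_linear":
        return ["g", "b"]
    if spec.name == "multistage":
        return ["g"] + [f"beta{i}" for i in range(1, spec.degree + 1)]
    if spec.name == "gamma":
        return ["g", "alpha", "b"]
    return ["g", "a", "b"]  # loglogistic, logprobit, weibull


_G_BOUNDS = (0.0, 0.99)
_SHAPE_HI = 18.0  # conventional upper bound on power/shape parameters
_SLOPE_HI = 1e4
_INTERCEPT_BOUNDS = (-50.0, 50.0)


def _bounds(spec: DRModelSpec) -> list[tuple[float, float]]:
    lo_shape = 1.0 if spec.restricted else 1e-8
    if spec.name in ("logistic", "probit"):
        return [_INTERCEPT_BOUNDS, (1e-8, 100.0)]
    if spec.name == "quantal_linear":
        return [_G_BOUNDS, (1e-8, _SLOPE_HI)]
    if spec.name == "multistage":
        return [_G_BOUNDS] + [(0.0, _SLOPE_HI)] * spec.degree
    if spec.name in ("loglogistic", "logprobit"):
        return [_G_BOUNDS, _INTERCEPT_BOUNDS, (lo_shape, _SHAPE_HI)]
    if spec.name == "weibull":
        return [_G_BOUNDS, (lo_shape, _SHAPE_HI), (1e-8, _SLOPE_HI)]
    if spec.name == "gamma":
        return [_G_BOUNDS, (lo_shape if spec.restricted else 0.2, _SHAPE_HI), (1e-8, _SLOPE_HI)]
    raise ValueError(spec.name)


def model_response(spec: DRModelSpec, params, concentration) -> np.ndarray | float:
    """Probability of an affected well at the given concentration(s)."""
    params = np.asarray(params, dtype=float)
    for v, (lo, hi) in zip(params, _bounds(spec)):
        if not (lo - 1e-12 <= v <= hi + 1e-12):
            raise ValueError(
                f"parameter value {v} outside bounds [{lo}, {hi}] for {spec.name}"
            )
    d = np.asarray(concentration, dtype=float)
    out = _response(spec.name, params, np.atleast_1d(d))
    return float(out[0]) if d.ndim == 0 else out


@dataclass
class FitResult:
    """Maximum-likelihood fit of one quantal model."""

    spec: DRModelSpec
    params: np.ndarray
    param_names: list[str]
    loglik: float
    converged: bool
    n_params: int
    max_dose: float = np.nan

    def predict(self, d) -> np.ndarray:
        return _response(self.spec.name, self.params, np.atleast_1d(np.asarray(d, float)))


@dataclass
class GofReport:
    """Pearson chi-square goodness of fit with per-group scaled residuals."""

    chi_square: float
    df: int
    p_value: float
    scaled_residuals: np.ndarray
    accepted: bool
    reason: str = ""


@dataclass
class BMCEstimate:
    """Selected benchmark concentration: the minimum over accepted fits."""

    compound_id: str
    bmc_d50: float
    bmr: float
    risk_type: str
    selected_model: DRModelSpec | None
    all_fits: list[tuple[FitResult, GofReport, float | None]]
    no_accepted_model: bool = False
    warnings: list[str] = field(default_factory=list)


def binomial_loglik(spec: DRModelSpec, params, data: QuantalDataset) -> float:
    """Binomial log likelihood sum y ln p + (n-y) ln(1-p), p clamped to
    [eps, 1-eps] with eps = 1e-9 so degenerate predictions stay finite."""
    p = _response(spec.name, np.asarray(params, float), data.concentrations_um)
    p = np.clip(p, _P_EPS, 1.0 - _P_EPS)
    y = data.affected
    n = data.n_wells
    return float(np.sum(y * np.log(p) + (n - y) * np.log1p(-p)))


# ---------------------------------------------------------------------------
# fitting

def _heuristic_start(spec: DRModelSpec, data: QuantalDataset) -> np.ndarray:
    """Data-driven initial parameters: empirical background plus a
    regression-based slope/intercept on the transformed response scale."""
    d = data.concentrations_um
    frac = (data.affected + 0.5) / (data.n_wells + 1.0)  # shrunk proportions
    ctrl = d == 0
    g0 = float(np.clip(frac[ctrl].mean(), 1e-3, 0.9)) if ctrl.any() else 1e-3
    pos = d > 0
    dp = d[pos]
    # background-adjusted response for the threshold models
    adj = np.clip((frac[pos] - g0) / (1.0 - g0), 0.01, 0.99)
    lo, hi = zip(*_bounds(spec))

    def clipped(vals):
        return np.clip(np.asarray(vals, float), np.asarray(lo) + 1e-8, np.asarray(hi) - 1e-8)

    if spec.name in ("logistic", "probit"):
        z = special.logit(np.clip(frac[pos], 0.01, 0.99))
        if spec.name == "probit":
            z = special.ndtri(np.clip(frac[pos], 0.01, 0.99))
        A = np.vstack([np.ones_like(dp), dp]).T
        coef, *_ = np.linalg.lstsq(A, z, rcond=None)
        return clipped([coef[0], max(coef[1], 1e-3)])
    if spec.name in ("loglogistic", "logprobit"):
        z = special.logit(adj) if spec.name == "loglogistic" else special.ndtri(adj)
        A = np.vstack([np.ones_like(dp), np.log(dp)]).T
        coef, *_ = np.linalg.lstsq(A, z, rcond=None)
        return clipped([g0, coef[0], max(coef[1], 1.01)])
    # cumulative-hazard scale for the exponential-family forms
    h = -np.log1p(-adj)
    if spec.name == "quantal_linear":
        b = float(np.sum(dp * h) / np.sum(dp**2))
        return clipped([g0, max(b, 1e-6)])
    if spec.name == "multistage":
        b1 = float(np.sum(dp * h) / np.sum(dp**2))
        start = [g0, max(b1, 1e-6)] + [1e-6] * (spec.degree - 1)
        return clipped(start)
    # weibull / gamma: regress ln h on ln d for power and rate
    A = np.vstack([np.ones_like(dp), np.log(dp)]).T
    coef, *_ = np.linalg.lstsq(A, np.log(np.maximum(h, 1e-6)), rcond=None)
    power = max(coef[1], 1.01)
    rate = float(np.exp(coef[0]))
    if spec.name == "weibull":
        return clipped([g0, power, max(rate, 1e-6)])
    # gamma: shape ~ power heuristic, rate matched at the median dose
    dmed = float(np.median(dp))
    return clipped([g0, power, max(1.0 / max(dmed, 1e-6), 1e-6)])


def fit_model(
    spec: DRModelSpec,
    data: QuantalDataset,
    n_starts: int = 8,
    random_state: int = 0,
) -> FitResult:
    """Fit one quantal model by multi-start bounded maximum likelihood.

    Starts are the data-driven heuristic initializer plus seeded
    log-normal perturbations of it and uniform draws within bounds;
    each start is optimized with L-BFGS-B.  Never raises on optimizer
    failure: if all starts fail the result carries ``converged=False``.
    """
    if data.n_groups < 3:
        raise ValueError("need at least 3 concentration groups to fit")
    if not np.any(data.concentrations_um > 0):
        raise ValueError("need at least one non-control group")
    bounds = _bounds(spec)
    rng = np.random.default_rng(random_state)
    starts = []
    try:
        h = _heuristic_start(spec, data)
        starts.append(h)
    except Exception:  # pragma: no cover - heuristic should not fail
        h = None
    k = len(bounds)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    # perturbations of the heuristic; cap the uniform draws to a sane range
    hi_draw = np.minimum(hi, 100.0)
    while len(starts) < n_starts:
        if h is not None and len(starts) < max(2, n_starts // 2):
            cand = np.clip(h * rng.lognormal(0.0, 0.5, size=k), lo + 1e-8, hi - 1e-8)
        else:
            cand = lo + (hi_draw - lo) * rng.uniform(0.05, 0.95, size=k)
        starts.append(cand)

    def nll(theta: np.ndarray) -> float:
        ll = binomial_loglik(spec, theta, data)
        return -ll if np.isfinite(ll) else 1e12

    best = None
    for x0 in starts:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    converged = best is not None and np.isfinite(best.fun) and best.fun < 1e11
    params = np.clip(best.x, lo, hi) if best is not None else np.full(k, np.nan)
    return FitResult(
        spec=spec,
        params=params,
        param_names=_param_names(spec),
        loglik=-float(best.fun) if best is not None else np.nan,
        converged=bool(converged),
        n_params=k,
        max_dose=data.max_dose,
    )


# ---------------------------------------------------------------------------
# benchmark concentration

def _bmc_closed_form(spec: DRModelSpec, params: np.ndarray, bmr: float) -> float | None:
    """Closed-form extra-risk BMC where one exists; None for multistage."""
    if spec.name == "quantal_linear":
        g, b = params
        return -np.log1p(-bmr) / b
    if spec.name == "weibull":
        g, a, b = params
        return (-np.log1p(-bmr) / b) ** (1.0 / a)
    if spec.name == "gamma":
        g, alpha, b = params
        return special.gammaincinv(alpha, bmr) / b
    if spec.name == "loglogistic":
        g, a, b = params
        return float(np.exp((special.logit(bmr) - a) / b))
    if spec.name == "logprobit":
        g, a, b = params
        return float(np.exp((special.ndtri(bmr) - a) / b))
    if spec.name == "logistic":
        a, b = params
        p0 = special.expit(a)
        target = p0 + bmr * (1.0 - p0)
        return float((special.logit(target) - a) / b)
    if spec.name == "probit":
        a, b = params
        p0 = special.ndtr(a)
        target = p0 + bmr * (1.0 - p0)
        return float((special.ndtri(target) - a) / b)
    return None


def bmc_from_fit(
    fit: FitResult,
    bmr: float = 0.5,
    risk_type: str = "extra",
    method: str = "auto",
    max_dose: float | None = None,
) -> float:
    """Concentration at which extra risk reaches ``bmr``.

    ``method`` "auto" uses the closed form where available, otherwise a
    bracketed root search on (0, 10 x max dose] with relative tolerance
    1e-8; "root" forces the root search (used to cross-check the closed
    forms).
    """
    if risk_type != "extra":
        raise ValueError("only extra risk is supported")
    if not 0 < bmr < 1:
        raise ValueError("bmr must be in (0, 1)")
    if not fit.converged:
        raise ValueError("cannot derive a BMC from a non-converged fit")
    if method == "auto":
        closed = _bmc_closed_form(fit.spec, fit.params, bmr)
        if closed is not None:
            return float(closed)
    dmax = max_dose if max_dose is not None else fit.max_dose
    if not np.isfinite(dmax) or dmax <= 0:
        raise ValueError("root search needs a positive max dose")
    p0 = float(fit.predict(0.0)[0])

    def extra(d: float) -> float:
        p = float(fit.predict(d)[0])
        return (p - p0) / (1.0 - p0) - bmr

    hi = 10.0 * dmax
    if extra(hi) < 0:
        raise ValueError("BMC beyond tested range (no root in (0, 10 x max dose])")
    lo = 1e-12 * dmax
    while extra(lo) > 0:  # pathological: response jumps immediately
        lo *= 1e-2
        if lo < 1e-300:
            raise ValueError("BMC not bracketable near zero")
    return float(optimize.brentq(extra, lo, hi, rtol=1e-10, xtol=1e-300))


def goodness_of_fit(
    fit: FitResult,
    data: QuantalDataset,
    p_min: float = 0.1,
    residual_max: float = 2.0,
) -> GofReport:
    """Pearson chi-square GOF with scaled residuals (y - n p)/sqrt(n p (1-p)).

    Accepted iff p >= ``p_min`` and max |scaled residual| <= ``residual_max``.
    With df = groups - n_params <= 0 the fit is unidentifiable and rejected.
    """
    if not fit.converged:
        return GofReport(np.nan, 0, np.nan, np.full(data.n_groups, np.nan), False, "non-converged")
    p = np.clip(fit.predict(data.concentrations_um), _P_EPS, 1.0 - _P_EPS)
    n = data.n_wells
    y = data.affected
    sd = np.sqrt(n * p * (1.0 - p))
    resid = (y - n * p) / sd
    chi2 = float(np.sum(resid**2))
    df = data.n_groups - fit.n_params
    if df <= 0:
        return GofReport(chi2, df, np.nan, resid, False, "unidentifiable")
    p_value = float(stats.chi2.sf(chi2, df))
    accepted = p_value >= p_min and float(np.max(np.abs(resid))) <= residual_max
    reason = "" if accepted else (
        f"p={p_value:.3f} < {p_min}" if p_value < p_min else
        f"max |scaled residual| {np.max(np.abs(resid)):.2f} > {residual_max}"
    )
    return GofReport(chi2, df, p_value, resid, accepted, reason)


def _default_degree(data: QuantalDataset, cap: int = 3) -> int:
    return max(1, min(data.n_groups - 2, cap))


def fit_all_models(
    data: QuantalDataset,
    bmr: float = 0.5,
    p_min: float = 0.1,
    residual_max: float = 2.0,
    restricted: bool = True,
    multistage_degree: int | None = None,
    n_starts: int = 8,
    random_state: int = 0,
) -> list[tuple[FitResult, GofReport, float | None]]:
    """Fit the full eight-model suite and evaluate GOF and BMC for each."""
    out = []
    for name in MODEL_NAMES:
        degree = (
            multistage_degree if multistage_degree is not None else _default_degree(data)
        ) if name == "multistage" else None
        spec = DRModelSpec(name, degree=degree, restricted=restricted)
        fit = fit_model(spec, data, n_starts=n_starts, random_state=random_state)
        gof = goodness_of_fit(fit, data, p_min=p_min, residual_max=residual_max)
        bmc: float | None
        try:
            bmc = bmc_from_fit(fit, bmr=bmr)
        except ValueError:
            bmc = None
        out.append((fit, gof, bmc))
    return out


def select_bmc(
    all_fits: list[tuple[FitResult, GofReport, float | None]],
    compound_id: str = "",
    bmr: float = 0.5,
    risk_type: str = "extra",
) -> BMCEstimate:
    """Lowest BMC among accepted fits.

    Ties in BMC are broken by higher GOF p-value, then fewer parameters.
    With no accepted model the estimate is flagged and carries the BMC of
    the best-p fit for inspection.
    """
    if not all_fits:
        raise ValueError("no fits supplied")
    accepted = [
        (fit, gof, bmc) for fit, gof, bmc in all_fits if gof.accepted and bmc is not None
    ]
    if accepted:
        fit, gof, bmc = min(accepted, key=lambda t: (t[2], -t[1].p_value, t[0].n_params))
        return BMCEstimate(
            compound_id=compound_id,
            bmc_d50=float(bmc),
            bmr=bmr,
            risk_type=risk_type,
            selected_model=fit.spec,
            all_fits=all_fits,
        )
    candidates = [
        (fit, gof, bmc) for fit, gof, bmc in all_fits
        if bmc is not None and np.isfinite(gof.p_value)
    ]
    warn = ["no accepted model; reporting the best-fitting (highest GOF p) candidate"]
    if not candidates:
        return BMCEstimate(compound_id, np.nan, bmr, risk_type, None, all_fits, True, warn)
    fit, gof, bmc = max(candidates, key=lambda t: t[1].p_value)
    return BMCEstimate(
        compound_id=compound_id,
        bmc_d50=float(bmc),
        bmr=bmr,
        risk_type=risk_type,
        selected_model=fit.spec,
        all_fits=all_fits,
        no_accepted_model=True,
        warnings=warn,
    )


# ---------------------------------------------------------------------------
# scikit-learn estimator layer

def _validate_xy(X, y) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        if X.shape[1] != 1:
            raise ValueError("X must be a single column of concentrations")
        X = X[:, 0]
    y = np.asarray(y)
    if y.ndim != 2 or y.shape[1] != 2:
        raise ValueError("y must be an (n_groups, 2) array of [affected, total] counts")
    return X, y[:, 0].astype(int), y[:, 1].astype(int)


class QuantalDoseResponse(BaseEstimator):
    """One quantal dose-response model as a scikit-learn style estimator.

    Parameters
    ----------
    model : str
        One of the eight quantal model names.
    degree : int
        Multistage polynomial degree (ignored for other models).
    restricted : bool
        Constrain shape/power parameters to >= 1 (the restricted forms).
    bmr : float
        Benchmark response, extra risk (default 0.5).
    n_starts, random_state
        Multi-start optimization control.

    After ``fit(X, y)`` with X the concentrations (uM) and y an
    (n_groups, 2) array of [affected, total] well counts, exposes
    ``params_``, ``loglik_``, ``converged_``, ``gof_`` and ``bmc_``
    (NaN when the benchmark response is not reached in range).
    """

    def __init__(
        self,
        model: str = "loglogistic",
        degree: int = 2,
        restricted: bool = True,
        bmr: float = 0.5,
        p_min: float = 0.1,
        residual_max: float = 2.0,
        n_starts: int = 8,
        random_state: int = 0,
    ):
        self.model = model
        self.degree = degree
        self.restricted = restricted
        self.bmr = bmr
        self.p_min = p_min
        self.residual_max = residual_max
        self.n_starts = n_starts
        self.random_state = random_state

    def fit(self, X, y, compound_id: str = ""):
        d, affected, n = _validate_xy(X, y)
        data = QuantalDataset(compound_id or "x", d, n, affected)
        spec = DRModelSpec(
            self.model,
            degree=self.degree if self.model == "multistage" else None,
            restricted=self.restricted,
        )
        fit = fit_model(spec, data, n_starts=self.n_starts, random_state=self.random_state)
        self.spec_ = spec
        self.fit_result_ = fit
        self.params_ = fit.params
        self.param_names_ = fit.param_names
        self.loglik_ = fit.loglik
        self.converged_ = fit.converged
        self.n_params_ = fit.n_params
        self.gof_ = goodness_of_fit(fit, data, self.p_min, self.residual_max)
        try:
            self.bmc_ = bmc_from_fit(fit, bmr=self.bmr)
        except ValueError:
            self.bmc_ = np.nan
        return self

    def predict(self, X) -> np.ndarray:
        """Predicted probability of an affected well at each concentration."""
        if not hasattr(self, "fit_result_"):
            raise AttributeError("estimator is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        return self.fit_result_.predict(X)


class BenchmarkDoseSelector(BaseEstimator):
    """Eight-model benchmark-concentration analysis as one estimator.

    Fits the full quantal suite by binomial maximum likelihood, screens
    each fit with the chi-square/scaled-residual acceptance rule and
    selects the lowest BMC among accepted models.  Fitted attributes:
    ``fits_`` (list of (FitResult, GofReport, bmc)), ``estimate_``
    (BMCEstimate), ``bmc_``, ``selected_model_``, ``no_accepted_model_``.
    """

    def __init__(
        self,
        bmr: float = 0.5,
        p_min: float = 0.1,
        residual_max: float = 2.0,
        restricted: bool = True,
        multistage_degree: int | None = None,
        n_starts: int = 8,
        random_state: int = 0,
    ):
        self.bmr = bmr
        self.p_min = p_min
        self.residual_max = residual_max
        self.restricted = restricted
        self.multistage_degree = multistage_degree
        self.n_starts = n_starts
        self.random_state = random_state

    def fit(self, X, y, compound_id: str = ""):
        d, affected, n = _validate_xy(X, y)
        data = QuantalDataset(compound_id or "x", d, n, affected)
        fits = fit_all_models(
            data,
            bmr=self.bmr,
            p_min=self.p_min,
            residual_max=self.residual_max,
            restricted=self.restricted,
            multistage_degree=self.multistage_degree,
            n_starts=self.n_starts,
            random_state=self.random_state,
        )
        est = select_bmc(fits, compound_id=data.compound_id, bmr=self.bmr)
        self.data_ = data
        self.fits_ = fits
        self.estimate_ = est
        self.bmc_ = est.bmc_d50
        self.selected_model_ = est.selected_model
        self.no_accepted_model_ = est.no_accepted_model
        return self

    def predict(self, X) -> np.ndarray:
        """Affected-well probability under the selected model."""
        if not hasattr(self, "estimate_"):
            raise AttributeError("estimator is not fitted")
        if self.estimate_.selected_model is None:
            raise ValueError("no model available for prediction")
        sel = self.estimate_.selected_model
        fit = next(f for f, _, _ in self.fits_ if f.spec == sel)
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        return fit.predict(X)
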