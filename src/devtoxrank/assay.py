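"""Embryoid-body differentiation scoring and WST-1 cytotoxicity handling.

Murine ES-D3 cells aggregated into embryoid bodies (one per well of a
24-well plate) either differentiate into contracting cardiomyocytes or
do not; a plate is scored by counting contracting wells per test
concentration.  A run is accepted only when the solvent control shows at
least 21 of 24 contracting wells (proportionally scaled for other plate
sizes).  Accepted runs are pooled into per-concentration binomial counts
of *affected* (non-contracting) wells for benchmark-concentration
modelling.

Viability (WST-1 formazan absorbance) is normalized to the solvent
control (100 %) and summarized with a four-parameter logistic curve used
for display and for checking that a benchmark concentration lies in the
non-cytotoxic range — never for deriving the benchmark itself.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

from .quantal import QuantalDataset

__all__ = [
    "DifferentiationRun",
    "ViabilityCurve",
    "accept_differentiation_run",
    "to_quantal",
    "normalize_viability",
    "FourParamLogistic",
    "fit_4pl",
    "cytotoxicity_guard",
]

DEFAULT_WELLS = 24
CONTROL_MIN_FRACTION = 21 / 24  # minimum contracting fraction in the solvent control


@dataclass
class DifferentiationRun:
    """One independent differentiation experiment for one compound."""

    compound_id: str
    experiment_id: str
    concentrations_um: np.ndarray
    wells_total: np.ndarray
    wells_contracting: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.concentrations_um, dtype=float)
        n = np.asarray(self.wells_total, dtype=int)
        c = np.asarray(self.wells_contracting, dtype=int)
        if not (d.size == n.size == c.size) or d.size == 0:
            raise ValueError("concentration/wells arrays must be equal-length, non-empty")
        if np.any(c < 0) or np.any(c > n):
            raise ValueError("0 <= wells_contracting <= wells_total violated")
        if np.any(d < 0):
            raise ValueError("concentrations must be non-negative")
        self.concentrations_um, self.wells_total, self.wells_contracting = d, n, c

    def control_counts(self) -> tuple[int, int]:
        ctrl = self.concentrations_um == 0
        if not ctrl.any():
            raise ValueError(
                f"run {self.compound_id}/{self.experiment_id} has no solvent control"
            )
        return int(self.wells_contracting[ctrl][0]), int(self.wells_total[ctrl][0])


def accept_differentiation_run(run: DifferentiationRun) -> tuple[bool, str]:
    """Run-acceptance gate on the solvent control.

    Accepted iff contracting control wells >= ceil(21/24 x wells_total):
    exactly the >= 21-of-24 rule at the default plate size, scaled
    proportionally for other designs.
    """
    contracting, total = run.control_counts()
    threshold = math.ceil(CONTROL_MIN_FRACTION * total)
    ok = contracting >= threshold
    reason = (
        f"control {contracting}/{total} >= {threshold}" if ok
        else f"control {contracting}/{total} below required {threshold}"
    )
    return ok, reason


def to_quantal(
    runs: list[DifferentiationRun],
    require_accepted: bool = True,
) -> QuantalDataset:
    """Pool accepted runs into per-concentration affected-well counts.

    Affected = non-contracting wells (wells_total - wells_contracting);
    wells are summed across runs per concentration so the binomial
    structure is preserved for the likelihood.  Rejected runs are
    excluded with a warning when ``require_accepted`` is set.
    """
    if not runs:
        raise ValueError("no runs supplied")
    compounds = {r.compound_id for r in runs}
    if len(compounds) > 1:
        raise ValueError(f"runs mix compounds: {sorted(compounds)}")
    used = []
    for r in runs:
        if require_accepted:
            ok, reason = accept_differentiation_run(r)
            if not ok:
                warnings.warn(
                    f"excluding run {r.compound_id}/{r.experiment_id}: {reason}",
                    stacklevel=2,
                )
                continue
        used.append(r)
    if not used:
        raise ValueError("all runs rejected by the control-quality gate")
    totals: dict[float, list[int]] = {}
    for r in used:
        for d, n, c in zip(r.concentrations_um, r.wells_total, r.wells_contracting):
            t = totals.setdefault(float(d), [0, 0])
            t[0] += int(n)
            t[1] += int(n) - int(c)
    doses = np.array(sorted(totals))
    n_wells = np.array([totals[d][0] for d in doses])
    affected = np.array([totals[d][1] for d in doses])
    return QuantalDataset(runs[0].compound_id, doses, n_wells, affected)


@dataclass
class ViabilityCurve:
    """Viability as % of solvent control for one compound and exposure."""

    compound_id: str
    exposure_days: int
    concentrations_um: np.ndarray
    viability_percent: np.ndarray
    params_4pl: tuple[float, float, float, float] | None = None  # bottom, top, ec50, hill
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.concentrations_um = np.asarray(self.concentrations_um, dtype=float)
        self.viability_percent = np.asarray(self.viability_percent, dtype=float)
        if self.concentrations_um.size != self.viability_percent.size:
            raise ValueError("concentrations and viability differ in length")
        if np.any(self.viability_percent < 0):
            raise ValueError("viability must be non-negative")


def normalize_viability(
    absorbances: np.ndarray, solvent_control_absorbance: float
) -> np.ndarray:
    """Absorbances -> % of solvent control (control == 100 %)."""
    if solvent_control_absorbance <= 0:
        raise ValueError("solvent control absorbance must be strictly positive")
    return 100.0 * np.asarray(absorbances, dtype=float) / solvent_control_absorbance


def _four_pl(d, bottom, top, ec50, hill):
    d = np.asarray(d, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(d > 0, d / ec50, 0.0) ** hill
    return bottom + (top - bottom) / (1.0 + ratio)


class FourParamLogistic(BaseEstimator):
    """Four-parameter logistic curve r(d) = bottom + (top-bottom)/(1+(d/ec50)^hill).

    Least-squares fit for display and cytotoxicity interpolation.  Fitted
    attributes: ``bottom_``, ``top_``, ``ec50_``, ``hill_``,
    ``converged_``, ``flags_``.  Near-flat responses leave the hill and
    ec50 unidentifiable; the fit is then flagged rather than trusted.
    """

    def __init__(self, maxfev: int = 10000):
        self.maxfev = maxfev

    def fit(self, X, y):
        d = np.asarray(X, dtype=float)
        if d.ndim == 2:
            d = d[:, 0]
        r = np.asarray(y, dtype=float)
        if np.unique(d).size < 4:
            raise ValueError("need at least 4 distinct concentrations for a 4PL fit")
        self.flags_ = []
        span = r.max() - r.min()
        if span < 1e-8 * max(1.0, abs(r.max())):
            # flat curve: ec50/hill carry no information
            self.bottom_ = self.top_ = float(r.mean())
            self.ec50_ = np.nan
            self.hill_ = np.nan
            self.converged_ = False
            self.flags_.append("flat response; ec50 and hill unidentifiable")
            return self
        pos = d[d > 0]
        ec50_0 = float(np.exp(np.mean(np.log(pos)))) if pos.size else 1.0
        p0 = [float(r.min()), float(r.max()), ec50_0, 1.0]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    _four_pl,
                    d,
                    r,
                    p0=p0,
                    bounds=([-np.inf, -np.inf, 1e-12, 0.05], [np.inf, np.inf, 1e12, 50.0]),
                    maxfev=self.maxfev,
                )
            self.bottom_, self.top_, self.ec50_, self.hill_ = map(float, popt)
            self.converged_ = True
        except RuntimeError:
            self.bottom_, self.top_ = float(r.min()), float(r.max())
            self.ec50_, self.hill_ = ec50_0, 1.0
            self.converged_ = False
            self.flags_.append("4PL fit did not converge")
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "bottom_"):
            raise AttributeError("estimator is not fitted")
        d = np.asarray(X, dtype=float)
        if d.ndim == 2:
            d = d[:, 0]
        if not np.isfinite(self.ec50_):
            return np.full(d.shape, self.bottom_)
        return _four_pl(d, self.bottom_, self.top_, self.ec50_, self.hill_)


def fit_4pl(
    concentrations: np.ndarray, responses: np.ndarray
) -> tuple[tuple[float, float, float, float], bool, list[str]]:
    """Thin wrapper: returns ((bottom, top, ec50, hill), converged, flags)."""
    est = FourParamLogistic().fit(np.asarray(concentrations), np.asarray(responses))
    return (est.bottom_, est.top_, est.ec50_, est.hill_), est.converged_, est.flags_


def cytotoxicity_guard(
    bmc_um: float,
    curves: list[ViabilityCurve],
    threshold_percent: float = 80.0,
) -> tuple[bool, list[str]]:
    """Check that the benchmark concentration is non-cytotoxic.

    Passes iff the viability interpolated at ``bmc_um`` is at least
    ``threshold_percent`` for every supplied exposure duration (4PL curve
    when fitted, otherwise linear interpolation).  A BMC outside the
    tested concentration range is evaluated at the nearest bound with an
    extrapolation warning.
    """
    if not curves:
        raise ValueError("no viability curves supplied")
    messages = []
    ok = True
    for curve in curves:
        d = curve.concentrations_um
        lo, hi = float(d.min()), float(d.max())
        eval_at = float(np.clip(bmc_um, lo, hi))
        if bmc_um < lo or bmc_um > hi:
            messages.append(
                f"{curve.compound_id} day {curve.exposure_days}: BMC {bmc_um:.3g} uM "
                f"outside tested range [{lo:g}, {hi:g}]; evaluated at {eval_at:g} uM"
            )
        if curve.params_4pl is not None:
            viab = float(_four_pl(eval_at, *curve.params_4pl))
        else:
            order = np.argsort(d)
            viab = float(np.interp(eval_at, d[order], curve.viability_percent[order]))
        if viab < threshold_percent:
            ok = False
            messages.append(
                f"{curve.compound_id} day {curve.exposure_days}: viability "
                f"{viab:.0f}% at BMC below threshold {threshold_percent:g}%"
            )
    return ok, messages
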