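"""Transwell transport kinetics and apparent permeability (Papp).

A transwell insert separates an apical (donor) compartment from a
basolateral (receiver) compartment by a cell layer grown on a permeable
membrane.  Compound is dosed apically and its appearance in the receiver
is followed over time.  At each sampling time an aliquot is withdrawn
from the receiver and replaced with blank buffer, so measured receiver
concentrations understate the cumulative transported amount; the
bookkeeping here adds every previously withdrawn aliquot back:

    Q(t_k) = c_k * V_b + V_s * sum_{j<k} c_j        [nmol]

with c_j the measured receiver concentration at sample j (uM), V_b the
receiver volume and V_s the aliquot volume (ml).

The apparent permeability coefficient is

    Papp (cm/s) = (dQ/dt) / (A * C0)

where dQ/dt is the receiver appearance rate (nmol/s), A the membrane
area (cm^2) and C0 the initial donor concentration.  C0 in uM equals
nmol/ml, and 1 ml = 1 cm^3, so C0 is numerically nmol/cm^3 and the
units close without a conversion factor.

Relative Papp expresses a compound's Papp as a fraction of the Papp of a
freely transported reference marker (antipyrine by convention), so that
potency estimates can be scaled by relative transfer velocity across the
barrier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SECONDS_PER_MINUTE = 60.0

__all__ = [
    "TranswellConfig",
    "TransportTimeCourse",
    "PappResult",
    "corrected_cumulative_amounts",
    "estimate_appearance_rate",
    "papp_coefficient",
    "relative_papp",
    "mass_balance",
    "intracellular_accumulation_percent",
    "analyze_timecourse",
    "summarize_transport",
]


@dataclass(frozen=True)
class TranswellConfig:
    """Geometry and dosing of one transwell insert.

    Defaults correspond to a 12-mm insert (membrane area 1.12 cm^2) with
    0.5 ml apical and 1.5 ml basolateral buffer, 0.2-ml sampling aliquots
    and a 50 uM apical dose (25 nmol added).
    """

    membrane_area_cm2: float = 1.12
    apical_volume_ml: float = 0.5
    basolateral_volume_ml: float = 1.5
    sample_volume_ml: float = 0.2
    initial_apical_concentration_um: float = 50.0

    def __post_init__(self) -> None:
        for name in (
            "membrane_area_cm2",
            "apical_volume_ml",
            "basolateral_volume_ml",
            "sample_volume_ml",
            "initial_apical_concentration_um",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.sample_volume_ml >= self.basolateral_volume_ml:
            raise ValueError("sample_volume_ml must be smaller than basolateral_volume_ml")

    @property
    def initial_amount_nmol(self) -> float:
        """Amount of compound added apically (nmol)."""
        return self.initial_apical_concentration_um * self.apical_volume_ml


@dataclass
class TransportTimeCourse:
    """Measured receiver concentrations for one insert (one replicate).

    ``final_apical_concentration_um`` and ``cell_associated_amount_nmol``
    are terminal measurements (end of the experiment) used for the mass
    balance and intracellular accumulation; they may be absent (``None``)
    for partial data.
    """

    compound_id: str
    replicate_id: str
    sample_times_min: np.ndarray
    basolateral_concentrations_um: np.ndarray
    final_apical_concentration_um: float | None = None
    cell_associated_amount_nmol: float | None = None

    def __post_init__(self) -> None:
        self.sample_times_min = np.asarray(self.sample_times_min, dtype=float)
        self.basolateral_concentrations_um = np.asarray(
            self.basolateral_concentrations_um, dtype=float
        )
        if self.sample_times_min.size == 0:
            raise ValueError("time course needs at least one sample time")
        if self.sample_times_min.size != self.basolateral_concentrations_um.size:
            raise ValueError("sample times and concentrations differ in length")
        if np.any(np.diff(self.sample_times_min) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(self.sample_times_min <= 0):
            raise ValueError("sample times must be positive")
        if np.any(self.basolateral_concentrations_um < 0):
            raise ValueError("concentrations must be non-negative")
        if (
            self.final_apical_concentration_um is not None
            and self.final_apical_concentration_um < 0
        ):
            raise ValueError("final apical concentration must be non-negative")
        if (
            self.cell_associated_amount_nmol is not None
            and self.cell_associated_amount_nmol < 0
        ):
            raise ValueError("cell associated amount must be non-negative")


@dataclass
class PappResult:
    """Per-insert permeability summary with QC flags."""

    compound_id: str
    replicate_id: str
    appearance_rate_nmol_s: float
    papp_cm_s: float
    relative_papp: float | None = None
    mass_balance_percent: float | None = None
    accumulation_percent: float | None = None
    qc_flags: list[str] = field(default_factory=list)


def corrected_cumulative_amounts(
    tc: TransportTimeCourse, cfg: TranswellConfig
) -> np.ndarray:
    """Cumulative transported amount (nmol) at each sample time.

    Adds back the mass of every previously withdrawn aliquot:
    ``Q_k = c_k * V_b + V_s * sum_{j<k} c_j``.  This is the closed form of
    the step-by-step sampling correction and equals exact event-by-event
    mass bookkeeping of the withdrawals and buffer replacements.
    """
    c = tc.basolateral_concentrations_um
    removed_before = np.concatenate(([0.0], np.cumsum(c)[:-1]))
    return c * cfg.basolateral_volume_ml + cfg.sample_volume_ml * removed_before


def estimate_appearance_rate(
    amounts_nmol: np.ndarray,
    times_min: np.ndarray,
    window_end_min: float = 30.0,
    mode: str = "single_point",
) -> float:
    """Receiver appearance rate dQ/dt in nmol/s.

    mode "single_point" (default): Q(window_end) / window_end, the rate
    through the origin at a single early time point within the linear
    phase of transport.  mode "ols": zero-intercept least-squares slope
    over all samples with t <= window_end.
    """
    amounts = np.asarray(amounts_nmol, dtype=float)
    times = np.asarray(times_min, dtype=float)
    if amounts.size != times.size:
        raise ValueError("amounts and times differ in length")
    if not np.any(np.isclose(times, window_end_min)):
        raise ValueError(
            f"window_end_min={window_end_min} is not a sample time; "
            f"available times: {times.tolist()}"
        )
    if mode == "single_point":
        k = int(np.argmin(np.abs(times - window_end_min)))
        return amounts[k] / (times[k] * SECONDS_PER_MINUTE)
    if mode == "ols":
        in_win = times <= window_end_min + 1e-9
        t_s = times[in_win] * SECONDS_PER_MINUTE
        q = amounts[in_win]
        return float(np.sum(t_s * q) / np.sum(t_s**2))
    raise ValueError(f"unknown rate mode: {mode!r}")


def papp_coefficient(rate_nmol_s: float, cfg: TranswellConfig) -> float:
    """Papp (cm/s) = rate / (A * C0).

    C0 enters in nmol/cm^3; since 1 uM = 1 nmol/ml = 1 nmol/cm^3 the
    stored uM value is used as-is (the ml -> cm^3 identity).
    """
    if rate_nmol_s < 0:
        raise ValueError("appearance rate must be non-negative")
    c0_nmol_cm3 = cfg.initial_apical_concentration_um  # 1 uM == 1 nmol/cm^3
    denom = cfg.membrane_area_cm2 * c0_nmol_cm3
    if denom <= 0:
        raise ValueError("membrane area and initial concentration must be positive")
    return rate_nmol_s / denom


def relative_papp(papp_cm_s: float, reference_papp_cm_s: float) -> float:
    """Papp as a dimensionless fraction of the reference compound's Papp."""
    if reference_papp_cm_s <= 0:
        raise ValueError("reference Papp must be strictly positive")
    return papp_cm_s / reference_papp_cm_s


def mass_balance(
    tc: TransportTimeCourse,
    cfg: TranswellConfig,
    acceptance_window: tuple[float, float] = (90.0, 110.0),
) -> tuple[float, list[str]]:
    """Percent of the dosed amount recovered at the end of the experiment.

    Recovery = apical remaining + cumulative receiver amount (sampling-
    corrected, so withdrawn aliquots count) + cell-associated amount,
    as a percentage of the dosed amount.  Returns ``(percent, qc_flags)``;
    a flag is raised when the recovery falls outside ``acceptance_window``
    (flagged, never dropped).
    """
    missing = []
    if tc.final_apical_concentration_um is None:
        missing.append("final_apical_concentration_um")
    if tc.cell_associated_amount_nmol is None:
        missing.append("cell_associated_amount_nmol")
    if missing:
        raise ValueError(f"mass balance needs terminal measurements: {missing}")
    apical = tc.final_apical_concentration_um * cfg.apical_volume_ml
    basolateral = corrected_cumulative_amounts(tc, cfg)[-1]
    total = apical + basolateral + tc.cell_associated_amount_nmol
    percent = 100.0 * total / cfg.initial_amount_nmol
    flags = []
    lo, hi = acceptance_window
    if not lo <= percent <= hi:
        flags.append(
            f"mass balance {percent:.1f}% outside acceptance window [{lo:g}, {hi:g}]%"
        )
    return percent, flags


def intracellular_accumulation_percent(
    cell_amount_nmol: float, cfg: TranswellConfig
) -> float:
    """Cell-associated amount as percent of the dosed amount."""
    if cell_amount_nmol < 0:
        raise ValueError("cell amount must be non-negative")
    return 100.0 * cell_amount_nmol / cfg.initial_amount_nmol


def analyze_timecourse(
    tc: TransportTimeCourse,
    cfg: TranswellConfig,
    window_end_min: float = 30.0,
    rate_mode: str = "single_point",
    mass_balance_window: tuple[float, float] = (90.0, 110.0),
) -> PappResult:
    """Full per-insert analysis: corrected amounts -> rate -> Papp (+ QC)."""
    amounts = corrected_cumulative_amounts(tc, cfg)
    rate = estimate_appearance_rate(
        amounts, tc.sample_times_min, window_end_min, mode=rate_mode
    )
    papp = papp_coefficient(rate, cfg)
    result = PappResult(
        compound_id=tc.compound_id,
        replicate_id=tc.replicate_id,
        appearance_rate_nmol_s=rate,
        papp_cm_s=papp,
    )
    if (
        tc.final_apical_concentration_um is not None
        and tc.cell_associated_amount_nmol is not None
    ):
        mb, flags = mass_balance(tc, cfg, mass_balance_window)
        result.mass_balance_percent = mb
        result.qc_flags.extend(flags)
    if tc.cell_associated_amount_nmol is not None:
        result.accumulation_percent = intracellular_accumulation_percent(
            tc.cell_associated_amount_nmol, cfg
        )
    return result


def summarize_transport(
    timecourses: list[TransportTimeCourse],
    cfg: TranswellConfig,
    reference_compound: str = "antipyrine",
    window_end_min: float = 30.0,
    rate_mode: str = "single_point",
    mass_balance_window: tuple[float, float] = (90.0, 110.0),
) -> pd.DataFrame:
    """Per-compound transport summary across replicates.

    Returns a table with the mean and SD of the Papp coefficient over
    replicates, the mean intracellular accumulation, the mean mass
    balance, the relative Papp (mean Papp over the reference compound's
    mean Papp; exactly 1 for the reference itself) and pooled QC flags.
    """
    results = [
        analyze_timecourse(tc, cfg, window_end_min, rate_mode, mass_balance_window)
        for tc in timecourses
    ]
    rows: dict[str, list[PappResult]] = {}
    for r in results:
        rows.setdefault(r.compound_id, []).append(r)
    if reference_compound not in rows:
        raise ValueError(
            f"reference compound {reference_compound!r} absent from transport data; "
            f"compounds present: {sorted(rows)}"
        )
    ref_papp = float(np.mean([r.papp_cm_s for r in rows[reference_compound]]))
    records = []
    for compound, res in rows.items():
        papps = np.array([r.papp_cm_s for r in res])
        acc = [r.accumulation_percent for r in res if r.accumulation_percent is not None]
        mb = [r.mass_balance_percent for r in res if r.mass_balance_percent is not None]
        flags = [f for r in res for f in r.qc_flags]
        mean_papp = float(papps.mean())
        rel = 1.0 if compound == reference_compound else relative_papp(mean_papp, ref_papp)
        records.append(
            {
                "compound": compound,
                "n_replicates": len(res),
                "accumulation_percent": float(np.mean(acc)) if acc else np.nan,
                "papp_1e6_cm_s_mean": mean_papp * 1e6,
                "papp_1e6_cm_s_sd": float(papps.std(ddof=1)) * 1e6
                if len(res) > 1
                else np.nan,
                "relative_papp": rel,
                "mass_balance_percent": float(np.mean(mb)) if mb else np.nan,
                "qc_flags": "; ".join(flags),
            }
        )
    return pd.DataFrame.from_records(records).set_index("compound")
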