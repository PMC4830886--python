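"""Synthetic transwell, differentiation and viability data with known truth.

The generators emulate the experimental designs the analysis modules
expect: a 12-mm transwell insert dosed apically at 50 uM (25 nmol) and
sampled basolaterally at 15/30/60/90 min with 0.2-ml aliquots replaced
by blank buffer; three independent 24-well differentiation experiments
per compound over a 0.2-60 uM concentration grid with binomial
well-level outcomes; and sigmoidal WST-1 viability curves.

Transport is forward-simulated by time-stepped Euler integration with
explicit apical depletion and explicit withdrawal/replacement events, so
the analytic linear-phase assumption of the Papp estimator is exercised
rather than baked in.  Concentration measurement noise is multiplicative
lognormal (concentrations stay positive).  Everything is reproducible
from the seed carried in the parameter object.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .assay import DifferentiationRun, ViabilityCurve
from .quantal import DRModelSpec, _response
from .transport import SECONDS_PER_MINUTE, TranswellConfig, TransportTimeCourse

__all__ = [
    "SyntheticTransportParams",
    "SyntheticAssayParams",
    "simulate_transport_timecourse",
    "simulate_differentiation_assay",
    "simulate_viability",
    "default_cohort",
    "well_separated_cohort",
    "simulate_cohort_inputs",
]

DEFAULT_SCHEDULE_MIN = (15.0, 30.0, 60.0, 90.0)
DEFAULT_ASSAY_GRID_UM = (0.0, 0.2, 0.6, 2.0, 6.0, 20.0, 60.0)


@dataclass(frozen=True)
class SyntheticTransportParams:
    """Ground truth for one simulated insert."""

    compound_id: str
    true_papp_cm_s: float
    geometry: TranswellConfig = field(default_factory=TranswellConfig)
    schedule_min: tuple[float, ...] = DEFAULT_SCHEDULE_MIN
    concentration_cv: float = 0.1
    cell_uptake_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_papp_cm_s < 0:
            raise ValueError("true Papp must be non-negative")
        if self.concentration_cv < 0:
            raise ValueError("concentration CV must be non-negative")
        if not 0 <= self.cell_uptake_fraction < 1:
            raise ValueError("cell uptake fraction must be in [0, 1)")
        if len(self.schedule_min) == 0:
            raise ValueError("sampling schedule must not be empty")


@dataclass(frozen=True)
class SyntheticAssayParams:
    """Ground truth for one compound's differentiation experiments."""

    compound_id: str
    model: DRModelSpec
    params: tuple[float, ...]
    grid_um: tuple[float, ...] = DEFAULT_ASSAY_GRID_UM
    wells_per_concentration: int = 24
    n_experiments: int = 3
    control_contracting_prob: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.control_contracting_prob <= 1:
            raise ValueError("control contracting probability must be in [0, 1]")
        if 0.0 not in self.grid_um:
            raise ValueError("grid must include the solvent control (0 uM)")


def simulate_transport_timecourse(p: SyntheticTransportParams) -> TransportTimeCourse:
    """Forward Euler (dt = 0.1 min) simulation of one insert.

    Flux is J = Papp * A * C_apical (sink assumption on the driving
    gradient); the apical compartment depletes as mass moves across.
    An optional fraction of the dose is sequestered into the cell layer
    at time zero.  At each sample time the measured basolateral
    concentration is the true concentration times lognormal noise with
    the given CV; the withdrawal removes true mass (0.2 ml at true
    concentration) and the volume is restored with blank buffer.
    """
    cfg = p.geometry
    rng = np.random.default_rng(p.seed)
    dt_min = 0.1
    amount_apical = cfg.initial_amount_nmol * (1.0 - p.cell_uptake_fraction)
    amount_cells = cfg.initial_amount_nmol * p.cell_uptake_fraction
    amount_baso = 0.0
    # Papp [cm/s] * A [cm^2] / V [cm^3] -> 1/s; per Euler step of dt minutes
    k_per_min = p.true_papp_cm_s * cfg.membrane_area_cm2 / cfg.apical_volume_ml * SECONDS_PER_MINUTE
    sigma = np.sqrt(np.log1p(p.concentration_cv**2))
    t = 0.0
    measured = []
    for t_sample in p.schedule_min:
        while t < t_sample - 1e-9:
            step = min(dt_min, t_sample - t)
            transferred = amount_apical * k_per_min * step
            amount_apical -= transferred
            amount_baso += transferred
            t += step
        c_true = amount_baso / cfg.basolateral_volume_ml
        noise = rng.lognormal(-0.5 * sigma**2, sigma) if p.concentration_cv > 0 else 1.0
        measured.append(c_true * noise)
        amount_baso -= c_true * cfg.sample_volume_ml  # aliquot out, buffer back in
    final_apical_c = amount_apical / cfg.apical_volume_ml
    return TransportTimeCourse(
        compound_id=p.compound_id,
        replicate_id=f"sim{p.seed}",
        sample_times_min=np.array(p.schedule_min),
        basolateral_concentrations_um=np.array(measured),
        final_apical_concentration_um=final_apical_c,
        cell_associated_amount_nmol=amount_cells,
    )


def simulate_differentiation_assay(p: SyntheticAssayParams) -> list[DifferentiationRun]:
    """Independent experiments with binomial well-level outcomes.

    At each positive concentration the number of contracting wells is
    Binomial(wells, 1 - p_affected(d)) under the generating model; the
    solvent control is drawn with its own contracting probability.
    """
    rng = np.random.default_rng(p.seed)
    grid = np.array(sorted(p.grid_um))
    p_affected = _response(p.model.name, np.asarray(p.params, float), grid)
    p_contract = 1.0 - p_affected
    ctrl = grid == 0
    p_contract[ctrl] = p.control_contracting_prob
    runs = []
    for e in range(p.n_experiments):
        contracting = rng.binomial(p.wells_per_concentration, p_contract)
        runs.append(
            DifferentiationRun(
                compound_id=p.compound_id,
                experiment_id=f"exp{e + 1}",
                concentrations_um=grid,
                wells_total=np.full(grid.size, p.wells_per_concentration),
                wells_contracting=contracting,
            )
        )
    return runs


def simulate_viability(
    params_4pl: tuple[float, float, float, float],
    grid_um: np.ndarray,
    noise_sd: float,
    seed: int,
    compound_id: str = "x",
    exposure_days: int = 5,
) -> ViabilityCurve:
    """4PL mean viability plus Gaussian noise, floored at zero."""
    from .assay import _four_pl

    rng = np.random.default_rng(seed)
    grid = np.asarray(grid_um, dtype=float)
    mean = _four_pl(grid, *params_4pl)
    noisy = mean + (rng.normal(0.0, noise_sd, size=grid.size) if noise_sd > 0 else 0.0)
    return ViabilityCurve(
        compound_id=compound_id,
        exposure_days=exposure_days,
        concentrations_um=grid,
        viability_percent=np.maximum(noisy, 0.0),
    )


def _loglogistic_assay(
    compound_id: str, bmc50_um: float, slope: float = 2.0, background: float = 0.05,
    seed: int = 0,
) -> SyntheticAssayParams:
    """Log-logistic generating model with the stated true BMC_d50
    (extra risk 0.5 is reached at d = exp(-a/slope))."""
    a = -slope * np.log(bmc50_um)
    return SyntheticAssayParams(
        compound_id=compound_id,
        model=DRModelSpec("loglogistic"),
        params=(background, a, slope),
        control_contracting_prob=1.0 - background,
        seed=seed,
    )


# Viability ground truth: (bottom at high dose, top, ec50 uM, hill) per
# exposure.  Day-1 exposure is non-cytotoxic across the tested range; day-5
# curves span the observed spectrum, the most cytotoxic compound falling to
# ~10 % viability at 60 uM.
_VIABILITY_5DAY = {
    "t0594": (60.0, 100.0, 45.0, 2.0),
    "t0595": (75.0, 100.0, 55.0, 2.0),
    "t0596": (25.0, 100.0, 40.0, 2.0),
    "t0599": (15.0, 100.0, 35.0, 2.0),
    "t0600": (75.0, 100.0, 55.0, 2.0),
    "t0618": (5.0, 100.0, 30.0, 2.0),
}
_VIABILITY_1DAY = (95.0, 100.0, 60.0, 1.0)  # essentially flat


def default_cohort(seed: int = 0) -> dict:
    """Six test compounds plus the reference markers, with true Papp and
    true BMC_d50 spanning the ranges of the study design they emulate
    (Papp 3-39 x 1e-6 cm/s, BMC 1.8-11.4 uM)."""
    papp = {
        "t0594": 11.5e-6,
        "t0595": 3.0e-6,
        "t0596": 24.4e-6,
        "t0599": 18.4e-6,
        "t0600": 7.9e-6,
        "t0618": 7.1e-6,
        "amoxicillin": 6.5e-6,
        "antipyrine": 38.9e-6,
    }
    bmc = {
        "t0594": 6.9,
        "t0595": 11.0,
        "t0596": 11.4,
        "t0599": 1.8,
        "t0600": 4.2,
        "t0618": 4.3,
    }
    uptake = {
        "t0594": 0.24, "t0595": 0.79, "t0596": 0.12,
        "t0599": 0.22, "t0600": 0.66, "t0618": 0.56,
    }
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(3 * len(papp))
    cohort = {}
    for i, (cid, p) in enumerate(papp.items()):
        entry = {
            "transport": SyntheticTransportParams(
                compound_id=cid,
                true_papp_cm_s=p,
                cell_uptake_fraction=uptake.get(cid, 0.0),
                seed=int(seeds[3 * i] % 2**31),
            )
        }
        if cid in bmc:
            entry["assay"] = _loglogistic_assay(
                cid, bmc[cid], seed=int(seeds[3 * i + 1] % 2**31)
            )
            entry["viability"] = {
                1: (_VIABILITY_1DAY, int(seeds[3 * i + 2] % 2**31)),
                5: (_VIABILITY_5DAY[cid], int(seeds[3 * i + 2] % 2**31) + 1),
            }
        cohort[cid] = entry
    return cohort


def well_separated_cohort(seed: int = 0) -> dict:
    """Six compounds whose true corrected BMC values are separated by a
    factor >= 2, so the full corrected-potency ordering is recoverable at
    realistic noise.  Used for end-to-end ranking recovery experiments."""
    papp = {
        "c1": 30.0e-6, "c2": 20.0e-6, "c3": 12.0e-6,
        "c4": 8.0e-6, "c5": 5.0e-6, "c6": 3.5e-6,
        "antipyrine": 38.9e-6,
    }
    # corrected BMC = bmc / (papp/38.9e-6): 2.6, 5.8, 13, 29.2, 62.2, 133.4
    bmc = {"c1": 2.0, "c2": 3.0, "c3": 4.0, "c4": 6.0, "c5": 8.0, "c6": 12.0}
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(2 * len(papp))
    cohort = {}
    for i, (cid, p) in enumerate(papp.items()):
        entry = {
            "transport": SyntheticTransportParams(
                compound_id=cid, true_papp_cm_s=p, seed=int(seeds[2 * i] % 2**31)
            )
        }
        if cid in bmc:
            entry["assay"] = _loglogistic_assay(
                cid, bmc[cid], seed=int(seeds[2 * i + 1] % 2**31)
            )
        cohort[cid] = entry
    return cohort


def simulate_cohort_inputs(
    cohort: dict, n_transport_replicates: int = 3
) -> tuple[list[TransportTimeCourse], list[DifferentiationRun], list[ViabilityCurve]]:
    """Materialize a cohort into the raw inputs the pipeline consumes."""
    timecourses = []
    runs = []
    curves = []
    for cid, entry in cohort.items():
        tp = entry["transport"]
        for r in range(n_transport_replicates):
            timecourses.append(
                simulate_transport_timecourse(replace(tp, seed=tp.seed + r))
            )
        if "assay" in entry:
            runs.extend(simulate_differentiation_assay(entry["assay"]))
        for days, (params, vseed) in entry.get("viability", {}).items():
            curves.append(
                simulate_viability(
                    params,
                    np.array([0.0, 1.0, 3.0, 10.0, 30.0, 60.0]),
                    noise_sd=5.0,
                    seed=vseed,
                    compound_id=cid,
                    exposure_days=days,
                )
            )
    return timecourses, runs, curves
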