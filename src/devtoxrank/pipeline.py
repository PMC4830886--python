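"""End-to-end orchestration: transport -> differentiation -> BMC -> ranking.

``run_pipeline`` executes the four analysis stages on the standard CSV
inputs and emits three report tables mirroring the study's summary
layout — the transport/permeability table, the potency table (BMC_d50,
relative Papp, corrected BMC_d50) and the ranking-comparison table —
plus concordance statistics and a JSON provenance record.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assay import cytotoxicity_guard, fit_4pl, to_quantal
from .io import (
    read_plates_csv,
    read_ranking,
    read_relative_papp_csv,
    read_toml,
    read_transport_csv,
    read_viability_csv,
)
from .quantal import BenchmarkDoseSelector
from .ranking import build_summary_table, potency_ranking, rank_concordance
from .transport import TranswellConfig, summarize_transport

log = logging.getLogger("devtoxrank")

__all__ = ["PipelineConfig", "PipelineError", "PipelineResult", "run_pipeline"]


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, loadable from TOML."""

    geometry: TranswellConfig = field(default_factory=TranswellConfig)
    reference_compound: str = "antipyrine"
    rate_window_end_min: float = 30.0
    rate_mode: str = "single_point"
    mass_balance_window: tuple[float, float] = (90.0, 110.0)
    bmr: float = 0.5
    risk_type: str = "extra"
    p_min: float = 0.1
    residual_max: float = 2.0
    restricted: bool = True
    multistage_degree: int | None = None
    n_starts: int = 8
    seed: int = 0
    cytotox_threshold_percent: float = 80.0

    def __post_init__(self) -> None:
        if self.risk_type != "extra":
            raise ValueError("config: risk_type must be 'extra'")
        if not 0 < self.bmr < 1:
            raise ValueError("config: bmr must be in (0, 1)")
        if not 0 <= self.p_min <= 1:
            raise ValueError("config: p_min must be in [0, 1]")
        if self.rate_mode not in ("single_point", "ols"):
            raise ValueError("config: rate_mode must be 'single_point' or 'ols'")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        raw = read_toml(path)
        geo = raw.pop("transwell", {})
        known_geo = {
            "membrane_area_cm2",
            "apical_volume_ml",
            "basolateral_volume_ml",
            "sample_volume_ml",
            "initial_apical_concentration_um",
        }
        bad = set(geo) - known_geo
        if bad:
            raise ValueError(f"{path}: unknown [transwell] keys {sorted(bad)}")
        bmd = raw.pop("bmd", {})
        qc = raw.pop("qc", {})
        kwargs: dict = {}
        if geo:
            kwargs["geometry"] = TranswellConfig(**geo)
        for key in ("reference_compound", "rate_window_end_min", "rate_mode", "seed"):
            if key in raw:
                kwargs[key] = raw.pop(key)
        for key in ("bmr", "risk_type", "p_min", "residual_max", "restricted",
                    "multistage_degree", "n_starts"):
            if key in bmd:
                kwargs[key] = bmd.pop(key)
        if "mass_balance_window" in qc:
            kwargs["mass_balance_window"] = tuple(qc.pop("mass_balance_window"))
        if "cytotox_threshold_percent" in qc:
            kwargs["cytotox_threshold_percent"] = qc.pop("cytotox_threshold_percent")
        leftover = {**raw, **bmd, **qc}
        if leftover:
            raise ValueError(f"{path}: unknown config keys {sorted(leftover)}")
        return cls(**kwargs)


@dataclass
class PipelineResult:
    transport_table: pd.DataFrame | None
    potency_table: pd.DataFrame
    ranking_table: pd.DataFrame
    concordance: dict
    fit_report: dict
    provenance: dict


def _sha256(path: str | Path | None) -> str | None:
    if path is None:
        return None
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(
    config: PipelineConfig,
    plates_csv: str | Path,
    transport_csv: str | Path | None = None,
    relative_papp_csv: str | Path | None = None,
    viability_csv: str | Path | None = None,
    ranking_file: str | Path | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis.

    Either ``transport_csv`` (raw time courses) or ``relative_papp_csv``
    (precomputed relative Papp values, the skip-transport path) must be
    given.  ``viability_csv`` enables the cytotoxicity guard and
    ``ranking_file`` the in vivo concordance comparison.
    """
    # --- transport stage -------------------------------------------------
    transport_table = None
    if transport_csv is not None:
        try:
            timecourses = read_transport_csv(transport_csv)
            transport_table = summarize_transport(
                timecourses,
                config.geometry,
                reference_compound=config.reference_compound,
                window_end_min=config.rate_window_end_min,
                rate_mode=config.rate_mode,
                mass_balance_window=config.mass_balance_window,
            )
            rel_papp = transport_table["relative_papp"].to_dict()
        except Exception as exc:
            raise PipelineError(f"[transport] {exc}") from exc
        log.info("transport stage: %d compounds", len(transport_table))
    elif relative_papp_csv is not None:
        try:
            rel_papp = read_relative_papp_csv(relative_papp_csv)
        except Exception as exc:
            raise PipelineError(f"[transport] {exc}") from exc
        log.info("transport stage skipped; %d precomputed relative Papp values", len(rel_papp))
    else:
        raise PipelineError("[transport] need transport_csv or relative_papp_csv")

    # --- differentiation gating + BMC stage ------------------------------
    try:
        runs = read_plates_csv(plates_csv)
        by_compound: dict[str, list] = {}
        for r in runs:
            by_compound.setdefault(r.compound_id, []).append(r)
        bmc: dict[str, float] = {}
        fit_report: dict = {}
        for cid, cruns in sorted(by_compound.items()):
            data = to_quantal(cruns)
            sel = BenchmarkDoseSelector(
                bmr=config.bmr,
                p_min=config.p_min,
                residual_max=config.residual_max,
                restricted=config.restricted,
                multistage_degree=config.multistage_degree,
                n_starts=config.n_starts,
                random_state=config.seed,
            ).fit(data.concentrations_um, np.c_[data.affected, data.n_wells], compound_id=cid)
            if sel.no_accepted_model_:
                log.warning("%s: no accepted dose-response model", cid)
            bmc[cid] = sel.bmc_
            fit_report[cid] = {
                "selected_model": (
                    sel.selected_model_.name if sel.selected_model_ else None
                ),
                "bmc_d50_um": sel.bmc_,
                "no_accepted_model": sel.no_accepted_model_,
                "models": [
                    {
                        "model": f.spec.name
                        + (f"(degree={f.spec.degree})" if f.spec.degree else ""),
                        "params": dict(zip(f.param_names, map(float, f.params))),
                        "loglik": f.loglik,
                        "converged": f.converged,
                        "gof_p": g.p_value,
                        "max_abs_scaled_residual": (
                            float(np.max(np.abs(g.scaled_residuals)))
                            if np.all(np.isfinite(g.scaled_residuals))
                            else None
                        ),
                        "accepted": g.accepted,
                        "bmc_um": b,
                    }
                    for f, g, b in sel.fits_
                ],
            }
            log.info("%s: BMC_d50 = %.3g uM (%s)", cid, sel.bmc_,
                     sel.selected_model_.name if sel.selected_model_ else "none")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"[bmd] {exc}") from exc

    # --- cytotoxicity guard ----------------------------------------------
    guard_verdicts: dict = {}
    if viability_csv is not None:
        try:
            curves = read_viability_csv(viability_csv)
            for curve in curves:
                (bottom, top, ec50, hill), ok4pl, flags = fit_4pl(
                    curve.concentrations_um, curve.viability_percent
                )
                if ok4pl:
                    curve.params_4pl = (bottom, top, ec50, hill)
                curve.flags.extend(flags)
            for cid in bmc:
                ccurves = [c for c in curves if c.compound_id == cid]
                if not ccurves:
                    continue
                ok, messages = cytotoxicity_guard(
                    bmc[cid], ccurves, config.cytotox_threshold_percent
                )
                guard_verdicts[cid] = {"non_cytotoxic_at_bmc": ok, "messages": messages}
                if not ok:
                    log.warning("%s: BMC in the cytotoxic range: %s", cid, messages)
        except Exception as exc:
            raise PipelineError(f"[cytotoxicity] {exc}") from exc

    # --- combination + ranking -------------------------------------------
    try:
        missing = [c for c in bmc if c not in rel_papp]
        if missing:
            raise ValueError(
                f"no relative Papp for {missing} (reference compound is "
                f"{config.reference_compound!r})"
            )
        in_vivo = read_ranking(ranking_file) if ranking_file is not None else None
        potency_table = build_summary_table(
            bmc, {c: rel_papp[c] for c in bmc}, in_vivo_order_most_potent_first=in_vivo
        )
        vitro_order = potency_ranking(bmc)
        corrected_order = potency_ranking(
            potency_table["corrected_bmc_d50_um"].to_dict()
        )
        rows = {
            "es_d3": vitro_order[::-1],
            "es_d3_plus_transfer": corrected_order[::-1],
        }
        concordance: dict = {}
        if in_vivo is not None:
            rows["in_vivo"] = in_vivo[::-1]
            for label, order in (
                ("es_d3_vs_in_vivo", vitro_order),
                ("es_d3_plus_transfer_vs_in_vivo", corrected_order),
            ):
                rho, tau, n_disc = rank_concordance(order, in_vivo)
                concordance[label] = {
                    "spearman_rho": rho,
                    "kendall_tau": tau,
                    "n_discordant_pairs": n_disc,
                }
        n = len(vitro_order)
        ranking_table = pd.DataFrame(
            [[method] + order for method, order in rows.items()],
            columns=["method"] + [f"rank_{i}_least_to_most_toxic" for i in range(1, n + 1)],
        ).set_index("method")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"[combine] {exc}") from exc

    provenance = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config": {
            **{k: v for k, v in asdict(config).items() if k != "geometry"},
            "geometry": asdict(config.geometry),
        },
        "inputs": {
            "plates_csv": _sha256(plates_csv),
            "transport_csv": _sha256(transport_csv),
            "relative_papp_csv": _sha256(relative_papp_csv),
            "viability_csv": _sha256(viability_csv),
            "ranking_file": _sha256(ranking_file),
        },
        "qc": {
            "cytotoxicity_guard": guard_verdicts,
            "transport_flags": (
                transport_table["qc_flags"].to_dict() if transport_table is not None else {}
            ),
        },
    }
    result = PipelineResult(
        transport_table=transport_table,
        potency_table=potency_table,
        ranking_table=ranking_table,
        concordance=concordance,
        fit_report=fit_report,
        provenance=provenance,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if transport_table is not None:
            transport_table.round(
                {"papp_1e6_cm_s_mean": 1, "papp_1e6_cm_s_sd": 1, "relative_papp": 2,
                 "accumulation_percent": 0, "mass_balance_percent": 1}
            ).to_csv(out / "transport_summary.csv")
        potency_table.round(
            {"bmc_d50_um": 1, "relative_papp": 2, "corrected_bmc_d50_um": 1}
        ).to_csv(out / "potency_summary.csv")
        ranking_table.to_csv(out / "ranking_comparison.csv")
        (out / "concordance.json").write_text(json.dumps(concordance, indent=2))
        (out / "fit_report.json").write_text(json.dumps(fit_report, indent=2))
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return result
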