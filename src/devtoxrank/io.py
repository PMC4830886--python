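"""CSV and config readers/writers for the pipeline's tabular formats.

All files are UTF-8 CSV with a header row, "." decimal separator and
empty fields for missing values.  The transport format is long-form:

    compound,replicate,time_min,compartment,concentration_uM_or_amount_nmol

with compartment one of ``basolateral`` (timed receiver concentration,
uM), ``apical_final`` (terminal donor concentration, uM) or ``cell``
(terminal cell-associated amount, nmol).  Configs are TOML.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .assay import DifferentiationRun, ViabilityCurve, normalize_viability
from .transport import TransportTimeCourse

__all__ = [
    "read_transport_csv",
    "write_transport_csv",
    "read_plates_csv",
    "write_plates_csv",
    "read_viability_csv",
    "write_viability_csv",
    "read_ranking",
    "write_ranking",
    "read_relative_papp_csv",
    "write_relative_papp_csv",
    "read_toml",
]

_TRANSPORT_COLS = [
    "compound",
    "replicate",
    "time_min",
    "compartment",
    "concentration_uM_or_amount_nmol",
]


def read_transport_csv(path: str | Path) -> list[TransportTimeCourse]:
    df = pd.read_csv(path)
    missing = [c for c in _TRANSPORT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing transport columns {missing}")
    out = []
    for (compound, replicate), grp in df.groupby(["compound", "replicate"], sort=True):
        baso = grp[grp.compartment == "basolateral"].sort_values("time_min")
        apical = grp[grp.compartment == "apical_final"]
        cell = grp[grp.compartment == "cell"]
        bad = set(grp.compartment) - {"basolateral", "apical_final", "cell"}
        if bad:
            raise ValueError(f"{path}: unknown compartment labels {sorted(bad)}")
        out.append(
            TransportTimeCourse(
                compound_id=str(compound),
                replicate_id=str(replicate),
                sample_times_min=baso.time_min.to_numpy(float),
                basolateral_concentrations_um=baso.concentration_uM_or_amount_nmol.to_numpy(float),
                final_apical_concentration_um=(
                    float(apical.concentration_uM_or_amount_nmol.iloc[0])
                    if len(apical)
                    else None
                ),
                cell_associated_amount_nmol=(
                    float(cell.concentration_uM_or_amount_nmol.iloc[0]) if len(cell) else None
                ),
            )
        )
    return out


def write_transport_csv(timecourses: list[TransportTimeCourse], path: str | Path) -> None:
    rows = []
    for tc in timecourses:
        for t, c in zip(tc.sample_times_min, tc.basolateral_concentrations_um):
            rows.append((tc.compound_id, tc.replicate_id, t, "basolateral", c))
        if tc.final_apical_concentration_um is not None:
            rows.append(
                (
                    tc.compound_id,
                    tc.replicate_id,
                    tc.sample_times_min[-1],
                    "apical_final",
                    tc.final_apical_concentration_um,
                )
            )
        if tc.cell_associated_amount_nmol is not None:
            rows.append(
                (
                    tc.compound_id,
                    tc.replicate_id,
                    tc.sample_times_min[-1],
                    "cell",
                    tc.cell_associated_amount_nmol,
                )
            )
    pd.DataFrame(rows, columns=_TRANSPORT_COLS).to_csv(path, index=False)


_PLATE_COLS = ["compound", "experiment", "concentration_uM", "wells_total", "wells_contracting"]


def read_plates_csv(path: str | Path) -> list[DifferentiationRun]:
    df = pd.read_csv(path)
    missing = [c for c in _PLATE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing plate columns {missing}")
    out = []
    for (compound, experiment), grp in df.groupby(["compound", "experiment"], sort=True):
        grp = grp.sort_values("concentration_uM")
        out.append(
            DifferentiationRun(
                compound_id=str(compound),
                experiment_id=str(experiment),
                concentrations_um=grp.concentration_uM.to_numpy(float),
                wells_total=grp.wells_total.to_numpy(int),
                wells_contracting=grp.wells_contracting.to_numpy(int),
            )
        )
    return out


def write_plates_csv(runs: list[DifferentiationRun], path: str | Path) -> None:
    rows = [
        (r.compound_id, r.experiment_id, d, n, c)
        for r in runs
        for d, n, c in zip(r.concentrations_um, r.wells_total, r.wells_contracting)
    ]
    pd.DataFrame(rows, columns=_PLATE_COLS).to_csv(path, index=False)


def read_viability_csv(path: str | Path) -> list[ViabilityCurve]:
    """Viability table with either a ``viability_percent`` or an
    ``absorbance`` column; absorbances are normalized to the mean
    absorbance of the 0-uM (solvent control) rows per compound/exposure."""
    df = pd.read_csv(path)
    base = ["compound", "exposure_days", "concentration_uM"]
    missing = [c for c in base if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing viability columns {missing}")
    has_pct = "viability_percent" in df.columns
    has_abs = "absorbance" in df.columns
    if not (has_pct or has_abs):
        raise ValueError(f"{path}: need a viability_percent or absorbance column")
    out = []
    for (compound, days), grp in df.groupby(["compound", "exposure_days"], sort=True):
        agg = grp.groupby("concentration_uM", sort=True)
        if has_pct:
            viab = agg.viability_percent.mean()
        else:
            ctrl = grp[grp.concentration_uM == 0].absorbance.mean()
            viab = agg.absorbance.mean().pipe(lambda s: pd.Series(
                normalize_viability(s.to_numpy(), float(ctrl)), index=s.index))
        out.append(
            ViabilityCurve(
                compound_id=str(compound),
                exposure_days=int(days),
                concentrations_um=viab.index.to_numpy(float),
                viability_percent=viab.to_numpy(float),
            )
        )
    return out


def write_viability_csv(curves: list[ViabilityCurve], path: str | Path) -> None:
    rows = [
        (c.compound_id, c.exposure_days, d, v)
        for c in curves
        for d, v in zip(c.concentrations_um, c.viability_percent)
    ]
    pd.DataFrame(
        rows, columns=["compound", "exposure_days", "concentration_uM", "viability_percent"]
    ).to_csv(path, index=False)


def read_ranking(path: str | Path, most_potent_first: bool = True) -> list[str]:
    """Ordered compound list, one per line, least toxic first (the table
    convention); returned most-potent-first unless told otherwise.
    Blank lines and ``#`` comments are ignored."""
    lines = [
        ln.strip()
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.strip().startswith("#")
    ]
    if len(set(lines)) != len(lines):
        raise ValueError(f"{path}: duplicate compounds in ranking")
    return lines[::-1] if most_potent_first else lines


def write_ranking(order_least_to_most: list[str], path: str | Path) -> None:
    Path(path).write_text(
        "# potency ranking, least toxic first\n" + "\n".join(order_least_to_most) + "\n"
    )


def read_relative_papp_csv(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path)
    for col in ("compound", "relative_papp"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    return {str(r.compound): float(r.relative_papp) for r in df.itertuples()}


def write_relative_papp_csv(values: dict[str, float], path: str | Path) -> None:
    pd.DataFrame(
        sorted(values.items()), columns=["compound", "relative_papp"]
    ).to_csv(path, index=False)


def read_toml(path: str | Path) -> dict:
    with open(path, "rb") as fh:
        try:
            return tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ValueError(f"{path}: invalid config: {exc}") from exc
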