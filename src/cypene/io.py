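"""Reading and writing the stationary-point table and frequency-list formats.

The tabular interchange format is a flat CSV (or equivalent JSON array) with
one row per stationary point::

    molecule,site,stereopath,enantiomer,multiplicity,stage,e_elec_hartree,
    h_hartree,g_hartree,dispersion_hartree,bsse_hartree,qh_hartree,
    solvent_hartree

Empty cells mean "absent optional field". Frequency lists are plain text,
one wavenumber (cm⁻¹) per line, negative = imaginary, ``#`` starts a comment.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .energetics import (
    CorrectionSet,
    Enantiomer,
    Molecule,
    Site,
    SpeciesLabel,
    Stage,
    StationaryPoint,
    Stereopath,
)

__all__ = [
    "TABLE_COLUMNS",
    "read_stationary_points",
    "write_stationary_points",
    "points_to_frame",
    "frame_to_points",
    "read_frequencies",
    "write_frequencies",
]

TABLE_COLUMNS = [
    "molecule",
    "site",
    "stereopath",
    "enantiomer",
    "multiplicity",
    "stage",
    "e_elec_hartree",
    "h_hartree",
    "g_hartree",
    "g_uncorrected_hartree",
    "dispersion_hartree",
    "bsse_hartree",
    "qh_hartree",
    "solvent_hartree",
]

_OPTIONAL_FLOAT_COLUMNS = [
    "e_elec_hartree",
    "h_hartree",
    "g_uncorrected_hartree",
    "dispersion_hartree",
    "bsse_hartree",
    "qh_hartree",
    "solvent_hartree",
]


def _opt(row: pd.Series, column: str) -> float | None:
    if column not in row or pd.isna(row[column]):
        return None
    return float(row[column])


def frame_to_points(frame: pd.DataFrame) -> list[StationaryPoint]:
    """Build typed stationary points from an interchange-schema DataFrame."""
    points: list[StationaryPoint] = []
    for _, row in frame.iterrows():
        label = SpeciesLabel(
            molecule=Molecule(row["molecule"]),
            site=Site(row["site"]),
            stereopath=Stereopath(row.get("stereopath") or "none"),
            enantiomer=Enantiomer(row.get("enantiomer") or "none"),
            multiplicity=int(row["multiplicity"]),
        )
        corr_terms = {
            "dispersion": _opt(row, "dispersion_hartree"),
            "bsse": _opt(row, "bsse_hartree"),
            "quasi_harmonic": _opt(row, "qh_hartree"),
        }
        corrections = None
        if all(v is not None for v in corr_terms.values()):
            corrections = CorrectionSet(
                solvent=_opt(row, "solvent_hartree") or 0.0,
                **corr_terms,  # type: ignore[arg-type]
            )
        points.append(
            StationaryPoint(
                label=label,
                stage=Stage(row["stage"]),
                g=float(row["g_hartree"]),
                e_elec=_opt(row, "e_elec_hartree"),
                h=_opt(row, "h_hartree"),
                g_uncorrected=_opt(row, "g_uncorrected_hartree"),
                corrections=corrections,
                note=str(row["note"]) if "note" in row and pd.notna(row.get("note")) else "",
            )
        )
    return points


def points_to_frame(points: Iterable[StationaryPoint]) -> pd.DataFrame:
    rows = []
    for p in points:
        c = p.corrections
        rows.append(
            {
                "molecule": p.label.molecule.value,
                "site": p.label.site.value,
                "stereopath": p.label.stereopath.value,
                "enantiomer": p.label.enantiomer.value,
                "multiplicity": p.label.multiplicity,
                "stage": p.stage.value,
                "e_elec_hartree": p.e_elec,
                "h_hartree": p.h,
                "g_hartree": p.g,
                "g_uncorrected_hartree": p.g_uncorrected,
                "dispersion_hartree": c.dispersion if c else None,
                "bsse_hartree": c.bsse if c else None,
                "qh_hartree": c.quasi_harmonic if c else None,
                "solvent_hartree": c.solvent if c else None,
                "note": p.note,
            }
        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS + ["note"])


def read_stationary_points(path: str | Path) -> list[StationaryPoint]:
    """Read a stationary-point table; format chosen by suffix (.csv / .json)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        frame = pd.DataFrame(json.loads(path.read_text(encoding="utf-8")))
    else:
        frame = pd.read_csv(path, dtype={"stereopath": str, "enantiomer": str})
    missing = {"molecule", "site", "multiplicity", "stage", "g_hartree"} - set(
        frame.columns
    )
    if missing:
        raise ValueError(f"input table missing required columns: {sorted(missing)}")
    return frame_to_points(frame)


def write_stationary_points(points: Iterable[StationaryPoint], path: str | Path) -> None:
    path = Path(path)
    frame = points_to_frame(points)
    if path.suffix.lower() == ".json":
        records = frame.where(pd.notna(frame), None).to_dict(orient="records")
        path.write_text(json.dumps(records, indent=1), encoding="utf-8")
    else:
        frame.to_csv(path, index=False, float_format="%.10g")


def read_frequencies(path: str | Path) -> np.ndarray:
    """Read a plain-text frequency list (cm⁻¹; ``#`` comments; negative = imaginary)."""
    values: list[float] = []
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            value = float(line)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: not a wavenumber: {line!r}") from exc
        if not math.isfinite(value):
            raise ValueError(f"{path}:{lineno}: non-finite wavenumber")
        values.append(value)
    return np.asarray(values, dtype=float)


def write_frequencies(frequencies: Iterable[float], path: str | Path) -> None:
    lines = [f"{f:.6f}" for f in frequencies]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
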