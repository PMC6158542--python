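"""Shared I/O: islet tables, dissociation tables, curve JSON, reports, config.

CSV columns carry explicit unit suffixes (``diameter_um``, ``area_um2``) —
the field's core failure mode is unit and size ambiguity, so the reader is
strict: header required, UTF-8, ``.`` decimal separator (values containing a
``,`` are rejected as ambiguous), per-row diagnostics on bad values.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence

import pandas as pd

from .cellnum import CalibrationCurve, DissociationRecord
from .dosing import TransplantGroup
from .ieq import IEQResult
from .morphometry import IsletBatch, IsletRecord, IsletShape

logger = logging.getLogger("isletquant")

ISLET_REQUIRED = ["id", "diameter_um"]
ISLET_OPTIONAL = ["a_um", "b_um", "c_um", "area_um2", "perimeter_um", "cell_count"]


class TableError(ValueError):
    """A table failed validation; message carries per-row diagnostics."""


def _to_float(value: Any, row: int, col: str, errors: list[str]) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    s = str(value).strip()
    if "," in s:
        errors.append(f"row {row}: {col}={s!r} contains ',' — ambiguous decimal separator")
        return None
    try:
        return float(s)
    except ValueError:
        errors.append(f"row {row}: {col}={s!r} is not numeric")
        return None


def read_islet_table(path: str | Path) -> IsletBatch:
    """Read a per-islet measurement CSV into a validated batch.

    Required columns ``id,diameter_um``; optional axis, area/perimeter and
    cell-count columns.  Raises :class:`TableError` listing every bad row.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in ISLET_REQUIRED if c not in df.columns]
    if missing:
        raise TableError(f"{path}: missing required columns: {', '.join(missing)}")
    errors: list[str] = []
    records: list[IsletRecord] = []
    for row, rec in enumerate(df.to_dict("records")):
        vals = {c: _to_float(rec.get(c), row, c, errors) for c in ["diameter_um"] + ISLET_OPTIONAL}
        d = vals["diameter_um"]
        if d is None:
            errors.append(f"row {row}: diameter_um is required")
            continue
        shape = None
        axes = [vals["a_um"], vals["b_um"], vals["c_um"]]
        if all(a is not None for a in axes):
            try:
                shape = IsletShape(*axes)
            except ValueError as e:
                errors.append(f"row {row}: {e}")
        cells = vals["cell_count"]
        try:
            records.append(
                IsletRecord(
                    id=str(rec.get("id", row)),
                    diameter=d,
                    shape=shape,
                    area=vals["area_um2"],
                    perimeter=vals["perimeter_um"],
                    cell_count=None if cells is None else int(cells),
                )
            )
        except ValueError as e:
            errors.append(f"row {row}: {e}")
    if errors:
        raise TableError(f"{path}: invalid islet table:\n  " + "\n  ".join(errors))
    return IsletBatch(records=records)


def write_islet_table(batch: IsletBatch, path: str | Path) -> None:
    rows = []
    for r in batch:
        rows.append(
            {
                "id": r.id,
                "diameter_um": r.diameter,
                "a_um": r.shape.a if r.shape else None,
                "b_um": r.shape.b if r.shape else None,
                "c_um": r.shape.c if r.shape else None,
                "area_um2": r.area,
                "perimeter_um": r.perimeter,
                "cell_count": r.cell_count,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")


def read_dissociation_table(path: str | Path) -> list[DissociationRecord]:
    """Read a dissociation CSV: ``islet_id,diameter_um,cells[,binned_diameter_um]``."""
    df = pd.read_csv(path, dtype=str)
    for c in ("islet_id", "diameter_um", "cells"):
        if c not in df.columns:
            raise TableError(f"{path}: missing required column {c!r}")
    errors: list[str] = []
    out: list[DissociationRecord] = []
    for row, rec in enumerate(df.to_dict("records")):
        d = _to_float(rec["diameter_um"], row, "diameter_um", errors)
        cells = _to_float(rec["cells"], row, "cells", errors)
        binned = _to_float(rec.get("binned_diameter_um"), row, "binned_diameter_um", errors)
        if d is None or cells is None:
            continue
        try:
            out.append(
                DissociationRecord(
                    islet_id=str(rec["islet_id"]), diameter=d, cells=int(cells),
                    binned_diameter=binned,
                )
            )
        except ValueError as e:
            errors.append(f"row {row}: {e}")
    if errors:
        raise TableError(f"{path}: invalid dissociation table:\n  " + "\n  ".join(errors))
    return out


def read_transplant_table(path: str | Path) -> list[TransplantGroup]:
    """Read a transplant-group CSV:
    ``group,cells_per_mouse_M,ieq_per_mouse,frac_failure,frac_partial,frac_normal[,n_mice]``.
    """
    df = pd.read_csv(path, dtype={"group": str})
    required = [
        "group", "cells_per_mouse_M", "ieq_per_mouse",
        "frac_failure", "frac_partial", "frac_normal",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableError(f"{path}: missing required columns: {', '.join(missing)}")
    groups = []
    for _, rec in df.iterrows():
        groups.append(
            TransplantGroup(
                group=str(rec["group"]),
                cells_per_mouse=float(rec["cells_per_mouse_M"]),
                ieq_per_mouse=float(rec["ieq_per_mouse"]),
                frac_failure=float(rec["frac_failure"]),
                frac_partial=float(rec["frac_partial"]),
                frac_normal=float(rec["frac_normal"]),
                n_mice=int(rec["n_mice"]) if "n_mice" in df.columns and pd.notna(rec.get("n_mice")) else None,
            )
        )
    return groups


# ---------------------------------------------------------------------------
# curve JSON

def write_curve(curve: CalibrationCurve, path: str | Path) -> None:
    payload = {
        "form": curve.form,
        "alpha": curve.alpha,
        "beta": curve.beta,
        "coeffs": list(curve.coeffs) if curve.coeffs else None,
        "fit_n": curve.fit_n,
        "residual_spread": curve.residual_spread,
        "species": curve.species,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_curve(path: str | Path) -> CalibrationCurve:
    raw = json.loads(Path(path).read_text())
    return CalibrationCurve(
        alpha=raw["alpha"],
        beta=raw["beta"],
        form=raw.get("form", "power"),
        coeffs=tuple(raw["coeffs"]) if raw.get("coeffs") else None,
        fit_n=raw.get("fit_n", 0),
        residual_spread=raw.get("residual_spread", 0.0),
        species=raw.get("species", "unspecified"),
    )


# ---------------------------------------------------------------------------
# reports and run configuration

def ieq_report_dict(result: IEQResult) -> dict:
    """Stable machine-readable form of a binned IEQ result."""
    return {
        "total_ieq": round(result.total_ieq, 6),
        "n_included": result.n_included,
        "n_excluded": result.n_excluded,
        "per_bin": {
            lab: {"count": b.count, "factor": round(b.factor, 6), "ieq": round(b.ieq, 6)}
            for lab, b in result.per_bin.items()
        },
    }


def write_report(results: dict, path: str | Path) -> None:
    """Write a deterministic JSON report (sorted keys, fixed float rounding)."""
    def _clean(x):
        if isinstance(x, dict):
            return {k: _clean(v) for k, v in x.items() if v is not None}
        if isinstance(x, (list, tuple)):
            return [_clean(v) for v in x]
        if isinstance(x, float):
            return round(x, 6)
        return x

    Path(path).write_text(json.dumps(_clean(results), indent=2, sort_keys=True) + "\n")


@dataclass
class RunConfig:
    """Serializable run configuration; round-trips losslessly through JSON."""

    seed: Optional[int] = None
    species: str = "rat"
    scheme_dialect: str = "midpoint"
    include_sub50: bool = False
    curve_path: Optional[str] = None
    out_dir: str = "."
    verbosity: str = "INFO"
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        return cls(**raw)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def configure_logging(verbosity: str = "INFO") -> None:
    logging.basicConfig(level=getattr(logging, verbosity.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
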