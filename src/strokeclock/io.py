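"""File I/O, manifest validation and run logging.

Formats: expression matrices are TSV with the gene ID in the first
column and sample IDs as the header; sample sheets and candidate lists
are CSV; decimal point is ".", encoding UTF-8, and a blank cell means
missing. Times are decimal hours since vessel occlusion (0 h is the
pre-anesthesia baseline draw).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import StudyDesign
from .errors import UserInputError


# ---------------------------------------------------------------------------
# expression matrices and sample sheets


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples TSV; duplicate gene IDs and non-numeric
    cells are labeled errors; blank cells become NaN."""
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise UserInputError(f"duplicate gene ID {dup!r} in {path.name}")
    for col in raw.columns:
        if raw[col].dtype == object:  # some cell failed numeric parsing
            for gene, cell in raw[col].items():
                if isinstance(cell, str) and cell.strip():
                    try:
                        float(cell)
                    except ValueError:
                        raise UserInputError(
                            f"non-numeric cell at gene {gene!r}, sample {col!r} "
                            f"in {path.name}"
                        ) from None
            raw[col] = raw[col].map(
                lambda x: float(x) if isinstance(x, str) and x.strip() else np.nan
            )
    matrix = raw.astype(float)
    matrix.index.name = raw.index.name or "gene_id"
    return matrix


def write_expression(matrix: pd.DataFrame, path) -> None:
    """Write a genes x samples TSV at full float precision."""
    out = matrix.copy()
    out.index.name = out.index.name or "gene_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a sample sheet CSV (sample_id, animal, time_h[, batch])."""
    sheet = pd.read_csv(path, dtype={"sample_id": str, "batch": str})
    required = {"sample_id", "animal", "time_h"}
    missing = required - set(sheet.columns)
    if missing:
        raise UserInputError(f"sample sheet lacks columns {sorted(missing)}")
    if "batch" not in sheet.columns:
        sheet["batch"] = "1"
    sheet["animal"] = sheet["animal"].astype(int)
    sheet["time_h"] = sheet["time_h"].astype(float)
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# manifest validation


@dataclass
class Manifest:
    """Validated sample accounting for a sheet against a design."""

    sheet: pd.DataFrame
    total: int
    per_timepoint: dict[float, int]
    per_animal: dict[int, int]
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.warnings


def validate_manifest(sheet: pd.DataFrame, design: StudyDesign | None = None) -> Manifest:
    """Count samples per timepoint/animal and check against the design.

    Duplicate (animal, time) pairs are an error; mismatches against the
    declared design (unknown animals or timepoints, unexpected totals)
    are reported as warnings.
    """
    dup = sheet.duplicated(["animal", "time_h"])
    if dup.any():
        a, t = sheet.loc[dup.idxmax(), ["animal", "time_h"]]
        raise UserInputError(f"duplicate sample for animal {a} at {t} h")
    per_tp = sheet.groupby("time_h").size().to_dict()
    per_animal = sheet.groupby("animal").size().to_dict()
    warnings: list[str] = []
    if design is not None:
        extra_t = sorted(set(sheet["time_h"]) - set(design.timepoints_h))
        if extra_t:
            warnings.append(f"timepoints not in design: {extra_t}")
        extra_a = sorted(a for a in per_animal if not 1 <= a <= design.n_animals)
        if extra_a:
            warnings.append(f"animals not in design: {extra_a}")
        if len(sheet) != design.n_samples:
            warnings.append(
                f"total {len(sheet)} differs from design's {design.n_samples}"
            )
        expected = {
            t: design.n_animals - sum(1 for (_, mt) in design.missing if mt == t)
            for t in design.timepoints_h
        }
        for t, n in expected.items():
            if per_tp.get(t, 0) != n:
                warnings.append(f"expected {n} samples at {t:g} h, found {per_tp.get(t, 0)}")
    return Manifest(sheet=sheet, total=len(sheet), per_timepoint=per_tp,
                    per_animal=per_animal, warnings=warnings)


# ---------------------------------------------------------------------------
# printed-volume arithmetic


def check_volume_arithmetic(total_mean: float, part_means, tol: float = 0.01) -> dict:
    """Does the sum of the part means reproduce the total mean?

    Returns {"consistent": bool, "residual": float, "sum_parts": float}.
    """
    sum_parts = float(np.sum(np.asarray(part_means, dtype=float))) if len(part_means) else 0.0
    residual = float(total_mean) - sum_parts
    return {
        "consistent": abs(residual) <= tol,
        "residual": residual,
        "sum_parts": sum_parts,
    }


# ---------------------------------------------------------------------------
# run logging


def file_digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_run_log(out_dir, command: str, settings: dict, inputs: dict | None = None) -> Path:
    """Machine-readable record of a CLI run: settings, seeds, input digests."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = {
        "command": command,
        "settings": {k: (v if not isinstance(v, Path) else str(v))
                     for k, v in settings.items()},
        "inputs": {name: {"path": str(p), "sha256": file_digest(p)}
                   for name, p in (inputs or {}).items()},
    }
    path = out_dir / f"run_log_{command}.json"
    path.write_text(json.dumps(log, indent=2, default=str))
    return path
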