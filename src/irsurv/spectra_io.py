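"""Open on-disk formats for hyperspectral cubes, tumour masks and cohort tables.

Infrared microspectroscopy vendors ship proprietary containers; this package
instead uses three deliberately simple, language-neutral formats:

* **Cube** — a JSON sidecar header (``<stem>.cube.json``: shape, wavenumber
  axis, patient id) next to a flat binary payload (``<stem>.cube.bin``) of
  little-endian 64-bit floats in row-major ``(row, col, wavenumber)`` order.
* **Mask** — a binary tumour annotation as either a single-channel PNG
  (``*.mask.png``, values 0/255) or a CSV of 0/1 (``*.mask.csv``), detected
  by extension.
* **Cohort** — a TSV (``cohort.tsv``) with header
  ``patient_id  time_months  event [risk_label] [score]``.

Pixel coordinates are 0-based ``(row, col)`` with row 0 at the top,
everywhere in the package.  Serialisation is canonical: writing what was
read produces a byte-identical file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import DataError, FormatError

_CUBE_FORMAT = "irsurv-cube"
_CUBE_VERSION = 1

COHORT_REQUIRED_COLUMNS = ["patient_id", "time_months", "event"]
COHORT_OPTIONAL_COLUMNS = ["risk_label", "true_class", "score"]


@dataclass
class HyperspectralCube:
    """A pixel grid of absorbance spectra sharing one wavenumber axis.

    ``data`` is indexed ``(row, col, wavenumber)``; ``axis`` holds the
    wavenumbers in cm⁻¹ and is strictly increasing.
    """

    axis: np.ndarray
    data: np.ndarray
    patient_id: str

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise FormatError("cube data must be 3-d (row, col, wavenumber)")
        if self.axis.ndim != 1 or self.axis.size != self.data.shape[2]:
            raise FormatError(
                f"axis length {self.axis.size} != spectral depth {self.data.shape[2]}"
            )
        if self.axis.size >= 2 and not np.all(np.diff(self.axis) > 0):
            raise FormatError("wavenumber axis must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise DataError("cube contains non-finite absorbance values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class AnnotationMask:
    """Binary tumour annotation on the pixel grid of the co-registered section."""

    grid: np.ndarray
    patient_id: str

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 2:
            raise FormatError("mask must be a 2-d grid")
        if not np.isin(grid, (0, 1)).all():
            raise FormatError("mask values must all be 0 or 1")
        self.grid = grid.astype(np.uint8)

    @property
    def tumour_fraction(self) -> float:
        return float(self.grid.mean())


def _cube_paths(path: str | Path) -> tuple[Path, Path]:
    """Resolve a cube stem / header / payload path to the (json, bin) pair."""
    p = Path(path)
    name = p.name
    for suffix in (".cube.json", ".cube.bin", ".cube"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
            break
    stem = p.with_name(name)
    return stem.parent / f"{stem.name}.cube.json", stem.parent / f"{stem.name}.cube.bin"


def write_cube(cube: HyperspectralCube, path: str | Path) -> tuple[Path, Path]:
    """Write ``<stem>.cube.json`` + ``<stem>.cube.bin``; returns both paths."""
    header_path, payload_path = _cube_paths(path)
    header = {
        "format": _CUBE_FORMAT,
        "version": _CUBE_VERSION,
        "patient_id": cube.patient_id,
        "shape": list(cube.shape),
        "axis": cube.axis.tolist(),
    }
    header_path.write_text(json.dumps(header, sort_keys=True, indent=2) + "\n")
    payload_path.write_bytes(np.ascontiguousarray(cube.data, dtype="<f8").tobytes())
    return header_path, payload_path


def read_cube(path: str | Path) -> HyperspectralCube:
    """Read a cube pair.

    A descending axis in the file is reordered ascending with the spectral
    planes permuted consistently; header/payload dimension mismatches raise
    :class:`~irsurv.errors.FormatError`.
    """
    header_path, payload_path = _cube_paths(path)
    try:
        header = json.loads(header_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{header_path}: invalid JSON header: {exc}") from exc
    if header.get("format") != _CUBE_FORMAT:
        raise FormatError(f"{header_path}: not an {_CUBE_FORMAT} header")
    shape = tuple(header["shape"])
    axis = np.asarray(header["axis"], dtype=float)
    if len(shape) != 3 or axis.size != shape[2]:
        raise FormatError(
            f"{header_path}: axis length {axis.size} inconsistent with shape {shape}"
        )
    raw = np.frombuffer(payload_path.read_bytes(), dtype="<f8")
    expected = int(np.prod(shape))
    if raw.size != expected:
        raise FormatError(
            f"{payload_path}: payload has {raw.size} values, header implies {expected}"
        )
    data = raw.reshape(shape).copy()
    if axis.size >= 2 and np.all(np.diff(axis) < 0):
        axis = axis[::-1].copy()
        data = data[:, :, ::-1].copy()
    return HyperspectralCube(axis=axis, data=data, patient_id=str(header["patient_id"]))


def write_mask(mask: AnnotationMask, path: str | Path) -> Path:
    """Write a mask as PNG (0/255) or CSV (0/1), chosen by extension."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        Image.fromarray((mask.grid * 255).astype(np.uint8), mode="L").save(path)
    elif path.suffix.lower() == ".csv":
        np.savetxt(path, mask.grid, fmt="%d", delimiter=",")
    else:
        raise FormatError(f"unsupported mask extension: {path.suffix!r}")
    return path


def read_mask(path: str | Path, patient_id: str | None = None) -> AnnotationMask:
    """Read a mask; values must be binary (0/1 in CSV, 0/255 or 0/1 in PNG)."""
    path = Path(path)
    if patient_id is None:
        patient_id = path.name.split(".")[0]
    if path.suffix.lower() == ".png":
        grid = np.asarray(Image.open(path).convert("L"))
        values = np.unique(grid)
        if np.isin(values, (0, 255)).all():
            grid = (grid > 0).astype(np.uint8)
        elif not np.isin(values, (0, 1)).all():
            raise FormatError(f"{path}: non-binary mask values {values[:5]}")
    elif path.suffix.lower() == ".csv":
        grid = np.loadtxt(path, delimiter=",", dtype=float, ndmin=2)
        if not np.isin(grid, (0, 1)).all():
            raise FormatError(f"{path}: non-binary mask values")
    else:
        raise FormatError(f"unsupported mask extension: {path.suffix!r}")
    return AnnotationMask(grid=grid.astype(np.uint8), patient_id=patient_id)


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort table and return it with canonical column order.

    Required columns: ``patient_id`` (unique), ``time_months`` (> 0),
    ``event`` (0/1).  Optional: ``risk_label`` (high/low), ``true_class``
    (high/low), ``score`` in [0, 1].
    """
    missing = [c for c in COHORT_REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"cohort table missing columns {missing}")
    table = table.copy()
    table["patient_id"] = table["patient_id"].astype(str)
    if table["patient_id"].duplicated().any():
        dupes = table.loc[table["patient_id"].duplicated(), "patient_id"].tolist()
        raise DataError(f"duplicate patient_id values: {dupes}")
    table["time_months"] = table["time_months"].astype(float)
    if not (table["time_months"] > 0).all():
        raise DataError("time_months must be strictly positive")
    if not table["event"].isin((0, 1)).all():
        raise DataError("event indicator must be 0 or 1")
    table["event"] = table["event"].astype(int)
    for col in ("risk_label", "true_class"):
        if col in table.columns and not table[col].isin(("high", "low")).all():
            raise DataError(f"{col} values must be 'high' or 'low'")
    if "score" in table.columns:
        score = table["score"].astype(float)
        valid = score.dropna()
        if not ((valid >= 0) & (valid <= 1)).all():
            raise DataError("score values must lie in [0, 1]")
        table["score"] = score
    ordered = COHORT_REQUIRED_COLUMNS + [
        c for c in COHORT_OPTIONAL_COLUMNS if c in table.columns
    ]
    return table[ordered].reset_index(drop=True)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate ``cohort.tsv``."""
    # round_trip parsing keeps %.17g values bit-exact across write/read cycles
    table = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return validate_cohort(table)


def write_cohort_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a validated cohort table as canonical TSV."""
    path = Path(path)
    # %.17g round-trips float64 exactly and is idempotent across write cycles
    validate_cohort(table).to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path
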