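"""Spectral preprocessing: co-registration, interferent correction, quality
filtering and fingerprint-region extraction.

The correction step follows the EMSC (extended multiplicative signal
correction) idea: each raw pixel spectrum ``s`` is regressed by ordinary
least squares onto a tissue reference, the interferent references and a
linear baseline,

    s ≈ a·tissue + b·paraffin + c·atmospheric + d0 + d1·axis_unit,

and the corrected spectrum is ``(s − b·paraffin − c·atmospheric − d0 −
d1·axis_unit) / a``, so the multiplicative coefficient ``a`` absorbs section
thickness.  Spectra whose fitted ``a`` is at or below a small positive floor
are flagged unusable rather than raising.

Tumour masks drawn on an adjacent stained section are aligned to the
infrared image via the amide-I (1650 cm⁻¹) absorbance map: an exhaustive
search over integer wrap-around translations maximises the Pearson
correlation between the shifted mask and the amide-I image thresholded at
its Otsu level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .errors import DataError, DegenerateInputError
from .spectra_io import AnnotationMask, HyperspectralCube
from .synthdata import ReferenceSpectra

__all__ = [
    "PreprocessConfig",
    "SpectralDataset",
    "amide1_image",
    "coregister",
    "correct_spectra",
    "quality_filter",
    "extract_fingerprint",
    "preprocess_patient",
    "write_dataset",
    "read_dataset",
]

FINGERPRINT_LOW = 1000.0
FINGERPRINT_HIGH = 1800.0
#: signal-poor band used for the noise estimate in the quality filter
NOISE_BAND = (1750.0, 1800.0)
#: fitted thickness coefficients at or below this floor mark a spectrum unusable
THICKNESS_FLOOR = 1e-3


@dataclass
class PreprocessConfig:
    """Tunables of the preprocessing stage.

    ``quality_min``/``quality_max`` bound the amide-I absorbance of a usable
    spectrum; ``snr_min`` is the minimum ratio of amide-I height to the noise
    estimated from first differences in the 1750–1800 cm⁻¹ band.
    ``thickness_correction`` selects whether the multiplicative coefficient
    divides the spectrum (``"divide"``) or is only used for flagging
    (``"none"``).
    """

    amide1_wavenumber: float = 1650.0
    quality_min: float = 0.1
    quality_max: float = 2.0
    snr_min: float = 3.0
    max_shift: int = 4
    interferent_set: tuple[str, ...] = ("paraffin", "atmospheric", "baseline")
    thickness_correction: str = "divide"

    def __post_init__(self) -> None:
        if not self.quality_min < self.quality_max:
            raise DataError("quality_min must be below quality_max")
        if self.max_shift < 0:
            raise DataError("max_shift must be non-negative")
        unknown = set(self.interferent_set) - {"paraffin", "atmospheric", "baseline"}
        if unknown:
            raise DataError(f"unknown interferents {sorted(unknown)}")
        if self.thickness_correction not in ("divide", "none"):
            raise DataError("thickness_correction must be 'divide' or 'none'")


@dataclass
class SpectralDataset:
    """Retained fingerprint-region spectra, one row per tumour datapoint.

    ``meta`` has columns ``patient_id, row, col`` aligned with ``matrix``
    rows; ``axis`` is the fingerprint wavenumber grid.
    """

    matrix: np.ndarray
    axis: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != len(self.meta):
            raise DataError("metadata rows must match spectra rows")
        if self.matrix.shape[1] != self.axis.size:
            raise DataError("axis length must match spectral columns")
        if not np.all(np.isfinite(self.matrix)):
            raise DataError("dataset contains non-finite values")

    @property
    def n_datapoints(self) -> int:
        return self.matrix.shape[0]

    def patients(self) -> list[str]:
        return list(pd.unique(self.meta["patient_id"]))


def concatenate_datasets(parts: Sequence[SpectralDataset]) -> SpectralDataset:
    """Stack per-patient datasets sharing one fingerprint axis."""
    if not parts:
        raise DegenerateInputError("no datasets to concatenate")
    axis = parts[0].axis
    for p in parts[1:]:
        if not np.array_equal(p.axis, axis):
            raise DataError("datasets have differing fingerprint axes")
    return SpectralDataset(
        matrix=np.vstack([p.matrix for p in parts]),
        axis=axis,
        meta=pd.concat([p.meta for p in parts], ignore_index=True),
    )


def write_dataset(dataset: SpectralDataset, path) -> None:
    """Serialise a SpectralDataset as TSV: meta columns, then one column per
    fingerprint wavenumber."""
    frame = pd.concat(
        [
            dataset.meta.reset_index(drop=True),
            pd.DataFrame(dataset.matrix, columns=[f"{w:g}" for w in dataset.axis]),
        ],
        axis=1,
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_dataset(path) -> SpectralDataset:
    """Read a SpectralDataset TSV written by :func:`write_dataset`."""
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    meta_cols = ["patient_id", "row", "col"]
    spectral = [c for c in frame.columns if c not in meta_cols]
    return SpectralDataset(
        matrix=frame[spectral].to_numpy(float),
        axis=np.array([float(c) for c in spectral]),
        meta=frame[meta_cols].copy(),
    )


def _nearest_index(axis: np.ndarray, wavenumber: float) -> int:
    axis = np.asarray(axis, dtype=float)
    if not axis[0] <= wavenumber <= axis[-1]:
        raise DataError(
            f"wavenumber {wavenumber} outside axis range [{axis[0]}, {axis[-1]}]"
        )
    return int(np.argmin(np.abs(axis - wavenumber)))


def amide1_image(cube: HyperspectralCube, wavenumber: float = 1650.0) -> np.ndarray:
    """Absorbance map at the axis point nearest ``wavenumber``."""
    return cube.data[:, :, _nearest_index(cube.axis, wavenumber)].copy()


def coregister(
    mask: AnnotationMask, image: np.ndarray, max_shift: int = 4
) -> tuple[AnnotationMask, tuple[int, int]]:
    """Align ``mask`` to ``image`` by an integer wrap-around translation.

    The image is binarised at its Otsu threshold; the offset within
    ``±max_shift`` maximising the Pearson correlation between the shifted
    mask and the binarised image wins.  Ties go to the smallest offset
    magnitude, then row offset before column offset.
    """
    grid = mask.grid
    image = np.asarray(image, dtype=float)
    if grid.shape != image.shape:
        raise DataError(f"mask shape {grid.shape} != image shape {image.shape}")
    if not grid.any():
        raise DegenerateInputError("all-zero mask cannot be co-registered")
    if np.ptp(image) == 0:
        target = np.zeros_like(image)
    else:
        target = (image >= threshold_otsu(image)).astype(float)

    offsets = sorted(
        (
            (dr, dc)
            for dr in range(-max_shift, max_shift + 1)
            for dc in range(-max_shift, max_shift + 1)
        ),
        key=lambda o: (o[0] ** 2 + o[1] ** 2, abs(o[0]), abs(o[1]), o[0], o[1]),
    )
    t_center = target - target.mean()
    t_norm = np.sqrt((t_center**2).sum())
    best: tuple[float, tuple[int, int]] | None = None
    for offset in offsets:
        shifted = np.roll(grid, offset, axis=(0, 1)).astype(float)
        s_center = shifted - shifted.mean()
        s_norm = np.sqrt((s_center**2).sum())
        corr = 0.0
        if s_norm > 0 and t_norm > 0:
            corr = float((s_center * t_center).sum() / (s_norm * t_norm))
        if best is None or corr > best[0] + 1e-12:
            best = (corr, offset)
    assert best is not None
    offset = best[1]
    aligned = AnnotationMask(
        grid=np.roll(grid, offset, axis=(0, 1)), patient_id=mask.patient_id
    )
    return aligned, offset


def _design_matrix(refs: ReferenceSpectra, interferent_set: Sequence[str]):
    columns = [refs.tissue_base]
    names = ["tissue"]
    if "paraffin" in interferent_set:
        columns.append(refs.paraffin)
        names.append("paraffin")
    if "atmospheric" in interferent_set:
        columns.append(refs.atmospheric)
        names.append("atmospheric")
    if "baseline" in interferent_set:
        columns.extend(refs.baseline_basis)
        names.extend(["baseline_offset", "baseline_slope"])
    return np.column_stack(columns), names


def correct_spectra(
    matrix: np.ndarray,
    refs: ReferenceSpectra,
    config: PreprocessConfig | None = None,
) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame, np.ndarray]:
    """EMSC-style correction of raw spectra (rows) on the reference axis.

    Returns ``(corrected, coefficients, standard_errors, usable)``; rows with
    thickness coefficient ``a`` at or below the floor are left NaN and
    flagged unusable (downstream quality filtering drops them).
    """
    if config is None:
        config = PreprocessConfig()
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if matrix.shape[1] != refs.axis.size:
        raise DataError("spectra and references must share one axis")

    design, names = _design_matrix(refs, config.interferent_set)
    coeffs, _, rank, _ = np.linalg.lstsq(design, matrix.T, rcond=None)
    coeffs = coeffs.T  # (n_spectra, n_terms)

    residuals = matrix - coeffs @ design.T
    dof = max(design.shape[0] - design.shape[1], 1)
    sigma2 = (residuals**2).sum(axis=1) / dof
    xtx_inv = np.linalg.inv(design.T @ design)
    se = np.sqrt(np.outer(sigma2, np.diag(xtx_inv)))

    a = coeffs[:, 0]
    usable = a > THICKNESS_FLOOR
    interference = coeffs[:, 1:] @ design[:, 1:].T if design.shape[1] > 1 else 0.0
    corrected = np.full_like(matrix, np.nan)
    cleaned = matrix[usable] - (
        interference[usable] if design.shape[1] > 1 else 0.0
    )
    if config.thickness_correction == "divide":
        corrected[usable] = cleaned / a[usable, None]
    else:
        corrected[usable] = cleaned
    coeff_df = pd.DataFrame(coeffs, columns=names)
    se_df = pd.DataFrame(se, columns=names)
    return corrected, coeff_df, se_df, usable


def quality_filter(
    matrix: np.ndarray, axis: np.ndarray, config: PreprocessConfig | None = None
) -> np.ndarray:
    """Boolean retention flags for spectra (rows) on ``axis``.

    A spectrum is retained iff its amide-I absorbance lies within
    ``[quality_min, quality_max]`` and its amide-I height divided by the
    noise estimate (std of first differences in the 1750–1800 cm⁻¹ band,
    divided by √2) reaches ``snr_min``.  Non-finite spectra never pass.
    """
    if config is None:
        config = PreprocessConfig()
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    axis = np.asarray(axis, dtype=float)
    finite = np.all(np.isfinite(matrix), axis=1)

    safe = np.where(np.isfinite(matrix), matrix, 0.0)
    amide = safe[:, _nearest_index(axis, config.amide1_wavenumber)]
    in_window = (amide >= config.quality_min) & (amide <= config.quality_max)

    band = (axis >= NOISE_BAND[0]) & (axis <= NOISE_BAND[1])
    if band.sum() >= 3:
        noise = np.std(np.diff(safe[:, band], axis=1), axis=1, ddof=0) / np.sqrt(2.0)
    else:
        noise = np.zeros(matrix.shape[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(noise > 0, amide / noise, np.inf)
    return finite & in_window & (snr >= config.snr_min)


def _fingerprint_columns(axis: np.ndarray) -> np.ndarray:
    return (axis >= FINGERPRINT_LOW) & (axis <= FINGERPRINT_HIGH)


def extract_fingerprint(
    cube: HyperspectralCube,
    mask: AnnotationMask,
    config: PreprocessConfig | None = None,
    corrected: np.ndarray | None = None,
) -> tuple[SpectralDataset, dict]:
    """Collect retained tumour-pixel spectra restricted to 1000–1800 cm⁻¹.

    ``corrected`` optionally supplies already-corrected spectra as a flat
    ``(n_pixels, n_wavenumbers)`` matrix in row-major pixel order; by default
    the cube's own values are used.  Returns the dataset plus a retention
    report; a patient losing every pixel yields an empty dataset and the
    report records the exclusion.
    """
    if config is None:
        config = PreprocessConfig()
    if cube.data.shape[:2] != mask.grid.shape:
        raise DataError("cube and mask have different spatial shapes")
    rows, cols = np.nonzero(mask.grid)
    if corrected is None:
        spectra = cube.data[rows, cols, :]
    else:
        corrected = np.asarray(corrected, dtype=float)
        spectra = corrected.reshape(*cube.data.shape)[rows, cols, :]
    flags = quality_filter(spectra, cube.axis, config)
    keep = _fingerprint_columns(cube.axis)
    dataset = SpectralDataset(
        matrix=spectra[flags][:, keep],
        axis=cube.axis[keep],
        meta=pd.DataFrame(
            {
                "patient_id": cube.patient_id,
                "row": rows[flags],
                "col": cols[flags],
            }
        ),
    )
    report = {
        "patient_id": cube.patient_id,
        "n_mask_pixels": int(len(rows)),
        "n_retained": int(flags.sum()),
        "excluded": bool(flags.sum() == 0),
    }
    return dataset, report


def preprocess_patient(
    cube: HyperspectralCube,
    mask: AnnotationMask,
    refs: ReferenceSpectra,
    config: PreprocessConfig | None = None,
) -> tuple[SpectralDataset, dict]:
    """Full per-patient chain: amide-I map → co-registration → EMSC-style
    correction of the mask pixels → quality filter → fingerprint extraction."""
    if config is None:
        config = PreprocessConfig()
    image = amide1_image(cube, config.amide1_wavenumber)
    aligned, offset = coregister(mask, image, config.max_shift)

    rows, cols = np.nonzero(aligned.grid)
    raw = cube.data[rows, cols, :]
    corrected, coeff_df, _, usable = correct_spectra(raw, refs, config)

    keep = _fingerprint_columns(cube.axis)
    flags = quality_filter(corrected, cube.axis, config) & usable
    dataset = SpectralDataset(
        matrix=corrected[flags][:, keep],
        axis=cube.axis[keep],
        meta=pd.DataFrame(
            {
                "patient_id": cube.patient_id,
                "row": rows[flags],
                "col": cols[flags],
            }
        ),
    )
    report = {
        "patient_id": cube.patient_id,
        "offset": [int(offset[0]), int(offset[1])],
        "n_mask_pixels": int(len(rows)),
        "n_usable": int(usable.sum()),
        "n_retained": int(flags.sum()),
        "excluded": bool(flags.sum() == 0),
        "median_thickness": float(np.median(coeff_df["tissue"][usable]))
        if usable.any()
        else float("nan"),
    }
    return dataset, report
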