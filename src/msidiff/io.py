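"""Data model and file I/O for the imaging pipeline.

The in-memory currency is small: a :class:`Spectrum` per pixel (profile m/z
and intensity arrays plus spatial coordinates and patient/region labels),
pandas DataFrames for pooled peak lists and downstream tables, and an
:class:`IonImage` grid for rendering per-group intensity maps.

Two spectra formats are supported: a long-format CSV
(``spectrum_id,patient_id,region,x,y,mz,intensity``) defined here because the
source instrument's native files are proprietary, and read-only imzML
(continuous or processed dialect) via pyimzml. imzML carries no patient or
region annotation, so an optional per-pixel annotation table supplies those
labels when reading imzML.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

REGIONS = ("diagnosis", "relapse")

SPECTRA_COLUMNS = ["spectrum_id", "patient_id", "region", "x", "y", "mz", "intensity"]
PEAK_COLUMNS = SPECTRA_COLUMNS + ["snr"]

__all__ = [
    "REGIONS",
    "SPECTRA_COLUMNS",
    "PEAK_COLUMNS",
    "Spectrum",
    "IonImage",
    "read_spectra",
    "spectra_to_frame",
    "write_table",
    "read_table",
    "render_ion_image",
]


@dataclass
class Spectrum:
    """One pixel's profile spectrum with its spatial and clinical labels."""

    spectrum_id: str
    patient_id: str
    region: str
    x: int
    y: int
    mz: np.ndarray
    intensity: np.ndarray

    def validate(self) -> "Spectrum":
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError(
                f"spectrum {self.spectrum_id}: mz and intensity must be 1-D and equal length"
            )
        if np.any(np.diff(self.mz) < 0):
            warnings.warn(
                f"spectrum {self.spectrum_id}: m/z not sorted, sorting", stacklevel=2
            )
            order = np.argsort(self.mz, kind="stable")
            self.mz, self.intensity = self.mz[order], self.intensity[order]
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError(f"spectrum {self.spectrum_id}: duplicate m/z values")
        if np.any(self.intensity < 0):
            bad = int(np.flatnonzero(self.intensity < 0)[0])
            raise ValueError(
                f"spectrum {self.spectrum_id}: negative intensity at index {bad}"
            )
        return self

    def clip_mass_range(self, lo: float, hi: float) -> "Spectrum":
        keep = (self.mz >= lo) & (self.mz <= hi)
        self.mz, self.intensity = self.mz[keep], self.intensity[keep]
        return self


@dataclass
class IonImage:
    """A per-pixel intensity grid for one peak group (NaN = missing pixel)."""

    group_id: str
    grid: np.ndarray
    x_offset: int = 0
    y_offset: int = 0
    patient_id: str | None = None
    region_mask: np.ndarray | None = None


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _spectra_from_frame(frame: pd.DataFrame) -> list[Spectrum]:
    missing = set(SPECTRA_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"spectra table missing columns: {sorted(missing)}")
    if frame[["spectrum_id", "patient_id", "region"]].isna().any().any():
        bad = int(frame[["spectrum_id", "patient_id", "region"]].isna().any(axis=1).idxmax())
        raise ValueError(f"missing patient/region label at row {bad}")
    neg = frame["intensity"] < 0
    if neg.any():
        raise ValueError(f"negative intensity at row {int(neg.idxmax())}")
    spectra = []
    for sid, sub in frame.groupby("spectrum_id", sort=False):
        spec = Spectrum(
            spectrum_id=str(sid),
            patient_id=str(sub["patient_id"].iloc[0]),
            region=str(sub["region"].iloc[0]),
            x=int(sub["x"].iloc[0]),
            y=int(sub["y"].iloc[0]),
            mz=sub["mz"].to_numpy(float),
            intensity=sub["intensity"].to_numpy(float),
        )
        spectra.append(spec.validate())
    _check_unique_pixels(spectra)
    return spectra


def _check_unique_pixels(spectra: Sequence[Spectrum]) -> None:
    seen: set[tuple] = set()
    for s in spectra:
        key = (s.patient_id, s.region, s.x, s.y)
        if key in seen:
            raise ValueError(f"duplicate pixel coordinates {key}")
        seen.add(key)


def read_spectra(
    path: str | Path,
    format: str | None = None,
    annotations: pd.DataFrame | str | Path | None = None,
) -> list[Spectrum]:
    """Read per-pixel spectra from CSV or imzML.

    Parameters
    ----------
    path : file path
    format : "csv" or "imzml"; inferred from the suffix when omitted.
    annotations : optional table (or CSV path) with columns
        x, y, patient_id, region — required to label imzML pixels, ignored
        for CSV input (the CSV carries its own labels).
    """
    path = Path(path)
    if format is None:
        format = "imzml" if path.suffix.lower() == ".imzml" else "csv"
    if format == "csv":
        return _spectra_from_frame(pd.read_csv(path))
    if format != "imzml":
        raise ValueError(f"unknown spectra format {format!r}")

    from pyimzml.ImzMLParser import ImzMLParser

    if annotations is not None and not isinstance(annotations, pd.DataFrame):
        annotations = pd.read_csv(annotations)
    lookup = {}
    if annotations is not None:
        for row in annotations.itertuples(index=False):
            lookup[(int(row.x), int(row.y))] = (str(row.patient_id), str(row.region))

    parser = ImzMLParser(str(path))
    spectra = []
    for i, (x, y, *_z) in enumerate(parser.coordinates):
        mz, inten = parser.getspectrum(i)
        # imzML coordinates are 1-based; the internal convention is 0-based
        px, py = int(x) - 1, int(y) - 1
        patient, region = lookup.get((px, py), ("sample", "unlabeled"))
        if annotations is not None and (px, py) not in lookup:
            warnings.warn(f"pixel ({px},{py}) missing from annotations", stacklevel=2)
        spec = Spectrum(
            spectrum_id=f"{patient}:{region}:{px}:{py}",
            patient_id=patient,
            region=region,
            x=px,
            y=py,
            mz=np.asarray(mz, float),
            intensity=np.asarray(inten, float),
        )
        spectra.append(spec.validate())
    _check_unique_pixels(spectra)
    return spectra


def spectra_to_frame(spectra: Iterable[Spectrum]) -> pd.DataFrame:
    """Long-format table of spectra (the CSV interchange layout)."""
    parts = []
    for s in spectra:
        parts.append(
            pd.DataFrame(
                {
                    "spectrum_id": s.spectrum_id,
                    "patient_id": s.patient_id,
                    "region": s.region,
                    "x": s.x,
                    "y": s.y,
                    "mz": s.mz,
                    "intensity": s.intensity,
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=SPECTRA_COLUMNS)
    return pd.concat(parts, ignore_index=True)[SPECTRA_COLUMNS]


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as CSV.

    Floats are serialized with 12 significant digits so a round trip
    reproduces values to better than 1e-9 relative; NaN becomes an empty
    field and is restored as missing on read. Column order is preserved.
    """
    records.to_csv(path, index=False, float_format="%.12g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# ion images
# ---------------------------------------------------------------------------


def _quantile_scale(values: np.ndarray) -> np.ndarray:
    """Map finite values to their normalized mid-ranks in [0, 1]."""
    from scipy.stats import rankdata

    out = np.full(values.shape, np.nan)
    mask = np.isfinite(values)
    n = int(mask.sum())
    if n == 0:
        return out
    if n == 1:
        out[mask] = 0.5
        return out
    out[mask] = (rankdata(values[mask]) - 1) / (n - 1)
    return out


def render_ion_image(
    matrix,
    group_id: str,
    scale: str = "linear",
    patient_id: str | None = None,
    path: str | Path | None = None,
) -> IonImage:
    """Build (and optionally save) the ion-intensity image of one peak group.

    The grid has one cell per pixel of the input spectra; missing pixels are
    NaN and rendered distinctly (grey). The color scale runs blue (lowest)
    to red (highest), monotone in intensity; ``scale="quantile"`` colors by
    normalized rank instead of raw value. Saving writes a PNG and a
    plain-text matrix (``<path>.txt``) side by side.
    """
    if scale not in {"linear", "quantile"}:
        raise ValueError(f"unknown scale {scale!r}")
    values = matrix.values
    if group_id not in values.index:
        available = ", ".join(map(str, values.index[:20]))
        raise KeyError(f"unknown group_id {group_id!r}; available: {available}")
    pixels = matrix.pixels
    row = values.loc[group_id]
    if patient_id is not None:
        keep = pixels["patient_id"] == patient_id
        pixels = pixels[keep]
        row = row[pixels.index]
    xs = pixels["x"].to_numpy(int)
    ys = pixels["y"].to_numpy(int)
    x0, y0 = xs.min(), ys.min()
    grid = np.full((ys.max() - y0 + 1, xs.max() - x0 + 1), np.nan)
    grid[ys - y0, xs - x0] = row.to_numpy(float)
    mask = np.full(grid.shape, "", dtype=object)
    mask[ys - y0, xs - x0] = pixels["region"].to_numpy()
    image = IonImage(
        group_id=str(group_id), grid=grid, x_offset=int(x0), y_offset=int(y0),
        patient_id=patient_id, region_mask=mask,
    )
    if path is not None:
        _save_ion_image(image, scale, Path(path))
    return image


def _save_ion_image(image: IonImage, scale: str, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shown = image.grid if scale == "linear" else _quantile_scale(image.grid)
    cmap = plt.get_cmap("jet").copy()
    cmap.set_bad("0.85")
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(np.ma.masked_invalid(shown), cmap=cmap, origin="lower",
                   interpolation="nearest")
    fig.colorbar(im, ax=ax, label="intensity" if scale == "linear" else "rank")
    ax.set_title(f"group {image.group_id}")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    np.savetxt(str(path) + ".txt", image.grid, fmt="%.6g")
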