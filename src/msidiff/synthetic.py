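"""Synthetic matched diagnosis/relapse imaging datasets and cohort tables.

Every downstream stage of the pipeline is exercised on data from this
module: per-pixel profile spectra with a known peptide panel, LC-MS/MS
identification tables, IHC measurement tables and survival cohorts, all
fully determined by a seed and accompanied by their ground truth.

The imaging generator emulates a matched-pair tryptic-peptide acquisition:
four patients, one diagnosis and one relapse region each, spectra over m/z
800-4000. Each pixel spectrum is a smooth exponential baseline plus
Gaussian peptide peaks (configurable FWHM — a generic reflectron-TOF
stand-in) at affine-drifted positions, with log-normal multiplicative pixel
abundance (median-log statistics are then natural and intensities stay
positive), four internal calibrant peaks, per-pixel dropout, and additive
Gaussian noise clipped at zero. A subset of panel peptides is planted at a
fold-change > 1 in the relapse regions; the default panel's five
differential entries carry the real tryptic sequences of the five
relapse-associated proteins this workflow was built to find (COL12A1,
FUBP1, PLEC, SLC4A1, TKT).

The default design is desk-scale: 20x20 pixels per region (3,200 pixels in
all) rather than a full-tissue acquisition; pooled-peak density filters are
rescaled accordingly via ``PipelineConfig.desk_profile``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .grouping import GroupIntensityMatrix
from .identify import PROTON_MASS, peptide_mh
from .io import Spectrum

__all__ = [
    "CalibrantTable",
    "DEFAULT_CALIBRANTS",
    "DEFAULT_PANEL",
    "PanelPeptide",
    "SimulationDesign",
    "GroundTruth",
    "simulate_msi",
    "iter_spectra",
    "simulate_group_matrix",
    "simulate_idtable",
    "simulate_ihc",
    "simulate_survival",
]


@dataclass(frozen=True)
class CalibrantTable:
    """Internal calibrant standards: (name, peptide sequence or fixed [M+H]+)."""

    entries: Tuple[Tuple[str, object], ...]

    def masses(self) -> np.ndarray:
        out = []
        for _name, seq_or_mass in self.entries:
            if isinstance(seq_or_mass, str):
                out.append(peptide_mh(seq_or_mass))
            else:
                out.append(float(seq_or_mass))
        return np.asarray(out)

    def __len__(self) -> int:
        return len(self.entries)


# The four peptide standards sprayed onto every section. The Dynorphin A
# fragment in use is instrument-lab specific; 1-13 is the common choice and
# the table is fully configurable.
DEFAULT_CALIBRANTS = CalibrantTable(
    (
        ("Angiotensin I", "DRVYIHPFHL"),
        ("[Glu1]-Fibrinopeptide B", "EGVNDNEEGFFSAR"),
        ("Dynorphin A (1-13)", "YGGFLRRIRPKLK"),
        ("ACTH (1-24)", "SYSMEHFRWGKPVGKKRRPVKVYP"),
    )
)


class PanelPeptide(BaseModel):
    """One panel entry: a tryptic peptide, its protein, and its planted effect."""

    sequence: str
    protein_accession: str
    protein_name: str = ""
    base_abundance: float = Field(100.0, gt=0)
    fold_change: float = Field(1.0, gt=0)

    @model_validator(mode="after")
    def _default_name(self) -> "PanelPeptide":
        if not self.protein_name:
            object.__setattr__(self, "protein_name", self.protein_accession)
        return self


_DIFFERENTIAL = [
    ("GPGDLEAPSNLVISER", "COL12A1", "Collagen alpha-1(XII) chain"),
    ("IGGNEGIDVPIPR", "FUBP1", "Far upstream element-binding protein 1"),
    ("VPLDEALQRGTVDAR", "PLEC", "Plectin"),
    ("VLLPLIFR", "SLC4A1", "Band 3 anion transport protein"),
    ("VLDPFTIKPLDR", "TKT", "Transketolase"),
]

# Background tryptic-like peptides, generated once with pairwise [M+H]+
# separation > 1 Da from each other, the markers and the calibrants.
_BACKGROUND = [
    "DTHANYR", "NTVWMNK", "DYLVFVR", "SHPWRPR", "DVDFLHMK", "EDFYHLVK",
    "VGQSAQYHNK", "AFQPRWEQK", "VQYHKTGEER", "FDAVLTPQHQR", "AQELRHSNHLK",
    "RFAYFLAVLRK", "GMMVRMSVNVER", "GLGKPFLLGNARAR", "TTMLFLHLLLLPK",
    "GWVLFFQYPFYHR", "QDWAVVKLNLRRNR", "LGMLTFDGEHNRWPK", "SGFSNGEFWDNWEVAR",
    "MGFLRDLSFMGVKQPGK", "RDTLNNNYSHWAGSMSK", "QLLNAHNQWEDTYTGVK",
    "HFTGGYPRWLNPAFFNR", "KPRDQMGNGNLFNTHTFR", "AYNRVLVQLSLRFWRLR",
]


def _default_panel() -> list[PanelPeptide]:
    panel = [
        PanelPeptide(
            sequence=seq, protein_accession=acc, protein_name=name,
            base_abundance=100.0, fold_change=3.0,
        )
        for seq, acc, name in _DIFFERENTIAL
    ]
    for i, seq in enumerate(_BACKGROUND):
        panel.append(
            PanelPeptide(
                sequence=seq,
                protein_accession=f"BGP{i + 1:02d}",
                base_abundance=40.0 + (i * 13) % 120,
                fold_change=1.0,
            )
        )
    return panel


class SimulationDesign(BaseModel):
    """Study design of one synthetic matched-pair imaging experiment."""

    model_config = {"arbitrary_types_allowed": True}

    n_patients: int = Field(4, ge=1)
    grid_shape: Tuple[int, int] = (20, 20)  # (ny, nx) pixels per region
    mass_range: Tuple[float, float] = (800.0, 4000.0)
    axis_step: float = Field(0.01, gt=0, description="profile axis spacing (Da)")
    panel: list[PanelPeptide] = Field(default_factory=_default_panel)
    noise_cv: float = Field(0.2, ge=0, description="per-peak multiplicative CV")
    pixel_gain_cv: float = Field(0.2, ge=0, description="shared per-pixel gain CV")
    additive_noise_sd: float = Field(1.0, ge=0)
    baseline_amplitude: float = Field(20.0, ge=0)
    baseline_scale: float = Field(600.0, gt=0, description="baseline decay length (Da)")
    drift_slope: float = Field(1.00001, gt=0)
    drift_offset: float = 0.02  # Da
    dropout_rate: float = Field(0.05, ge=0, lt=1)
    peak_fwhm: float = Field(0.1, gt=0, description="Gaussian peak FWHM (Da)")
    calibrants: CalibrantTable = DEFAULT_CALIBRANTS
    calibrant_intensity: float = Field(150.0, gt=0)
    id_error_ppm: float = Field(0.0, ge=0, description="LC-MS/MS m/z error sd (ppm)")
    seed: int = 0

    @field_validator("calibrants", mode="before")
    @classmethod
    def _coerce_calibrants(cls, v):
        if isinstance(v, CalibrantTable):
            return v
        if isinstance(v, dict):
            v = v.get("entries", v)
        return CalibrantTable(tuple((str(name), m) for name, m in v))

    @model_validator(mode="after")
    def _check(self) -> "SimulationDesign":
        ny, nx = self.grid_shape
        if ny < 2 or nx < 2:
            raise ValueError(f"grid shape must be >= 2x2, got {self.grid_shape}")
        lo, hi = self.mass_range
        if not lo < hi:
            raise ValueError(f"mass_range must be increasing, got {self.mass_range}")
        for pep in self.panel:
            mz = peptide_mh(pep.sequence)
            if not (lo + 5 * self.peak_fwhm <= mz <= hi - 5 * self.peak_fwhm):
                raise ValueError(
                    f"peptide {pep.sequence!r} [M+H]+ {mz:.3f} outside mass range "
                    f"{self.mass_range}"
                )
        if len(self.calibrants) < 2:
            raise ValueError("at least 2 calibrants required for affine recalibration")
        for (name, _), mass in zip(self.calibrants.entries, self.calibrants.masses()):
            if not lo <= mass <= hi:
                raise ValueError(
                    f"calibrant {name!r} [M+H]+ {mass:.3f} outside mass range "
                    f"{self.mass_range}"
                )
        return self

    @property
    def n_differential(self) -> int:
        return sum(1 for p in self.panel if p.fold_change != 1.0)

    @property
    def n_pixels(self) -> int:
        ny, nx = self.grid_shape
        return self.n_patients * 2 * ny * nx

    def peptide_mzs(self) -> np.ndarray:
        return np.asarray([peptide_mh(p.sequence) for p in self.panel])

    def patients(self) -> list[str]:
        return [f"P{i + 1}" for i in range(self.n_patients)]

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        data = self.model_dump(exclude={"calibrants"})
        data["calibrants"] = [list(e) for e in self.calibrants.entries]
        data["mass_range"] = list(data["mass_range"])
        data["grid_shape"] = list(data["grid_shape"])
        return data

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationDesign":
        import yaml

        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class GroundTruth:
    """What was planted: per-peptide truth and the global mass drift."""

    peptides: pd.DataFrame  # sequence, protein_accession, mz, base, fold, differential
    drift_slope: float
    drift_offset: float

    @property
    def differential_proteins(self) -> list[str]:
        sub = self.peptides[self.peptides["differential"]]
        return sorted(sub["protein_accession"].unique())


def _truth(design: SimulationDesign) -> GroundTruth:
    rows = [
        {
            "sequence": p.sequence,
            "protein_accession": p.protein_accession,
            "protein_name": p.protein_name,
            "mz": peptide_mh(p.sequence),
            "base_abundance": p.base_abundance,
            "fold_change": p.fold_change,
            "differential": p.fold_change != 1.0,
        }
        for p in design.panel
    ]
    return GroundTruth(
        peptides=pd.DataFrame(rows),
        drift_slope=design.drift_slope,
        drift_offset=design.drift_offset,
    )


def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


def iter_spectra(design: SimulationDesign, seed: int | None = None) -> Iterator[Spectrum]:
    """Stream the design's pixel spectra one at a time (seed-deterministic).

    Identical to ``simulate_msi(...)[0]`` but without materializing all
    spectra — a full desk-scale design is a few thousand profile spectra.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    lo, hi = design.mass_range
    axis = np.arange(lo, hi + design.axis_step / 2, design.axis_step)
    baseline = design.baseline_amplitude * np.exp(-(axis - lo) / design.baseline_scale)
    sigma_peak = design.peak_fwhm / 2.3548200450309493  # FWHM -> sd
    sigma_ln = _lognormal_sigma(design.noise_cv)
    sigma_gain = _lognormal_sigma(design.pixel_gain_cv)

    pep_mz = design.peptide_mzs()
    pep_base = np.asarray([p.base_abundance for p in design.panel])
    pep_fold = np.asarray([p.fold_change for p in design.panel])
    cal_mz = design.calibrants.masses()
    ny, nx = design.grid_shape
    half_w = 5 * sigma_peak

    def add_peak(y: np.ndarray, center: float, amp: float) -> None:
        i0 = np.searchsorted(axis, center - half_w)
        i1 = np.searchsorted(axis, center + half_w)
        if i1 > i0:
            y[i0:i1] += amp * np.exp(-0.5 * ((axis[i0:i1] - center) / sigma_peak) ** 2)

    for patient in design.patients():
        for region in ("diagnosis", "relapse"):
            for yy in range(ny):
                for xx in range(nx):
                    gain = (
                        rng.lognormal(-0.5 * sigma_gain**2, sigma_gain)
                        if design.pixel_gain_cv > 0
                        else 1.0
                    )
                    y = baseline * gain
                    amps = gain * pep_base * np.where(region == "relapse", pep_fold, 1.0)
                    if design.noise_cv > 0:
                        amps = amps * rng.lognormal(
                            -0.5 * sigma_ln**2, sigma_ln, len(amps)
                        )
                    present = (
                        rng.random(len(amps)) >= design.dropout_rate
                        if design.dropout_rate > 0
                        else np.ones(len(amps), bool)
                    )
                    cal_amps = np.full(len(cal_mz), gain * design.calibrant_intensity)
                    if design.noise_cv > 0:
                        cal_amps = cal_amps * rng.lognormal(
                            -0.5 * sigma_ln**2, sigma_ln, len(cal_amps)
                        )
                    for mz0, amp, ok in zip(pep_mz, amps, present):
                        if ok:
                            add_peak(
                                y,
                                design.drift_slope * mz0 + design.drift_offset,
                                amp,
                            )
                    for mz0, amp in zip(cal_mz, cal_amps):
                        add_peak(
                            y, design.drift_slope * mz0 + design.drift_offset, amp
                        )
                    if design.additive_noise_sd > 0:
                        y = y + rng.normal(0, design.additive_noise_sd, len(axis))
                        np.clip(y, 0, None, out=y)
                    yield Spectrum(
                        spectrum_id=f"{patient}:{region}:{xx}:{yy}",
                        patient_id=patient,
                        region=region,
                        x=xx,
                        y=yy,
                        mz=axis,
                        intensity=y,
                    )


def simulate_msi(
    design: SimulationDesign, seed: int | None = None
) -> tuple[list[Spectrum], GroundTruth]:
    """Generate the design's full spectrum collection plus its ground truth."""
    return list(iter_spectra(design, seed)), _truth(design)


def simulate_group_matrix(
    design: SimulationDesign, seed: int | None = None
) -> tuple[GroupIntensityMatrix, GroundTruth]:
    """Per-pixel peptide intensities from the abundance model directly.

    Skips profile-spectrum rendering and peak detection: the returned
    matrix holds the same log-normal per-pixel abundances (with dropout)
    that the spectral generator would plant as peak amplitudes, one row per
    panel peptide. Intended for replicate-level statistical calibration
    studies where only the intensity model matters.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    sigma_ln = _lognormal_sigma(design.noise_cv)
    sigma_gain = _lognormal_sigma(design.pixel_gain_cv)
    ny, nx = design.grid_shape
    px_per_region = ny * nx
    pep_base = np.asarray([p.base_abundance for p in design.panel])
    pep_fold = np.asarray([p.fold_change for p in design.panel])
    n_pep = len(design.panel)

    cols, col_meta, blocks = [], [], []
    for patient in design.patients():
        for region in ("diagnosis", "relapse"):
            amps = pep_base * (pep_fold if region == "relapse" else 1.0)
            block = np.tile(amps[:, None], (1, px_per_region)).astype(float)
            if design.noise_cv > 0:
                block = block * rng.lognormal(
                    -0.5 * sigma_ln**2, sigma_ln, (n_pep, px_per_region)
                )
            if design.pixel_gain_cv > 0:
                block = block * rng.lognormal(
                    -0.5 * sigma_gain**2, sigma_gain, px_per_region
                )[None, :]
            if design.dropout_rate > 0:
                block = block * (
                    rng.random((n_pep, px_per_region)) >= design.dropout_rate
                )
            blocks.append(block)
            for k in range(px_per_region):
                xx, yy = k % nx, k // nx
                cols.append(f"{patient}:{region}:{xx}:{yy}")
                col_meta.append((patient, region, xx, yy))
    truth = _truth(design)
    values = pd.DataFrame(
        np.hstack(blocks),
        index=pd.Index(
            [f"G{k + 1:04d}" for k in range(n_pep)], name="group_id"
        ),
        columns=cols,
    )
    pixels = pd.DataFrame(
        col_meta, columns=["patient_id", "region", "x", "y"],
        index=pd.Index(cols, name="spectrum_id"),
    )
    groups = pd.DataFrame(
        {"centroid_mz": truth.peptides["mz"].to_numpy(), "n_peaks": values.shape[1]},
        index=values.index,
    )
    return GroupIntensityMatrix(values=values, pixels=pixels, groups=groups), truth


def simulate_idtable(
    design: SimulationDesign,
    ground_truth: GroundTruth | None = None,
    charge_states: Sequence[int] = (1, 2, 3),
    seed: int | None = None,
) -> pd.DataFrame:
    """LC-MS/MS identification table for the design's peptide panel.

    For each panel peptide, pool and charge state, the observed m/z is
    (M + z * proton) / z plus Gaussian measurement error of
    ``design.id_error_ppm`` (0 by default: identifications are exact and
    identity transfer is limited only by the imaging centroids).
    """
    if not set(charge_states) <= {1, 2, 3, 4}:
        raise ValueError(f"charge states must be within 1..4, got {charge_states}")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    truth = ground_truth or _truth(design)
    rows = []
    for rec in truth.peptides.itertuples(index=False):
        neutral = rec.mz - PROTON_MASS
        for pool in ("diagnosis", "relapse"):
            for z in charge_states:
                mz = (neutral + z * PROTON_MASS) / z
                if design.id_error_ppm > 0:
                    mz += rng.normal(0, design.id_error_ppm * mz / 1e6)
                rows.append(
                    {
                        "sequence": rec.sequence,
                        "charge": z,
                        "observed_mz": mz,
                        "protein_accession": rec.protein_accession,
                        "protein_name": rec.protein_name,
                        "sample_pool": pool,
                        "score": 50.0,
                    }
                )
    return pd.DataFrame(rows)


def simulate_ihc(
    n_pairs: int = 4,
    effect: float = 50.0,
    within_sd: float = 15.0,
    mean_diagnosis: float = 120.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Paired diagnosis/relapse IHC measurement table.

    Each patient contributes 5-6 scored areas per timepoint (alternating).
    An area's staining is summarized by a latent mean intensity bin
    lambda in [0, 3]; its reported intensity-bin fractions are the exact
    Binomial(3, lambda/3) probabilities, so the area H-score is exactly
    100 * lambda. Relapse areas have lambda shifted by ``effect``/100, with
    between-area Gaussian jitter of sd ``within_sd``/100; in the
    ``within_sd=0`` limit every paired difference equals ``effect``
    exactly. Stroma rows carry positive/total pixel counts with positivity
    lambda/3.
    """
    if not (0 <= mean_diagnosis <= 300 and 0 <= mean_diagnosis + effect <= 300):
        raise ValueError(
            f"H-scores must stay in [0, 300]: diagnosis {mean_diagnosis}, "
            f"relapse {mean_diagnosis + effect}"
        )
    rng = np.random.default_rng(seed)
    rows = []
    total_px = 10000
    for i in range(n_pairs):
        patient = f"P{i + 1}"
        n_areas = 5 + (i % 2)  # 5-6 areas per tissue
        for timepoint, mean_h in (
            ("diagnosis", mean_diagnosis),
            ("relapse", mean_diagnosis + effect),
        ):
            for a in range(n_areas):
                h = mean_h + (rng.normal(0, within_sd) if within_sd > 0 else 0.0)
                lam = float(np.clip(h / 100.0, 0.0, 3.0))
                p = lam / 3.0
                f = [
                    (1 - p) ** 3,
                    3 * p * (1 - p) ** 2,
                    3 * p * p * (1 - p),
                    p**3,
                ]
                rows.append(
                    {
                        "patient_id": patient, "timepoint": timepoint,
                        "area_id": a, "compartment": "epithelial",
                        "bin0": f[0], "bin1": f[1], "bin2": f[2], "bin3": f[3],
                        "positive": np.nan, "total": np.nan,
                    }
                )
                rows.append(
                    {
                        "patient_id": patient, "timepoint": timepoint,
                        "area_id": a, "compartment": "stroma",
                        "bin0": np.nan, "bin1": np.nan, "bin2": np.nan, "bin3": np.nan,
                        "positive": int(round(p * total_px)), "total": total_px,
                    }
                )
    return pd.DataFrame(rows)


def simulate_survival(
    n: int = 200,
    true_hr: float = 2.0,
    censor_rate: float = 0.0,
    marker_link: Literal["median_threshold"] = "median_threshold",
    baseline_hazard: float = 1.0 / 12.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Survival cohort with a marker-linked hazard.

    Event times are exponential with baseline hazard (per month); subjects
    whose marker is at or above the cohort median have their hazard
    multiplied by ``true_hr``. Censoring is independent exponential with
    its rate set so the expected censored fraction is ``censor_rate``
    (0 means every subject has an event).
    """
    if true_hr <= 0:
        raise ValueError(f"true_hr must be > 0, got {true_hr}")
    if not 0 <= censor_rate < 1:
        raise ValueError(f"censor_rate must be in [0, 1), got {censor_rate}")
    rng = np.random.default_rng(seed)
    marker = rng.lognormal(0.0, 0.5, n)
    high = marker >= np.median(marker)
    hazard = baseline_hazard * np.where(high, true_hr, 1.0)
    event_time = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        censor_hazard = hazard * censor_rate / (1.0 - censor_rate)
        censor_time = rng.exponential(1.0 / censor_hazard)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    return pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:04d}" for i in range(n)],
            "time": time,
            "event": (event_time <= censor_time).astype(int),
            "marker": marker,
            "group": np.where(high, "high", "low"),
        }
    )
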