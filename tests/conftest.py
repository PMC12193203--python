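import numpy as np
import pytest

from msidiff.io import Spectrum
from msidiff.synthetic import CalibrantTable, PanelPeptide, SimulationDesign


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_spectrum(mz, intensity, sid="s1", patient="P1", region="diagnosis", x=0, y=0):
    return Spectrum(sid, patient, region, x, y,
                    np.asarray(mz, float), np.asarray(intensity, float)).validate()


@pytest.fixture
def gaussian_spectrum():
    """Factory: spectrum with Gaussian peaks on a dense axis."""

    def build(centers, amps, sigma=0.05, lo=900.0, hi=1100.0, step=0.01,
              noise_sd=0.0, baseline=0.0, seed=0, **kwargs):
        rng = np.random.default_rng(seed)
        axis = np.arange(lo, hi + step / 2, step)
        y = np.full(len(axis), float(baseline))
        for c, a in zip(np.atleast_1d(centers), np.atleast_1d(amps)):
            y += a * np.exp(-0.5 * ((axis - c) / sigma) ** 2)
        if noise_sd > 0:
            y += rng.normal(0, noise_sd, len(axis))
            y = np.clip(y, 0, None)
        return make_spectrum(axis, y, **kwargs)

    return build


def make_tiny_design():
    """Small, fast design: 3 patients, 6x6 px/region, 6-peptide panel."""
    panel = [
        PanelPeptide(sequence="VLLPLIFR", protein_accession="SLC4A1",
                     base_abundance=100.0, fold_change=3.0),
        PanelPeptide(sequence="IGGNEGIDVPIPR", protein_accession="FUBP1",
                     base_abundance=100.0, fold_change=3.0),
        PanelPeptide(sequence="VLDPFTIKPLDR", protein_accession="TKT",
                     base_abundance=100.0, fold_change=3.0),
        PanelPeptide(sequence="DTHANYR", protein_accession="BG1",
                     base_abundance=80.0),
        PanelPeptide(sequence="EDFYHLVK", protein_accession="BG2",
                     base_abundance=60.0),
        PanelPeptide(sequence="FDAVLTPQHQR", protein_accession="BG3",
                     base_abundance=120.0),
    ]
    calibrants = CalibrantTable((("Angiotensin I", "DRVYIHPFHL"),
                                 ("cal-1250", 1250.0)))
    return SimulationDesign(
        n_patients=3, grid_shape=(6, 6), mass_range=(850.0, 1500.0),
        panel=panel, calibrants=calibrants, seed=7,
    )


@pytest.fixture
def tiny_design():
    return make_tiny_design()
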