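"""End-to-end discovery pipeline.

Chains the stages — preprocessing, DBSCAN peak grouping, median-log
ranking, per-patient ROC discrimination, identity transfer and
protein-level aggregation — over a spectrum collection (or a synthetic
design, streamed pixel by pixel) and one LC-MS/MS identification table.
Per-stage row counts, the configuration hash and the seed are logged so a
run can be audited and reproduced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .config import PipelineConfig
from .discriminate import call_differentials
from .grouping import GroupIntensityMatrix, build_matrix, dbscan_mz, filter_groups, rank_groups
from .identify import call_proteins, match_groups
from .io import Spectrum
from .preprocess import preprocess_spectra
from .synthetic import GroundTruth, SimulationDesign, iter_spectra, simulate_idtable

logger = logging.getLogger("msidiff")

__all__ = ["DiscoveryResult", "run_discovery"]


@dataclass
class DiscoveryResult:
    """All tables produced by one discovery run."""

    peaks: pd.DataFrame
    recalibration: pd.DataFrame
    norm_factors: pd.DataFrame
    groups: list
    matrix: GroupIntensityMatrix
    ranked: pd.DataFrame
    ranked_detail: pd.DataFrame
    roc: pd.DataFrame
    calls: pd.DataFrame
    call_summary: pd.DataFrame
    matches: pd.DataFrame
    proteins: pd.DataFrame
    conflicts: pd.DataFrame
    truth: Optional[GroundTruth] = None


def run_discovery(
    source: SimulationDesign | Iterable[Spectrum],
    config: PipelineConfig,
    id_table: pd.DataFrame | None = None,
    calibrant_masses=None,
    seed: int | None = None,
) -> DiscoveryResult:
    """Run the full discovery pipeline.

    ``source`` is either a synthetic design (spectra are streamed and the
    matching LC-MS/MS table is generated unless one is supplied) or an
    iterable of spectra, in which case ``id_table`` drives identity
    transfer (skipped when absent) and ``calibrant_masses`` enables
    recalibration.
    """
    logger.info("run_discovery: config %s seed %s", config.config_hash(), seed)
    truth = None
    if isinstance(source, SimulationDesign):
        design = source
        truth = None
        spectra = iter_spectra(design, seed)
        if calibrant_masses is None:
            calibrant_masses = design.calibrants.masses()
        if id_table is None:
            id_table = simulate_idtable(design, seed=seed)
        from .synthetic import _truth

        truth = _truth(design)
    else:
        spectra = source

    peaks, fits, factors = preprocess_spectra(spectra, config, calibrant_masses)
    logger.info("preprocess: %d peaks from %d spectra",
                len(peaks), peaks["spectrum_id"].nunique() if len(peaks) else 0)

    groups = dbscan_mz(peaks, config.dbscan_eps, config.dbscan_min_density)
    logger.info("dbscan: %d groups", len(groups))
    groups = filter_groups(groups, config.min_group_size)

    matrix = build_matrix(groups, peaks)
    ranked, ranked_detail = rank_groups(matrix, config.log_offset)
    roc, calls, call_summary = call_differentials(
        matrix, auc_min=config.auc_min, q_max=config.q_max,
        hotspot_quantile=config.hotspot_quantile,
    )
    logger.info("discriminate: %d passing calls", int(calls["passes"].sum()))

    if id_table is not None:
        matches = match_groups(
            pd.DataFrame(
                {
                    "group_id": [g.group_id for g in groups],
                    "centroid_mz": [g.centroid_mz for g in groups],
                }
            ),
            id_table,
            tolerance=config.match_tolerance,
        )
        proteins, conflicts = call_proteins(matches, calls, config.min_patients)
    else:
        matches = pd.DataFrame()
        proteins = pd.DataFrame()
        conflicts = pd.DataFrame()
    logger.info("identify: %d matches, %d protein calls", len(matches), len(proteins))

    return DiscoveryResult(
        peaks=peaks, recalibration=fits, norm_factors=factors, groups=groups,
        matrix=matrix, ranked=ranked, ranked_detail=ranked_detail, roc=roc,
        calls=calls, call_summary=call_summary, matches=matches,
        proteins=proteins, conflicts=conflicts, truth=truth,
    )
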