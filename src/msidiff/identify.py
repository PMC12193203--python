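"""Identity transfer from LC-MS/MS identifications to imaging peak groups.

MALDI imaging resolves tryptic peptides as singly protonated ions but carries
no sequence information. Identities are borrowed from a parallel LC-MS/MS run
of the same tissue digests: every multiply charged LC-MS/MS observation is
deconvoluted to its singly protonated m/z and compared to the centroid of each
imaging peak group; agreement within a mass tolerance (default ±0.25 Da,
boundary inclusive) transfers the peptide — and hence protein — identity.
Protein-level calls then require consistent differential support across a
minimum number of patients.

Matching deliberately compares *experimental* LC-MS/MS m/z to *experimental*
group centroids: uncorrected systematic offsets cancel between the two
measurements, whereas theoretical monoisotopic masses can sit well outside the
tolerance. The theoretical [M+H]+ is still computed and reported per match as
a QC annotation (``delta_theoretical``).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PROTON_MASS",
    "WATER_MASS",
    "RESIDUE_MASSES",
    "peptide_mh",
    "to_singly_protonated",
    "match_groups",
    "call_proteins",
]

# Monoisotopic residue masses (Da), standard 20 amino acids.
# Values from the IUPAC 2021 atomic masses via elemental composition,
# rounded to 5-6 decimals; I and L are isobaric.
RESIDUE_MASSES: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

WATER_MASS = 18.010565
PROTON_MASS = 1.007276

#: Supported variable modifications and their monoisotopic mass shifts (Da).
MODIFICATION_MASSES: dict[str, float] = {"oxidation(M)": 15.994915}


def peptide_mh(sequence: str, modifications: Sequence[str] | None = None) -> float:
    """Monoisotopic [M+H]+ of a peptide sequence in Da.

    Sum of residue monoisotopic masses plus one water (termini) plus one
    proton, plus any variable-modification shifts. Only methionine oxidation
    is supported as a modification (``"oxidation(M)"``), optionally repeated.

    Raises
    ------
    ValueError
        On an unknown residue letter (the message names its position) or an
        unsupported modification, or more oxidations than methionines.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    total = WATER_MASS + PROTON_MASS
    for pos, letter in enumerate(sequence):
        try:
            total += RESIDUE_MASSES[letter]
        except KeyError:
            raise ValueError(
                f"unknown residue {letter!r} at position {pos} in {sequence!r}"
            ) from None
    if modifications:
        n_ox = 0
        for mod in modifications:
            if mod not in MODIFICATION_MASSES:
                raise ValueError(f"unsupported modification {mod!r}")
            n_ox += 1
            total += MODIFICATION_MASSES[mod]
        if n_ox > sequence.count("M"):
            raise ValueError(
                f"{n_ox} oxidation(M) modifications but only "
                f"{sequence.count('M')} methionines in {sequence!r}"
            )
    return total


def to_singly_protonated(observed_mz: float, charge: int) -> float:
    """Deconvolute an observed m/z at a given charge to its [M+H]+ (Da).

    M = z * observed_mz - z * proton; returns M + proton. Errors on a
    non-positive neutral mass or charge < 1.
    """
    charge = int(charge)
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    neutral = charge * observed_mz - charge * PROTON_MASS
    if neutral <= 0:
        raise ValueError(
            f"non-positive neutral mass from m/z {observed_mz} at charge {charge}"
        )
    return neutral + PROTON_MASS


def _groups_frame(groups) -> pd.DataFrame:
    """Accept a list of PeakGroup-like objects or a DataFrame."""
    if isinstance(groups, pd.DataFrame):
        need = {"group_id", "centroid_mz"}
        missing = need - set(groups.columns)
        if missing:
            raise ValueError(f"groups table missing columns: {sorted(missing)}")
        return groups[["group_id", "centroid_mz"]].copy()
    return pd.DataFrame(
        {
            "group_id": [g.group_id for g in groups],
            "centroid_mz": [g.centroid_mz for g in groups],
        }
    )


def match_groups(
    groups,
    ids: pd.DataFrame,
    tolerance: float = 0.25,
    pool: str | None = None,
) -> pd.DataFrame:
    """Match LC-MS/MS identifications to peak groups by m/z tolerance.

    Every (group, identification) pair whose singly protonated experimental
    m/z lies within ``tolerance`` Da of the group centroid (boundary
    inclusive) yields one match record. All matches are reported — a group
    may match several peptides and vice versa — sorted by |delta_mz| within
    each group and annotated with a within-group rank.

    Parameters
    ----------
    groups : list of PeakGroup or DataFrame with group_id / centroid_mz
    ids : DataFrame
        Columns sequence, charge, observed_mz, protein_accession and
        optionally protein_name, sample_pool, score.
    tolerance : float
        Match tolerance in Da (> 0).
    pool : str, optional
        If given, only identifications with this ``sample_pool`` are used
        (pool-specific matching); default uses all rows.
    """
    if tolerance <= 0:
        raise ValueError(f"tolerance must be > 0, got {tolerance}")
    gframe = _groups_frame(groups)
    idtab = ids
    if pool is not None and "sample_pool" in idtab.columns:
        idtab = idtab[idtab["sample_pool"] == pool]
    cols = [
        "group_id", "centroid_mz", "sequence", "charge", "observed_mz",
        "mh_experimental", "delta_mz", "delta_theoretical",
        "protein_accession", "protein_name", "sample_pool", "match_rank",
    ]
    if gframe.empty or idtab.empty:
        return pd.DataFrame(columns=cols)

    mh = np.array(
        [to_singly_protonated(m, z) for m, z in zip(idtab["observed_mz"], idtab["charge"])]
    )
    mh_theory = np.array([peptide_mh(s) for s in idtab["sequence"]])
    centroids = gframe["centroid_mz"].to_numpy(float)
    # all-pairs |delta| <= tolerance, boundary inclusive
    delta = mh[None, :] - centroids[:, None]
    gi, ii = np.nonzero(np.abs(delta) <= tolerance + 1e-12)
    rows = pd.DataFrame(
        {
            "group_id": gframe["group_id"].to_numpy()[gi],
            "centroid_mz": centroids[gi],
            "sequence": idtab["sequence"].to_numpy()[ii],
            "charge": idtab["charge"].to_numpy()[ii],
            "observed_mz": idtab["observed_mz"].to_numpy()[ii],
            "mh_experimental": mh[ii],
            "delta_mz": delta[gi, ii],
            "delta_theoretical": mh_theory[ii] - centroids[gi],
            "protein_accession": idtab["protein_accession"].to_numpy()[ii],
            "protein_name": (
                idtab["protein_name"].to_numpy()[ii]
                if "protein_name" in idtab.columns
                else idtab["protein_accession"].to_numpy()[ii]
            ),
            "sample_pool": (
                idtab["sample_pool"].to_numpy()[ii]
                if "sample_pool" in idtab.columns
                else "all"
            ),
        }
    )
    rows["_abs"] = rows["delta_mz"].abs()
    rows = rows.sort_values(["group_id", "_abs", "sequence"], kind="stable")
    rows["match_rank"] = rows.groupby("group_id").cumcount() + 1
    return rows.drop(columns="_abs").reset_index(drop=True)[cols]


def call_proteins(
    matches: pd.DataFrame,
    differential_calls: pd.DataFrame,
    min_patients: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate matched differential peak groups to protein-level calls.

    A protein is supported in direction *d* by patient *p* when at least one
    of its matched groups passes the differential-call thresholds for *p* in
    direction *d*. Proteins whose passing support is confined to a single
    direction and reaches ``min_patients`` patients are called; proteins with
    passing support in both directions are reported separately as conflicts
    and receive no directional call.

    Returns
    -------
    (calls, conflicts) : tuple of DataFrame
        ``calls`` has one row per (protein, direction) meeting the support
        threshold; ``conflicts`` lists proteins with opposing support.
    """
    if min_patients < 1:
        raise ValueError(f"min_patients must be >= 1, got {min_patients}")
    call_cols = [
        "protein_accession", "protein_name", "direction",
        "n_patients_support", "patients", "groups", "peptides",
    ]
    if matches.empty or differential_calls.empty:
        return pd.DataFrame(columns=call_cols), pd.DataFrame(
            columns=["protein_accession", "directions"]
        )
    passing = differential_calls[differential_calls["passes"]]
    joined = matches.merge(
        passing[["group_id", "patient_id", "direction"]], on="group_id", how="inner"
    )
    if joined.empty:
        return pd.DataFrame(columns=call_cols), pd.DataFrame(
            columns=["protein_accession", "directions"]
        )

    support = (
        joined.groupby(["protein_accession", "direction"])
        .agg(
            protein_name=("protein_name", "first"),
            patients=("patient_id", lambda s: sorted(set(s))),
            groups=("group_id", lambda s: sorted(set(s))),
            peptides=("sequence", lambda s: sorted(set(s))),
        )
        .reset_index()
    )
    support["n_patients_support"] = support["patients"].map(len)

    directions_per_protein = support.groupby("protein_accession")["direction"].nunique()
    conflicted = set(directions_per_protein[directions_per_protein > 1].index)
    conflicts = (
        support[support["protein_accession"].isin(conflicted)]
        .groupby("protein_accession")["direction"]
        .apply(lambda s: ";".join(sorted(s)))
        .rename("directions")
        .reset_index()
    )
    calls = support[
        ~support["protein_accession"].isin(conflicted)
        & (support["n_patients_support"] >= min_patients)
    ].copy()
    for col in ("patients", "groups", "peptides"):
        calls[col] = calls[col].map(";".join)
    calls = calls.sort_values(
        ["n_patients_support", "protein_accession"], ascending=[False, True]
    ).reset_index(drop=True)
    return calls[call_cols], conflicts
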