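"""Chemical-shift perturbations and NOE-derived contact profiles.

CSP combines the backbone amide ¹H and ¹⁵N shift changes between two
conditions as

    CSP = sqrt(ΔδH² + ΔδN² / 10²)   [ppm]

with the ¹⁵N change down-weighted by a factor of 10 to account for the
different gyromagnetic ratios of the two nuclei.

Contact profiling normalises lipid (CH₂ window, 1.35–1.25 ppm) and water
(4.6 ppm) NOE cross-peak intensities to the corresponding diagonal peak,
and excludes from the lipid track any residue whose own protons — or the
protons of the preceding residue — resonate inside the lipid window, since
their cross peaks cannot be distinguished from intramolecular NOEs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import PeakTable, ShiftTable

N_SCALE = 10.0  # gyromagnetic-ratio weighting of the 15N shift change

LIPID_WINDOW = (1.25, 1.35)  # ppm, lipid CH2 resonances
WATER_PPM = 4.6


@dataclass
class CSPProfile:
    """Per-residue chemical-shift perturbations (ppm)."""

    residues: np.ndarray
    values: np.ndarray
    only_in_a: list[int] = field(default_factory=list)
    only_in_b: list[int] = field(default_factory=list)


@dataclass
class ContactProfile:
    """Diagonal-normalised lipid/water NOE tracks with a per-residue class.

    Classes: 'lipid', 'water', 'both', 'none', or 'excluded' (overlap rule).
    """

    residues: np.ndarray
    lipid: np.ndarray
    water: np.ndarray
    classes: list[str]
    t_lipid: float
    t_water: float


def csp(a: ShiftTable, b: ShiftTable) -> CSPProfile:
    """Chemical-shift perturbation per residue shared by the two tables.

    Residues present in only one table are reported, never fabricated.
    """
    da, db = a.as_dict(), b.as_dict()
    shared = sorted(set(da) & set(db))
    if not shared:
        raise ValueError("shift tables share no residues")
    vals = np.array(
        [
            np.sqrt((da[r][0] - db[r][0]) ** 2 + ((da[r][1] - db[r][1]) / N_SCALE) ** 2)
            for r in shared
        ]
    )
    return CSPProfile(
        np.asarray(shared, dtype=int),
        vals,
        only_in_a=sorted(set(da) - set(db)),
        only_in_b=sorted(set(db) - set(da)),
    )


def contact_profile(
    peaks: PeakTable,
    exclusions: set[int] | None = None,
    t_lipid: float = 0.05,
    t_water: float = 0.05,
) -> ContactProfile:
    """Normalised lipid/water contact tracks with threshold classification.

    Each intensity is divided by the residue's diagonal-peak intensity.
    Residues in ``exclusions`` (or flagged excluded in the table) are
    passed through with class 'excluded' and NaN tracks.
    """
    exclusions = set() if exclusions is None else set(exclusions)
    lipid = np.empty(len(peaks))
    water = np.empty(len(peaks))
    classes: list[str] = []
    for i, r in enumerate(peaks.residues):
        if bool(peaks.excluded[i]) or int(r) in exclusions:
            lipid[i] = np.nan
            water[i] = np.nan
            classes.append("excluded")
            continue
        if peaks.I_diag[i] <= 0:
            raise ValueError(f"residue {int(r)}: missing/non-positive diagonal intensity")
        lipid[i] = peaks.I_lipid[i] / peaks.I_diag[i]
        water[i] = peaks.I_water[i] / peaks.I_diag[i]
        is_l, is_w = lipid[i] >= t_lipid, water[i] >= t_water
        classes.append("both" if is_l and is_w else "lipid" if is_l else "water" if is_w else "none")
    return ContactProfile(peaks.residues.copy(), lipid, water, classes, t_lipid, t_water)


def flag_overlaps(
    assignments: dict[int, list[float]],
    window: tuple[float, float] = LIPID_WINDOW,
    margin: float = 0.05,
) -> set[int]:
    """Residues whose lipid-window cross peaks are unusable due to overlap.

    Residue *i* is excluded when any proton of residue *i* or of residue
    *i−1* resonates within [window.low − margin, window.high + margin].
    """
    lo, hi = min(window) - margin, max(window) + margin
    offenders = {
        r for r, shifts in assignments.items() if any(lo <= s <= hi for s in shifts)
    }
    # an offender poisons its own amide cross peak and that of residue i+1
    # (whose i-1 protons it is)
    return offenders | {r + 1 for r in offenders}
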