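"""Sliding-window hydropathy profiling of TM/JM constructs.

A 4-residue moving average — about one α-helix turn — of a per-residue
hydrophobicity scale locates the transmembrane run and any additional
hydrophobic juxtamembrane patch in a single-pass receptor construct. The
companion interface-propensity operation scores a segment on the
Wimley–White interfacial scale, where aromatic-rich JM segments come out
strongly interface-favourable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AnnotatedSequence
from .scales import SCALES, SCALE_UNITS


@dataclass
class HydropathyProfile:
    """Windowed mean hydropathy along a sequence.

    ``positions[i]`` is the absolute residue number anchoring window *i*
    (the window's first residue by default, its centre with
    ``anchor='center'``); ``values[i]`` is the arithmetic mean of the scale
    over that window.
    """

    positions: np.ndarray
    values: np.ndarray
    scale_name: str
    frame: int
    anchor: str = "first"


@dataclass
class RegionAnnotation:
    """Maximal hydrophobic/hydrophilic runs of a profile.

    ``segments`` is a list of (first_position, last_position, label,
    n_residues_covered) tuples tiling the profiled positions; labels are
    'hydrophobic' (windowed value > threshold) or 'hydrophilic'.
    """

    segments: list[tuple[int, int, str, int]]
    threshold: float
    frame: int

    def hydrophobic(self) -> list[tuple[int, int]]:
        return [(a, b) for a, b, lab, _ in self.segments if lab == "hydrophobic"]


@dataclass
class InterfacePropensity:
    """Per-residue Wimley–White interface free energies and their mean."""

    positions: np.ndarray
    values: np.ndarray
    mean: float
    units: str = SCALE_UNITS["ww_interface"]


def residue_values(seq: AnnotatedSequence, scale: str) -> np.ndarray:
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}; shipped scales: {sorted(SCALES)}")
    table = SCALES[scale]
    return np.array([table[aa] for aa in seq.residues], dtype=float)


def window_hydropathy(
    seq: AnnotatedSequence,
    scale: str = "kd",
    frame: int = 4,
    anchor: str = "first",
) -> HydropathyProfile:
    """Moving-average hydropathy with a window of ``frame`` residues.

    Value *i* is the mean scale value over residues [i, i+frame-1]. The
    default frame of four residues approximates one α-helix turn, so a
    helical face's composition is averaged out and the profile tracks the
    segment-scale hydrophobic character.
    """
    if frame < 1:
        raise ValueError("frame must be positive")
    if frame > len(seq):
        raise ValueError(f"frame {frame} exceeds sequence length {len(seq)}")
    if anchor not in ("first", "center"):
        raise ValueError("anchor must be 'first' or 'center'")
    vals = residue_values(seq, scale)
    kernel = np.full(frame, 1.0 / frame)
    means = np.convolve(vals, kernel, mode="valid")
    first = seq.numbering()[: len(means)]
    positions = first if anchor == "first" else first + (frame - 1) // 2
    return HydropathyProfile(positions, means, scale, frame, anchor)


def annotate_regions(profile: HydropathyProfile, threshold: float = 0.0) -> RegionAnnotation:
    """Label maximal runs of windows above/below a hydrophobicity threshold.

    Windows with value strictly above ``threshold`` are 'hydrophobic'.
    Segments are reported over window positions and tile the profiled
    range; each also reports the number of residues its windows cover.
    """
    if len(profile.values) == 0:
        raise ValueError("empty profile")
    labels = np.where(profile.values > threshold, "hydrophobic", "hydrophilic")
    segments: list[tuple[int, int, str, int]] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            a = int(profile.positions[start])
            b = int(profile.positions[i - 1])
            covered = b - a + profile.frame  # residues spanned by the run's windows
            segments.append((a, b, str(labels[start]), covered))
            start = i
    return RegionAnnotation(segments, threshold, profile.frame)


def interface_propensity(
    seq: AnnotatedSequence,
    residue_range: tuple[int, int] | None = None,
) -> InterfacePropensity:
    """Wimley–White interface free-energy track over a residue range.

    Returns per-residue values (kcal/mol, water → POPC interface; negative
    = interface-favourable) and their mean. A JM segment rich in Trp/Phe/Tyr
    scores well below a polar control of equal length.
    """
    if residue_range is None:
        sub = seq
    else:
        sub = seq.subsequence(*residue_range)
    vals = residue_values(sub, "ww_interface")
    return InterfacePropensity(sub.numbering(), vals, float(vals.mean()))
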