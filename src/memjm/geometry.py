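"""Conformer-ensemble geometry.

Rigid superposition and pairwise RMSD statistics across an NMR-style
conformer set, least-squares helix-axis fits, interhelical angles and
kink/bend profiles along a helix.

Conventions: helix axes are unit vectors directed N→C; angles are reported
in degrees on [0, 180] with arithmetic mean and sample SD (ddof=1) across
conformers; RMSDs are in Å.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.spatial.transform import Rotation

from .io import StructureEnsemble

BACKBONE_ATOMS = {"N", "CA", "C"}

# one-turn running-centroid length used to cancel helix phase before the
# least-squares line fit (3.6 residues/turn rounds to 4)
_AXIS_SMOOTH = 4


@dataclass(frozen=True)
class HelixSegment:
    """Inclusive absolute residue range treated as one helix."""

    start: int
    end: int
    chain: str | None = None

    def __post_init__(self) -> None:
        if self.end - self.start + 1 < 5:
            raise ValueError(
                f"segment {self.start}-{self.end}: axis fit needs >= 5 residues"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    @classmethod
    def parse(cls, text: str, chain: str | None = None) -> "HelixSegment":
        """Parse '586-606' style ranges."""
        a, b = text.split("-")
        return cls(int(a), int(b), chain)


@dataclass
class AxisFit:
    """Per-conformer helix axis (unit, N→C) and centroid for a segment."""

    segment: HelixSegment
    axes: np.ndarray       # (M, 3) unit vectors
    centroids: np.ndarray  # (M, 3) Å


@dataclass
class AngleStat:
    """Per-conformer interhelical angles with mean ± sample SD (degrees)."""

    angles: np.ndarray
    mean: float
    sd: float


@dataclass
class RmsdStat:
    """All-unordered-pair conformer RMSDs with mean ± sample SD (Å)."""

    values: np.ndarray
    mean: float
    sd: float
    atom_set: str


@dataclass
class BendProfile:
    """Per-residue bend angle track along a helix (degrees).

    ``residues[i]`` anchors the angle between local axes fitted to the two
    windows straddling that residue; ``mean``/``sd`` are over conformers.
    """

    residues: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    per_conformer: np.ndarray  # (M, n_positions)
    window: int
    offset: int


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of paired point sets (Kabsch).

    Returns (rotation R, translation t, rmsd) such that ``mobile @ R.T + t``
    minimises the RMSD to ``reference``. The rotation is proper (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(f"shape mismatch: {mobile.shape} vs {reference.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("need >= 3 paired 3D points")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    a, b = mobile - mc, reference - rc
    if np.linalg.matrix_rank(b, tol=1e-8) < 2 or np.linalg.matrix_rank(a, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set")
    rot, rssd = Rotation.align_vectors(b, a)
    R = rot.as_matrix()
    t = rc - R @ mc
    rmsd = float(rssd / np.sqrt(mobile.shape[0]))
    return R, t, rmsd


def _segment_mask(ens: StructureEnsemble, segments: list[HelixSegment], atom_set: str) -> np.ndarray:
    if atom_set not in ("backbone", "heavy"):
        raise ValueError("atom_set must be 'backbone' or 'heavy'")
    m = np.zeros(ens.n_atoms, dtype=bool)
    for seg in segments:
        m |= ens.mask(res_range=(seg.start, seg.end))
    if atom_set == "backbone":
        m &= np.isin(ens.atom_name, sorted(BACKBONE_ATOMS))
        for seg in segments:
            for r in range(seg.start, seg.end + 1):
                present = set(ens.atom_name[(ens.res_id == r) & m])
                missing = BACKBONE_ATOMS - present
                if missing:
                    raise ValueError(
                        f"residue {r}: backbone atoms missing from shared index: "
                        f"{sorted(missing)}"
                    )
    else:
        m &= ens.element != "H"
    if not m.any():
        raise ValueError("no atoms selected for the requested segments")
    return m


def pairwise_rmsd(
    ens: StructureEnsemble,
    segments: list[HelixSegment] | HelixSegment,
    atom_set: str = "backbone",
) -> RmsdStat:
    """Average pairwise RMSD over all unordered conformer pairs.

    Each pair is superposed on the selected atoms of the selected segments
    jointly before the RMSD is taken, so the statistic reflects internal
    (conformational) spread, not rigid-body scatter.
    """
    if isinstance(segments, HelixSegment):
        segments = [segments]
    if ens.n_models < 2:
        raise ValueError("pairwise RMSD needs at least 2 conformers")
    mask = _segment_mask(ens, segments, atom_set)
    xyz = ens.coords[:, mask, :]
    vals = [
        kabsch_superpose(xyz[i], xyz[j])[2]
        for i, j in combinations(range(ens.n_models), 2)
    ]
    vals = np.asarray(vals)
    return RmsdStat(vals, float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0, atom_set)


# ---------------------------------------------------------------------------
# helix axes
# ---------------------------------------------------------------------------

def _line_fit_axis(points: np.ndarray) -> np.ndarray:
    """First principal direction of a point cloud (total least squares)."""
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, full_matrices=False, compute_uv=False)
    if s.size < 2 or s[1] < 1e-8 * max(s[0], 1e-12):
        # rank < 2: the CA cloud carries no helical spread around the line
        raise ValueError("degenerate CA cloud (rank < 2); cannot fit a helix axis")
    u, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0]


def _smoothed_axis(ca: np.ndarray) -> np.ndarray:
    """Least-squares helix axis for one conformer's CA trace (unit, N→C).

    The line is fitted to one-turn (4-residue) running centroids of the CA
    positions, which cancels the helical phase; the raw CA cloud is used
    when the segment is too short to smooth.
    """
    if len(ca) >= _AXIS_SMOOTH + 2:
        pts = np.stack(
            [ca[i : i + _AXIS_SMOOTH].mean(axis=0) for i in range(len(ca) - _AXIS_SMOOTH + 1)]
        )
    else:
        pts = ca
    v = _line_fit_axis(pts)
    if v @ (ca[-1] - ca[0]) < 0:
        v = -v
    return v


def _turn_axis(ca: np.ndarray) -> np.ndarray:
    """Rotation-geometry helix axis from successive CA differences.

    The second differences of the CA trace (bisector vectors) are
    perpendicular to the helix axis, so their pairwise cross products all
    point along it. Exact for an ideal helix at any window length; used for
    the short windows of the bend profile where a plain line fit is
    phase-biased.
    """
    d = np.diff(ca, axis=0)
    a = np.diff(d, axis=0)
    if len(a) < 2:
        raise ValueError("need >= 4 CA atoms for a rotation-geometry axis")
    cross = np.cross(a[:-1], a[1:])
    # orient every cross product along the chain direction before summing
    chain = ca[-1] - ca[0]
    sign = np.where(cross @ chain < 0, -1.0, 1.0)
    v = (cross * sign[:, None]).sum(axis=0)
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        raise ValueError("degenerate CA trace; cannot determine local axis")
    v = v / norm
    if v @ chain < 0:
        v = -v
    return v


def fit_axis(ens: StructureEnsemble, seg: HelixSegment) -> AxisFit:
    """Per-conformer least-squares helix axis for a segment's CA atoms.

    The axis is the principal direction of the (phase-smoothed) CA trace,
    sign-fixed so it points from the segment's N-terminus to its
    C-terminus.
    """
    ca = ens.ca_coords(seg.start, seg.end)
    axes = np.stack([_smoothed_axis(ca[m]) for m in range(ens.n_models)])
    centroids = ca.mean(axis=1)
    return AxisFit(seg, axes, centroids)


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    return float(np.degrees(np.arccos(np.clip(u @ v, -1.0, 1.0))))


def interhelix_angle(
    ens: StructureEnsemble,
    seg1: HelixSegment,
    seg2: HelixSegment,
    on_mean_structure: bool = False,
) -> AngleStat:
    """Angle between two helix axes, per conformer, mean ± sample SD.

    Axes are N→C directed, so 0° is parallel (same chain direction) and
    180° antiparallel. With ``on_mean_structure=True`` the angle is instead
    computed once on the coordinate-averaged structure.
    """
    if on_mean_structure:
        mean_ens = StructureEnsemble(
            ens.chain_id, ens.res_id, ens.res_name, ens.atom_name, ens.element,
            ens.coords.mean(axis=0, keepdims=True),
        )
        return interhelix_angle(mean_ens, seg1, seg2)
    f1, f2 = fit_axis(ens, seg1), fit_axis(ens, seg2)
    angles = np.array([_angle_deg(a, b) for a, b in zip(f1.axes, f2.axes)])
    sd = float(angles.std(ddof=1)) if len(angles) > 1 else 0.0
    return AngleStat(angles, float(angles.mean()), sd)


def bend_profile(
    ens: StructureEnsemble,
    seg: HelixSegment,
    window: int = 7,
    offset: int = 7,
) -> BendProfile:
    """Local bend/kink angle track along a helix.

    At each position, two ``window``-residue windows are placed with their
    starts ``offset`` residues apart and the angle between their local
    helix axes is recorded, anchored to the residue the window pair
    straddles. Maxima of the mean track locate kinks.
    """
    if window < 5:
        raise ValueError("window must be >= 5 residues")
    if offset < 1:
        raise ValueError("offset must be >= 1 residue")
    n = len(seg)
    n_pos = n - window - offset + 1
    if n_pos < 1:
        raise ValueError(
            f"segment {seg.start}-{seg.end} too short for window={window}, offset={offset}"
        )
    ca = ens.ca_coords(seg.start, seg.end)
    anchors = seg.start + (window + offset) // 2 + np.arange(n_pos)
    per = np.empty((ens.n_models, n_pos))
    for m in range(ens.n_models):
        for p in range(n_pos):
            a1 = _turn_axis(ca[m, p : p + window])
            a2 = _turn_axis(ca[m, p + offset : p + offset + window])
            per[m, p] = _angle_deg(a1, a2)
    sd = per.std(axis=0, ddof=1) if ens.n_models > 1 else np.zeros(n_pos)
    return BendProfile(anchors, per.mean(axis=0), sd, per, window, offset)


def kink_positions(
    prof: BendProfile, min_angle: float = 10.0, tol: float = 1.0
) -> list[int]:
    """Kink loci from a bend profile: midpoints of near-maximal plateaus.

    Window pairs that cleanly straddle a kink all read the full kink angle,
    so a planted kink shows as a ~2-position plateau (window pairs partially
    covering the kink may overshoot by a fraction of a degree); the locus is
    therefore the midpoint of the contiguous run within ``tol`` degrees of
    each local maximum above ``min_angle``.
    """
    x = prof.mean
    found: list[int] = []
    for i in range(len(x)):
        left = x[i - 1] if i > 0 else -np.inf
        right = x[i + 1] if i < len(x) - 1 else -np.inf
        if x[i] >= left and x[i] >= right and x[i] >= min_angle:
            j0 = i
            while j0 > 0 and x[j0 - 1] >= x[i] - tol:
                j0 -= 1
            j1 = i
            while j1 < len(x) - 1 and x[j1 + 1] >= x[i] - tol:
                j1 += 1
            found.append(int(round((int(prof.residues[j0]) + int(prof.residues[j1])) / 2)))
    return sorted(set(found))
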