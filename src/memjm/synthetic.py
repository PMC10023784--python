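"""Synthetic fixtures with known ground truth.

Ideal α-helices (1.5 Å rise, 100° twist, 2.3 Å CA radius), two-helix
hairpins built at an exact inter-axis angle, Gaussian-noise conformer
ensembles, block-designed sequences, and shift/peak tables with planted
perturbations and contacts. Every generator is a pure function of its
parameters and seed, so analysis modules can be tested end-to-end by
recovering the planted quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .io import AnnotatedSequence, PeakTable, ShiftTable, StructureEnsemble

# textbook ideal alpha-helix parameters
IDEAL_RISE = 1.5       # Å per residue
IDEAL_TWIST = 100.0    # degrees per residue (3.6 residues/turn)
IDEAL_CA_RADIUS = 2.3  # Å

HYDROPHOBIC_AA = "LIVFLIVALIVFLIVALIVF"  # cycled for designed blocks
HYDROPHILIC_AA = "SQKENSQDNTSQKENSQDNT"


@dataclass(frozen=True)
class HelixSpec:
    """Construction recipe for an ideal α-helix CA (or backbone) trace."""

    n_residues: int
    rise: float = IDEAL_RISE
    twist: float = IDEAL_TWIST
    radius: float = IDEAL_CA_RADIUS
    kinks: tuple[tuple[int, float], ...] = ()  # (absolute residue, degrees)
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    start_number: int = 1
    chain: str = "A"

    def __post_init__(self) -> None:
        if self.n_residues < 5:
            raise ValueError("helix needs at least 5 residues")
        if not (0 < self.twist < 360):
            raise ValueError("twist must be in (0, 360) degrees")
        if self.radius <= 0:
            raise ValueError("radius must be positive")


def _rotation_to(axis: np.ndarray) -> np.ndarray:
    """Proper rotation taking +z to the given direction."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, axis)
    s = np.linalg.norm(v)
    if s < 1e-12:
        return np.eye(3) if axis[2] > 0 else Rotation.from_euler("x", 180, degrees=True).as_matrix()
    return Rotation.from_rotvec(v / s * np.arccos(np.clip(z @ axis, -1, 1))).as_matrix()


def _ca_trace(spec: HelixSpec) -> np.ndarray:
    k = np.arange(spec.n_residues)
    ang = np.deg2rad(spec.twist * k)
    ca = np.c_[spec.radius * np.cos(ang), spec.radius * np.sin(ang), spec.rise * k]
    # apply kinks in sequence order: rotate everything downstream of the
    # kink residue about that residue's CA, around a direction
    # perpendicular to the current local axis
    direction = np.array([0.0, 0.0, 1.0])
    for pos, angle in sorted(spec.kinks):
        idx = pos - spec.start_number
        if not (0 < idx < spec.n_residues - 1):
            raise ValueError(f"kink residue {pos} outside the helix interior")
        perp = np.cross(direction, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-9:
            perp = np.cross(direction, [0.0, 1.0, 0.0])
        perp = perp / np.linalg.norm(perp)
        R = Rotation.from_rotvec(np.deg2rad(angle) * perp).as_matrix()
        pivot = ca[idx]
        ca[idx:] = (ca[idx:] - pivot) @ R.T + pivot
        direction = R @ direction
    return ca @ _rotation_to(np.asarray(spec.axis)).T


def _ensemble_from_ca(
    ca_models: np.ndarray, start_number: int, chain: str, atoms: str
) -> StructureEnsemble:
    m, n, _ = ca_models.shape
    if atoms == "CA":
        res_id = np.arange(start_number, start_number + n)
        return StructureEnsemble(
            chain_id=np.full(n, chain),
            res_id=res_id,
            res_name=np.full(n, "ALA"),
            atom_name=np.full(n, "CA"),
            element=np.full(n, "C"),
            coords=ca_models,
        )
    if atoms != "backbone":
        raise ValueError("atoms must be 'CA' or 'backbone'")
    # place N and C by simple internal coordinates along the chain trace;
    # good enough for atom-set plumbing, never used for angle ground truth
    coords = np.empty((m, 3 * n, 3))
    for mi in range(m):
        ca = ca_models[mi]
        prev_dir = np.empty_like(ca)
        next_dir = np.empty_like(ca)
        prev_dir[1:] = ca[:-1] - ca[1:]
        prev_dir[0] = ca[0] - ca[1]
        next_dir[:-1] = ca[1:] - ca[:-1]
        next_dir[-1] = ca[-1] - ca[-2]
        coords[mi, 0::3] = ca + 0.38 * prev_dir / np.linalg.norm(prev_dir, axis=1, keepdims=True)
        coords[mi, 1::3] = ca
        coords[mi, 2::3] = ca + 0.40 * next_dir / np.linalg.norm(next_dir, axis=1, keepdims=True)
    res_id = np.repeat(np.arange(start_number, start_number + n), 3)
    return StructureEnsemble(
        chain_id=np.full(3 * n, chain),
        res_id=res_id,
        res_name=np.full(3 * n, "ALA"),
        atom_name=np.tile(np.array(["N", "CA", "C"]), n),
        element=np.tile(np.array(["N", "C", "C"]), n),
        coords=coords,
    )


def make_helix(spec: HelixSpec, atoms: str = "CA") -> StructureEnsemble:
    """One-conformer ideal helix; CA-only or CA+N+C backbone."""
    ca = _ca_trace(spec)
    return _ensemble_from_ca(ca[None, :, :], spec.start_number, spec.chain, atoms)


def make_hairpin(
    angle: float,
    helix1_spec: HelixSpec | None = None,
    helix2_spec: HelixSpec | None = None,
    gap: float = 6.0,
    seed: int = 0,
    atoms: str = "CA",
) -> StructureEnsemble:
    """Two ideal helices whose construction axes subtend exactly ``angle``.

    Helix 1 runs along +z; helix 2 is a copy rotated by ``angle`` and
    placed ``gap`` Å beyond helix 1's C-terminus. Residue numbering is
    continuous with a 3-residue unmodelled gap between the helices (the
    linker is not built, so the axis ground truth stays exact). Placements
    that clash (< 1 Å interatomic) are retried with seeded jitter.
    """
    if not (0.0 <= angle <= 180.0):
        raise ValueError("angle must be in [0, 180] degrees")
    h1 = helix1_spec or HelixSpec(18)
    n2 = helix2_spec.n_residues if helix2_spec else 18
    start2 = h1.start_number + h1.n_residues + 3
    h2 = HelixSpec(
        n_residues=n2,
        rise=(helix2_spec.rise if helix2_spec else IDEAL_RISE),
        twist=(helix2_spec.twist if helix2_spec else IDEAL_TWIST),
        radius=(helix2_spec.radius if helix2_spec else IDEAL_CA_RADIUS),
        start_number=start2,
        chain=h1.chain,
    )
    ca1 = _ca_trace(h1)
    ca2 = _ca_trace(h2)
    R = Rotation.from_euler("x", angle, degrees=True).as_matrix()
    ca2 = ca2 @ R.T
    d2 = R @ np.array([0.0, 0.0, 1.0])  # helix-2 axis direction

    rng = np.random.default_rng(seed)
    base_offset = ca1[-1] + gap * d2 - ca2[0]
    for attempt in range(11):
        jitter = np.zeros(3) if attempt == 0 else rng.normal(0, 1.5, 3)
        placed = ca2 + base_offset + jitter
        dmin = np.min(
            np.linalg.norm(ca1[:, None, :] - placed[None, :, :], axis=-1)
        )
        if dmin > 1.0:
            break
    else:
        raise RuntimeError("could not place hairpin helices without clashes")

    both = np.concatenate([ca1, placed])[None, :, :]
    res_id = np.concatenate(
        [
            np.arange(h1.start_number, h1.start_number + h1.n_residues),
            np.arange(start2, start2 + n2),
        ]
    )
    n = both.shape[1]
    ens = StructureEnsemble(
        chain_id=np.full(n, h1.chain),
        res_id=res_id,
        res_name=np.full(n, "ALA"),
        atom_name=np.full(n, "CA"),
        element=np.full(n, "C"),
        coords=both,
    )
    if atoms == "backbone":
        # rebuild with N/C placed along the concatenated trace per helix
        e1 = _ensemble_from_ca(ca1[None], h1.start_number, h1.chain, "backbone")
        e2 = _ensemble_from_ca(placed[None], start2, h1.chain, "backbone")
        return StructureEnsemble(
            chain_id=np.concatenate([e1.chain_id, e2.chain_id]),
            res_id=np.concatenate([e1.res_id, e2.res_id]),
            res_name=np.concatenate([e1.res_name, e2.res_name]),
            atom_name=np.concatenate([e1.atom_name, e2.atom_name]),
            element=np.concatenate([e1.element, e2.element]),
            coords=np.concatenate([e1.coords, e2.coords], axis=1),
        )
    return ens


def perturb_ensemble(
    base: StructureEnsemble,
    n_models: int,
    sigma: float,
    seed: int = 0,
    rigid_jitter: bool = False,
) -> StructureEnsemble:
    """Gaussian-noise conformer ensemble from a single base structure.

    Each of the ``n_models`` copies receives i.i.d. Gaussian noise of
    ``sigma`` Å per coordinate; with ``rigid_jitter`` each copy is
    additionally rotated and translated at random (which no internal
    statistic should see).
    """
    if n_models < 2:
        raise ValueError("n_models must be >= 2")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    ref = base.coords[0]
    coords = np.empty((n_models, base.n_atoms, 3))
    for m in range(n_models):
        xyz = ref + rng.normal(0.0, sigma, ref.shape)
        if rigid_jitter:
            R = Rotation.random(rng=rng).as_matrix()
            t = rng.uniform(-10.0, 10.0, 3)
            xyz = xyz @ R.T + t
        coords[m] = xyz
    return StructureEnsemble(
        base.chain_id.copy(), base.res_id.copy(), base.res_name.copy(),
        base.atom_name.copy(), base.element.copy(), coords,
    )


def make_sequence(
    blocks: list[tuple[str, int]],
    start_number: int = 1,
    name: str = "designed",
) -> AnnotatedSequence:
    """Sequence from (kind, length) blocks, kind 'hydrophobic'|'hydrophilic'."""
    parts = []
    for kind, length in blocks:
        src = {"hydrophobic": HYDROPHOBIC_AA, "hydrophilic": HYDROPHILIC_AA}[kind]
        parts.append((src * (length // len(src) + 1))[:length])
    return AnnotatedSequence("".join(parts), start_number, name)


def make_tlr_like_sequence(kind: str = "separated", start_number: int = 581) -> AnnotatedSequence:
    """Designed single-pass TM/JM construct.

    'separated' mimics receptors whose hydrophobic JM patch is split from
    the TM run by a short polar hinge; 'contiguous' mimics a construct
    whose TM and JM hydrophobicity merge into one span.
    """
    if kind == "separated":
        blocks = [
            ("hydrophilic", 8),   # extracellular flank
            ("hydrophobic", 21),  # TM helix
            ("hydrophilic", 5),   # polar hinge
            ("hydrophobic", 10),  # JM surface helix
            ("hydrophilic", 8),   # linker toward the signalling domain
        ]
    elif kind == "contiguous":
        blocks = [
            ("hydrophilic", 8),
            ("hydrophobic", 29),  # TM + JM merged, no polar break
            ("hydrophilic", 6),
        ]
    else:
        raise ValueError("kind must be 'separated' or 'contiguous'")
    return make_sequence(blocks, start_number, f"tlr_like_{kind}")


@dataclass(frozen=True)
class PlantedEffects:
    """Ground truth for shift/peak/assignment table generation.

    ``csp``: residue -> CSP in ppm (planted as a pure ¹H change);
    ``lipid``/``water``: residue -> normalised contact intensity;
    ``methyl_shifts``: residue -> proton shift (ppm) planted in the
    assignment table (e.g. 1.30 to trigger the lipid-window overlap rule).
    """

    residues: tuple[int, ...]
    csp: dict[int, float] = field(default_factory=dict)
    lipid: dict[int, float] = field(default_factory=dict)
    water: dict[int, float] = field(default_factory=dict)
    methyl_shifts: dict[int, float] = field(default_factory=dict)


def make_tables(
    planted: PlantedEffects, seed: int = 0, diag_intensity: float = 100.0
) -> tuple[ShiftTable, ShiftTable, PeakTable, dict[int, list[float]]]:
    """Shift-table pair, peak table and assignment table with exact ground truth.

    The second shift table differs from the first by ΔH = planted CSP and
    ΔN = 0, so ``csp()`` recovers the planted values exactly. Peak-table
    cross intensities equal planted fraction × diagonal. The assignment
    table carries each residue's amide proton plus any planted methyl.
    """
    rng = np.random.default_rng(seed)
    res = np.asarray(planted.residues, dtype=int)
    h = rng.normal(8.3, 0.3, len(res))
    n15 = rng.normal(120.0, 3.0, len(res))
    ref = ShiftTable(res, h, n15)
    pert = ShiftTable(
        res,
        h + np.array([planted.csp.get(int(r), 0.0) for r in res]),
        n15.copy(),
    )
    peaks = PeakTable(
        res,
        np.array([planted.lipid.get(int(r), 0.0) for r in res]) * diag_intensity,
        np.array([planted.water.get(int(r), 0.0) for r in res]) * diag_intensity,
        np.full(len(res), diag_intensity),
    )
    assignments = {
        int(r): [float(hh)] + ([planted.methyl_shifts[int(r)]] if int(r) in planted.methyl_shifts else [])
        for r, hh in zip(res, h)
    }
    return ref, pert, peaks, assignments
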