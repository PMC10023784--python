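"""Input/output layer and shared data model.

Reads the plain-text formats the pipeline touches — FASTA sequences with
absolute (UNIPROT-style) numbering, multi-model PDB conformer ensembles,
and tab-separated chemical-shift / NOE-peak tables — and defines the
in-memory containers every analysis module consumes.

Coordinates are stored in Å throughout; unit conversion happens only at
output boundaries (e.g. the mobility map reports nm).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

import biotite.structure as struc
import biotite.structure.io.pdb as pdb

logger = logging.getLogger(__name__)

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotatedSequence:
    """One-letter amino-acid string carrying an absolute numbering offset.

    ``start_number`` follows the UNIPROT convention: the first residue of
    the string has this absolute index, so a 49-residue construct starting
    at 698 ends at residue 746.
    """

    residues: str
    start_number: int = 1
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("sequence must contain at least one residue")
        if self.start_number < 1:
            raise ValueError("start_number must be >= 1")
        for i, aa in enumerate(self.residues):
            if aa not in CANONICAL_AA:
                raise ValueError(
                    f"non-canonical residue code {aa!r} at position "
                    f"{self.start_number + i} of {self.name or 'sequence'}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def end_number(self) -> int:
        return self.start_number + len(self.residues) - 1

    def numbering(self) -> np.ndarray:
        """Absolute residue numbers, one per residue."""
        return np.arange(self.start_number, self.end_number + 1)

    def subsequence(self, start: int, end: int) -> "AnnotatedSequence":
        """Slice by absolute residue numbers (inclusive)."""
        if start < self.start_number or end > self.end_number or start > end:
            raise ValueError(
                f"range {start}-{end} outside sequence "
                f"{self.start_number}-{self.end_number}"
            )
        i = start - self.start_number
        j = end - self.start_number + 1
        return AnnotatedSequence(self.residues[i:j], start, self.name)


def read_fasta(path: str | Path) -> list[AnnotatedSequence]:
    """Read FASTA records into numbered sequences.

    An optional ``start=N`` token anywhere in the header sets the absolute
    number of the first residue; otherwise numbering starts at 1.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        start = 1
        for token in rec.description.split():
            if token.startswith("start="):
                start = int(token.split("=", 1)[1])
        records.append(
            AnnotatedSequence(str(rec.seq).upper(), start_number=start, name=rec.id)
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(seqs: list[AnnotatedSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.name or 'seq'} start={s.start_number}\n{s.residues}\n")


# ---------------------------------------------------------------------------
# structure ensembles
# ---------------------------------------------------------------------------

@dataclass
class StructureEnsemble:
    """M conformers over a shared atom table.

    The atom table (``chain_id``, ``res_id``, ``res_name``, ``atom_name``,
    ``element``) is the intersection of the atoms present in every
    conformer (the *shared index*); ``coords`` has shape (M, N, 3) in Å.
    """

    chain_id: np.ndarray
    res_id: np.ndarray
    res_name: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_models, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("ensemble needs at least one conformer")
        if self.coords.shape[1] < 1:
            raise ValueError("shared atom index is empty")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        keys = list(zip(self.chain_id, self.res_id, self.atom_name))
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (chain, residue, atom) keys")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def shared_index(self) -> set[tuple[int, str]]:
        return set(zip(self.res_id.tolist(), self.atom_name.tolist()))

    def residue_ids(self) -> np.ndarray:
        return np.unique(self.res_id)

    def mask(
        self,
        res_range: tuple[int, int] | None = None,
        atom_names: set[str] | None = None,
        heavy_only: bool = False,
    ) -> np.ndarray:
        m = np.ones(self.n_atoms, dtype=bool)
        if res_range is not None:
            lo, hi = res_range
            m &= (self.res_id >= lo) & (self.res_id <= hi)
        if atom_names is not None:
            m &= np.isin(self.atom_name, sorted(atom_names))
        if heavy_only:
            m &= self.element != "H"
        return m

    def ca_coords(self, start: int, end: int) -> np.ndarray:
        """CA coordinates for residues start..end, shape (M, n_res, 3).

        Residues in the range must all carry a CA atom in the shared index.
        """
        wanted = np.arange(start, end + 1)
        out = np.empty((self.n_models, len(wanted), 3))
        ca = self.mask(atom_names={"CA"})
        ids = self.res_id[ca]
        xyz = self.coords[:, ca, :]
        for k, r in enumerate(wanted):
            hit = np.flatnonzero(ids == r)
            if hit.size == 0:
                raise ValueError(f"residue {r} has no CA atom in the shared index")
            out[:, k, :] = xyz[:, hit[0], :]
        return out

    def subset(self, mask: np.ndarray) -> "StructureEnsemble":
        return StructureEnsemble(
            self.chain_id[mask],
            self.res_id[mask],
            self.res_name[mask],
            self.atom_name[mask],
            self.element[mask],
            self.coords[:, mask, :],
        )


def read_pdb_ensemble(path: str | Path, chain: str | None = None) -> StructureEnsemble:
    """Read a multi-model PDB file into a :class:`StructureEnsemble`.

    Conformers keep file order. Alternate locations are resolved to the
    highest-occupancy variant (ties resolve to the first listed, which by
    PDB convention is altloc 'A'). Atoms not present in every model are
    dropped from the shared index with a warning.
    """
    pf = pdb.PDBFile.read(str(path))
    n_models = pf.get_model_count()
    if n_models == 0:
        raise ValueError(f"{path}: no ATOM records")

    models = []
    for i in range(1, n_models + 1):
        arr = pf.get_structure(model=i, altloc="occupancy")
        arr = arr[~arr.hetero]
        if arr.array_length() == 0:
            raise ValueError(f"{path}: no ATOM records in model {i}")
        models.append(arr)

    chains = sorted(set(models[0].chain_id))
    if chain is None:
        chain = models[0].chain_id[0]
    elif chain not in chains:
        raise ValueError(
            f"chain {chain!r} not found in {path}; available chains: {chains}"
        )
    models = [m[m.chain_id == chain] for m in models]

    def keys(arr):
        return list(zip(arr.chain_id, arr.res_id, arr.atom_name))

    shared = set(keys(models[0]))
    union = set(shared)
    for m in models[1:]:
        k = set(keys(m))
        shared &= k
        union |= k
    if not shared:
        raise ValueError(f"{path}: models share no atoms")
    dropped = union - shared
    if dropped:
        warnings.warn(
            f"{Path(path).name}: {len(dropped)} atom(s) absent from some models "
            f"dropped from shared index: "
            + ", ".join(f"{r}:{a}" for _, r, a in sorted(dropped)[:10])
            + ("..." if len(dropped) > 10 else ""),
            stacklevel=2,
        )

    ref = models[0]
    ref_keys = keys(ref)
    keep = [i for i, k in enumerate(ref_keys) if k in shared]
    order = [ref_keys[i] for i in keep]

    coords = np.empty((n_models, len(keep), 3))
    for mi, m in enumerate(models):
        lookup = {k: i for i, k in enumerate(keys(m))}
        idx = [lookup[k] for k in order]
        coords[mi] = m.coord[idx]

    ref = ref[np.asarray(keep, dtype=int)]
    return StructureEnsemble(
        chain_id=np.asarray(ref.chain_id),
        res_id=np.asarray(ref.res_id),
        res_name=np.asarray(ref.res_name),
        atom_name=np.asarray(ref.atom_name),
        element=np.asarray(ref.element),
        coords=coords,
    )


def write_pdb_ensemble(ens: StructureEnsemble, path: str | Path) -> None:
    """Write the ensemble as a multi-model PDB file (MODEL/ENDMDL blocks)."""
    n = ens.n_atoms
    template = struc.AtomArray(n)
    template.chain_id = ens.chain_id
    template.res_id = ens.res_id
    template.res_name = ens.res_name
    template.atom_name = ens.atom_name
    template.element = ens.element
    stack = struc.stack([template] * ens.n_models)
    stack.coord = ens.coords.copy()
    pf = pdb.PDBFile()
    pf.set_structure(stack)
    pf.write(str(path))


# ---------------------------------------------------------------------------
# shift and peak tables
# ---------------------------------------------------------------------------

@dataclass
class ShiftTable:
    """Backbone amide chemical shifts per residue (¹H and ¹⁵N, ppm)."""

    residues: np.ndarray
    H_ppm: np.ndarray
    N_ppm: np.ndarray

    def __post_init__(self) -> None:
        self.residues = np.asarray(self.residues, dtype=int)
        self.H_ppm = np.asarray(self.H_ppm, dtype=float)
        self.N_ppm = np.asarray(self.N_ppm, dtype=float)
        if len(np.unique(self.residues)) != len(self.residues):
            raise ValueError("duplicate residue numbers in shift table")
        if not (np.all(np.isfinite(self.H_ppm)) and np.all(np.isfinite(self.N_ppm))):
            raise ValueError("non-finite chemical shifts")

    def __len__(self) -> int:
        return len(self.residues)

    def as_dict(self) -> dict[int, tuple[float, float]]:
        return {
            int(r): (float(h), float(n))
            for r, h, n in zip(self.residues, self.H_ppm, self.N_ppm)
        }


@dataclass
class PeakTable:
    """NOE cross-peak intensities per residue.

    ``I_lipid`` is the cross-peak with the lipid CH₂ window (1.35–1.25 ppm),
    ``I_water`` with water (4.6 ppm), ``I_diag`` the diagonal peak used for
    normalisation. ``excluded`` marks residues removed from the lipid track
    because their own protons (or those of residue i−1) resonate inside the
    lipid window.
    """

    residues: np.ndarray
    I_lipid: np.ndarray
    I_water: np.ndarray
    I_diag: np.ndarray
    excluded: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.residues = np.asarray(self.residues, dtype=int)
        self.I_lipid = np.asarray(self.I_lipid, dtype=float)
        self.I_water = np.asarray(self.I_water, dtype=float)
        self.I_diag = np.asarray(self.I_diag, dtype=float)
        if self.excluded is None:
            self.excluded = np.zeros(len(self.residues), dtype=bool)
        else:
            self.excluded = np.asarray(self.excluded, dtype=bool)
        if len(np.unique(self.residues)) != len(self.residues):
            raise ValueError("duplicate residue numbers in peak table")
        if np.any(self.I_lipid < 0) or np.any(self.I_water < 0):
            raise ValueError("negative cross-peak intensities")
        bad = self.residues[(self.I_diag <= 0) & ~self.excluded]
        if bad.size:
            raise ValueError(
                "non-positive diagonal intensity for residue(s): "
                + ", ".join(map(str, bad.tolist()))
            )

    def __len__(self) -> int:
        return len(self.residues)


SHIFT_COLUMNS = ("residue", "H_ppm", "N_ppm")
PEAK_COLUMNS = ("residue", "I_lipid", "I_water", "I_diag")
ASSIGNMENT_COLUMNS = ("residue", "shift_ppm")


def read_table(path: str | Path, schema: str):
    """Read a TSV table with a named-column header.

    schema 'shift' -> :class:`ShiftTable` (residue, H_ppm, N_ppm)
    schema 'peak' -> :class:`PeakTable` (residue, I_lipid, I_water, I_diag
    and an optional boolean 'excluded' column)
    schema 'assignment' -> dict residue -> list of proton shifts (ppm)

    Rows with any blank required field are skipped and counted in the log.
    """
    required = {
        "shift": SHIFT_COLUMNS,
        "peak": PEAK_COLUMNS,
        "assignment": ASSIGNMENT_COLUMNS,
    }.get(schema)
    if required is None:
        raise ValueError(f"unknown schema {schema!r}; use 'shift', 'peak' or 'assignment'")

    df = pd.read_csv(path, sep="\t", comment="#")
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")

    n0 = len(df)
    df = df.dropna(subset=list(required))
    if len(df) < n0:
        logger.info("%s: skipped %d row(s) with blank required fields", path, n0 - len(df))

    if schema == "shift":
        return ShiftTable(df["residue"].to_numpy(), df["H_ppm"].to_numpy(), df["N_ppm"].to_numpy())
    if schema == "peak":
        excl = df["excluded"].astype(bool).to_numpy() if "excluded" in df.columns else None
        return PeakTable(
            df["residue"].to_numpy(),
            df["I_lipid"].to_numpy(),
            df["I_water"].to_numpy(),
            df["I_diag"].to_numpy(),
            excluded=excl,
        )
    out: dict[int, list[float]] = {}
    for r, s in zip(df["residue"].astype(int), df["shift_ppm"].astype(float)):
        out.setdefault(int(r), []).append(float(s))
    return out
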