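"""Validation of computed geometry against the reported TLR TM/JM values.

Consumes a user-supplied directory holding the deposited multi-model PDB
files 8AR0 (TLR2), 8AR1 (TLR3), 8AR2 (TLR5) and 8AR3 (TLR9) — never
downloads — and recomputes per-segment average pairwise RMSDs and
interhelical TM/JM angles, comparing each against the published reference
value with its reported spread.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .geometry import HelixSegment, interhelix_angle, pairwise_rmsd
from .io import read_pdb_ensemble

# published per-construct reference geometry: helix segments with
# backbone/heavy average pairwise RMSD (value, sd) in Å, and the TM/JM
# interhelical angle (value, sd) in degrees where one was reported
REFERENCE = {
    "8AR0": {
        "construct": "TLR2tmjm",
        "segments": {
            "H586-G606": {"range": (586, 606), "backbone": (0.45, 0.19), "heavy": (1.27, 0.11)},
            "L615-Q626": {"range": (615, 626), "backbone": (0.54, 0.24), "heavy": (1.39, 0.25)},
        },
        "angle": {"helix1": (586, 606), "helix2": (615, 626), "value": (80.0, 10.0)},
    },
    "8AR1": {
        "construct": "TLR3tmjm",
        "segments": {
            "F702-M707": {"range": (702, 707), "backbone": (0.47, 0.11), "heavy": (2.15, 0.38)},
            "T710-G727": {"range": (710, 727), "backbone": (0.29, 0.22), "heavy": (0.93, 0.13)},
            "S737-L742": {"range": (737, 742), "backbone": (0.52, 0.23), "heavy": (1.47, 0.42)},
        },
        "angle": {"helix1": (710, 727), "helix2": (737, 742), "value": (65.0, 30.0)},
    },
    "8AR2": {
        "construct": "TLR5tmjm",
        "segments": {
            "V634-F643": {"range": (634, 643), "backbone": (1.12, 0.53), "heavy": (1.93, 0.53)},
            "T647-R664": {"range": (647, 664), "backbone": (2.15, 0.43), "heavy": (2.83, 0.35)},
            "C667-L677": {"range": (667, 677), "backbone": (0.78, 0.22), "heavy": (1.64, 0.35)},
        },
        "angle": None,  # U-shaped single long helix; no two-helix angle reported
    },
    "8AR3": {
        "construct": "TLR9tmjm",
        "segments": {
            "C818-M834": {"range": (818, 834), "backbone": (0.50, 0.19), "heavy": (1.04, 0.28)},
            "L843-W853": {"range": (843, 853), "backbone": (0.33, 0.07), "heavy": (1.59, 0.38)},
        },
        "angle": {"helix1": (818, 834), "helix2": (843, 853), "value": (60.0, 20.0)},
    },
}


@dataclass
class ValidationRow:
    accession: str
    quantity: str
    computed: float
    computed_sd: float
    reference: float
    reference_sd: float

    @property
    def within_reference_sd(self) -> bool:
        return abs(self.computed - self.reference) <= self.reference_sd

    @property
    def deviation(self) -> float:
        return self.computed - self.reference


def _seg(rng: tuple[int, int]) -> HelixSegment:
    return HelixSegment(*rng)


def validate_accession_dir(directory: str | Path) -> list[ValidationRow]:
    """Recompute geometry for every deposited file found in ``directory``.

    Files must be named ``<accession>.pdb`` (case-insensitive). Missing
    accessions are simply not reported; an empty directory yields an
    empty report.
    """
    directory = Path(directory)
    rows: list[ValidationRow] = []
    for acc, ref in REFERENCE.items():
        path = None
        for cand in (f"{acc}.pdb", f"{acc.lower()}.pdb"):
            if (directory / cand).exists():
                path = directory / cand
                break
        if path is None:
            continue
        ens = read_pdb_ensemble(path)
        for name, seg in ref["segments"].items():
            for atom_set in ("backbone", "heavy"):
                stat = pairwise_rmsd(ens, _seg(seg["range"]), atom_set=atom_set)
                rows.append(
                    ValidationRow(
                        acc, f"rmsd[{name}][{atom_set}]",
                        stat.mean, stat.sd, *seg[atom_set],
                    )
                )
        if ref["angle"] is not None:
            a = ref["angle"]
            stat = interhelix_angle(ens, _seg(a["helix1"]), _seg(a["helix2"]))
            rows.append(
                ValidationRow(acc, "tm_jm_angle_deg", stat.mean, stat.sd, *a["value"])
            )
    return rows


def format_report(rows: list[ValidationRow]) -> str:
    if not rows:
        return "no deposited ensembles found in the given directory\n"
    lines = [
        f"{'accession':<10}{'quantity':<30}{'computed':>12}{'reference':>16}{'ok':>5}"
    ]
    for r in rows:
        lines.append(
            f"{r.accession:<10}{r.quantity:<30}"
            f"{r.computed:>8.2f}±{r.computed_sd:<4.2f}"
            f"{r.reference:>10.2f}±{r.reference_sd:<4.2f}"
            f"{'yes' if r.within_reference_sd else 'NO':>4}"
        )
    return "\n".join(lines) + "\n"
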