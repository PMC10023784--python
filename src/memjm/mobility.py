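"""Internal mobility maps.

The mobility map of a conformer ensemble is the matrix of standard
deviations of CA(i)–CA(j) distances across conformers. Distances are rigid
invariants, so the map is blind to overall tumbling and highlights genuine
internal rearrangement: low-deviation blocks on the diagonal are rigid
structural domains (individual helices), while a high off-diagonal block
between two helices means their mutual arrangement varies across the set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import StructureEnsemble


@dataclass
class MobilityMap:
    """Symmetric per-residue-pair matrix of CA–CA distance SDs."""

    residues: np.ndarray
    matrix: np.ndarray
    n_conformers: int
    units: str = "nm"


def mobility_map(
    ens: StructureEnsemble,
    residue_range: tuple[int, int] | None = None,
    units: str = "nm",
) -> MobilityMap:
    """Sample SD (ddof=1) of every CA–CA distance over the ensemble.

    Output is in nm by default (Å / 10); pass ``units='angstrom'`` to keep Å.
    """
    if ens.n_models < 2:
        raise ValueError("mobility map needs at least 2 conformers")
    if units not in ("nm", "angstrom"):
        raise ValueError("units must be 'nm' or 'angstrom'")
    ca_mask = ens.mask(res_range=residue_range, atom_names={"CA"})
    residues = ens.res_id[ca_mask]
    order = np.argsort(residues)
    residues = residues[order]
    xyz = ens.coords[:, ca_mask, :][:, order, :]  # (M, n, 3)
    diff = xyz[:, :, None, :] - xyz[:, None, :, :]
    dist = np.linalg.norm(diff, axis=-1)          # (M, n, n)
    sd = dist.std(axis=0, ddof=1)
    np.fill_diagonal(sd, 0.0)
    if units == "nm":
        sd = sd / 10.0
    return MobilityMap(residues, sd, ens.n_models, units)


def rigid_blocks(mob: MobilityMap, cutoff: float = 0.1) -> list[tuple[int, int]]:
    """Maximal diagonal intervals whose internal pairwise SDs are all < cutoff.

    The cutoff is in the map's own units (default 0.1 nm). Returned
    intervals are absolute residue ranges; intervals contained in a longer
    qualifying interval are not reported.
    """
    m = mob.matrix
    n = len(mob.residues)
    blocks: list[tuple[int, int]] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and np.all(m[i : j + 2, i : j + 2][~np.eye(j + 2 - i, dtype=bool)] < cutoff):
            j += 1
        blocks.append((int(mob.residues[i]), int(mob.residues[j])))
        i = j + 1 if j > i else i + 1
    # drop intervals fully contained in an earlier, longer one
    out = []
    for a, b in blocks:
        if not any(a >= a2 and b <= b2 and (a, b) != (a2, b2) for a2, b2 in blocks):
            out.append((a, b))
    return out
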