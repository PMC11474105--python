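"""All-atom reconstruction from backbone plus chi angles.

Side-chain atoms are placed by natural-extension-of-reference-frame (NeRF)
construction from the idealized internal-coordinate templates: every bond
length and bond angle internal to a rigid group matches the template exactly,
and the torsion about each chi axis is the supplied chi angle, so measuring
chi on the output recovers the input.
"""

from __future__ import annotations

import numpy as np

from ..structure import Residue, StructureRecord, TorsionSet
from .rigid import DegenerateGeometryError, dihedral
from .templates import (
    BACKBONE_ANGLES,
    BACKBONE_BONDS,
    CHI_ATOMS,
    CHI_COUNT,
    SIDECHAIN_TEMPLATES,
    ONE_TO_THREE,
)

__all__ = ["nerf_place", "measure_chi", "reconstruct_all_atom"]


def nerf_place(
    p3: np.ndarray, p2: np.ndarray, p1: np.ndarray,
    bond: float, angle_deg: float, torsion_rad: float,
) -> np.ndarray:
    """Place an atom X bonded to ``p1`` with |X-p1| = bond, angle(p2,p1,X) =
    ``angle_deg`` and dihedral(p3,p2,p1,X) = ``torsion_rad``."""
    theta = np.deg2rad(angle_deg)
    bc = p1 - p2
    bc = bc / np.linalg.norm(bc)
    ab = p2 - p3
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise DegenerateGeometryError("collinear reference atoms in NeRF placement")
    n = n / nn
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(torsion_rad),
            bond * np.sin(theta) * np.sin(torsion_rad),
        ]
    )
    return p1 + d[0] * bc + d[1] * m + d[2] * n


def measure_chi(record: StructureRecord) -> TorsionSet:
    """Measure chi1..chi4 on a structure; absent atoms give masked entries."""
    n = len(record)
    angles = np.zeros((n, 4))
    mask = np.zeros((n, 4), dtype=bool)
    for i, res in enumerate(record):
        for k, (a, b, c, d) in enumerate(CHI_ATOMS[res.resname]):
            if all(x in res.atoms for x in (a, b, c, d)):
                angles[i, k] = dihedral(
                    res.atoms[a], res.atoms[b], res.atoms[c], res.atoms[d]
                )
                mask[i, k] = True
    return TorsionSet(angles, mask)


def _place_oxygen(residues: list[Residue]) -> None:
    """Fill missing backbone O atoms; the carbonyl is positioned anti to the
    next residue's N (psi + pi), or at a fixed torsion for the last residue."""
    for i, res in enumerate(residues):
        if "O" in res.atoms:
            continue
        n, ca, c = res.atoms["N"], res.atoms["CA"], res.atoms["C"]
        nxt = residues[i + 1] if i + 1 < len(residues) else None
        if nxt is not None and nxt.chain_id == res.chain_id and "N" in nxt.atoms:
            psi = dihedral(n, ca, c, nxt.atoms["N"])
            torsion = psi + np.pi
        else:
            torsion = np.pi
        res.atoms["O"] = nerf_place(
            n, ca, c,
            BACKBONE_BONDS[("C", "O")],
            BACKBONE_ANGLES[("CA", "C", "O")],
            torsion,
        )


def reconstruct_all_atom(
    record: StructureRecord, torsions: TorsionSet
) -> StructureRecord:
    """Rebuild all side-chain atoms from backbone coordinates and chi angles.

    The input record needs N/CA/C per residue; O is kept if present, placed
    ideally otherwise.  Existing side-chain atoms are discarded and rebuilt.
    """
    if len(torsions.angles) != len(record):
        raise ValueError("torsion set length does not match record")
    out: list[Residue] = []
    for i, res in enumerate(record):
        if res.aa not in ONE_TO_THREE or res.resname not in SIDECHAIN_TEMPLATES:
            raise ValueError(f"unknown residue type {res.aa!r} at index {i}")
        if not res.has_backbone():
            raise ValueError(f"residue {res.chain_id}{res.imgt} lacks backbone atoms")
        n_chi = CHI_COUNT[res.resname]
        if int(torsions.mask[i].sum()) not in (0, n_chi) or np.any(
            torsions.mask[i, n_chi:]
        ):
            raise ValueError(
                f"chi mask at residue {i} inconsistent with {res.resname} "
                f"(expects {n_chi} chi angles)"
            )
        atoms = {
            k: v.copy() for k, v in res.atoms.items() if k in ("N", "CA", "C", "O")
        }
        new = Residue(
            chain_id=res.chain_id, aa=res.aa, imgt=res.imgt, icode=res.icode,
            region=res.region, atoms=atoms,
        )
        for name, (p1, p2, p3), bond, angle, tor in SIDECHAIN_TEMPLATES[res.resname]:
            if tor[0] == "chi":
                _, k, offset = tor
                torsion = torsions.angles[i, k - 1] + np.deg2rad(offset)
            else:
                torsion = np.deg2rad(tor[1])
            new.atoms[name] = nerf_place(
                new.atoms[p3], new.atoms[p2], new.atoms[p1], bond, angle, torsion
            )
        out.append(new)
    _place_oxygen(out)
    return StructureRecord(out, record.plddt)
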