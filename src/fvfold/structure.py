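"""Structure containers: per-residue coordinates, masks and annotations.

``StructureRecord`` is the universal currency passed between the geometry,
loss and metric layers: a paired Fv with per-residue chain id, one-letter
code, IMGT number (integer plus optional insertion code), region label and a
name -> coordinate map for the heavy atoms present.  PDB/mmCIF round-trips go
through gemmi; predicted per-residue confidence (pLDDT, 0-100) is written to
the B-factor column on output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

from .features import RegionLabel, SequencePair, assign_imgt_regions
from .geometry.rigid import Rigid, frames_from_three_points
from .geometry.templates import ONE_TO_THREE, THREE_TO_ONE

__all__ = ["Residue", "StructureRecord", "TorsionSet"]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class Residue:
    chain_id: str  # 'H' or 'L'
    aa: str  # one-letter code
    imgt: int
    icode: str = ""
    region: RegionLabel | None = None
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def resname(self) -> str:
        return ONE_TO_THREE[self.aa]

    def has_backbone(self) -> bool:
        return all(a in self.atoms for a in ("N", "CA", "C"))


@dataclass
class StructureRecord:
    """A paired-Fv structure; residues ordered heavy chain then light chain."""

    residues: list[Residue]
    plddt: np.ndarray | None = None  # per residue, 0-100

    def __post_init__(self):
        chains = {r.chain_id for r in self.residues}
        if not chains <= {"H", "L"}:
            raise ValueError(f"chain ids must be H/L, got {sorted(chains)}")
        for r in self.residues:
            r.atoms = {k: np.asarray(v, dtype=np.float64) for k, v in r.atoms.items()}

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    # -- views ------------------------------------------------------------

    def chain(self, chain_id: str) -> list[Residue]:
        return [r for r in self.residues if r.chain_id == chain_id]

    @property
    def sequence_pair(self) -> SequencePair:
        h = self.chain("H")
        l = self.chain("L")
        return SequencePair(
            heavy="".join(r.aa for r in h),
            light="".join(r.aa for r in l),
            heavy_numbering=[(r.imgt, r.icode) for r in h],
            light_numbering=[(r.imgt, r.icode) for r in l],
        )

    @property
    def regions(self) -> list[RegionLabel]:
        return [r.region for r in self.residues]

    def backbone_coords(self, atoms=("N", "CA", "C")) -> np.ndarray:
        """Stacked coordinates (n_res, len(atoms), 3); requires presence."""
        return np.stack(
            [np.stack([r.atoms[a] for a in atoms]) for r in self.residues]
        )

    def all_atom_points(self) -> tuple[np.ndarray, list[tuple[int, str]]]:
        """Flat (n_atoms, 3) array plus (residue index, atom name) labels."""
        pts, labels = [], []
        for i, r in enumerate(self.residues):
            for name, xyz in r.atoms.items():
                pts.append(xyz)
                labels.append((i, name))
        return np.asarray(pts), labels

    def frames(self) -> Rigid:
        """Per-residue backbone frames (batched Rigid)."""
        bb = self.backbone_coords()
        return frames_from_three_points(bb[:, 0], bb[:, 1], bb[:, 2])

    def transformed(self, transform: Rigid) -> "StructureRecord":
        """A copy with every atom mapped through a global rigid transform."""
        new = []
        for r in self.residues:
            new.append(
                replace(
                    r,
                    atoms={k: transform.apply(v) for k, v in r.atoms.items()},
                )
            )
        return StructureRecord(new, None if self.plddt is None else self.plddt.copy())

    def validate(self) -> None:
        """Check the container invariants; raises ValueError on violation."""
        from .features import IMGT_CDR_RANGES  # noqa: F401 (documented link)

        pair = self.sequence_pair
        expected = assign_imgt_regions(pair)
        for r, exp in zip(self.residues, expected):
            if not r.has_backbone():
                raise ValueError(f"residue {r.chain_id}{r.imgt}{r.icode} lacks N/CA/C")
            if r.region is not None and r.region != exp:
                raise ValueError(
                    f"residue {r.chain_id}{r.imgt}{r.icode}: region {r.region} "
                    f"inconsistent with IMGT number (expected {exp})"
                )

    # -- file IO -----------------------------------------------------------

    def to_file(self, path: str | Path) -> None:
        """Write PDB (default) or mmCIF (by .cif extension); pLDDT, when
        present, goes into the B-factor column scaled 0-100."""
        st = gemmi.Structure()
        st.name = "fvfold"
        model = gemmi.Model("1")
        for chain_id in ("H", "L"):
            ch = gemmi.Chain(chain_id)
            for i, r in enumerate(self.residues):
                if r.chain_id != chain_id:
                    continue
                res = gemmi.Residue()
                res.name = r.resname
                res.seqid = gemmi.SeqId(r.imgt, r.icode if r.icode else " ")
                b = 0.0 if self.plddt is None else float(self.plddt[i])
                for name, xyz in r.atoms.items():
                    at = gemmi.Atom()
                    at.name = name
                    at.element = gemmi.Element(name[0])
                    at.pos = gemmi.Position(*xyz)
                    at.occ = 1.0
                    at.b_iso = b
                    res.add_atom(at)
                ch.add_residue(res)
            model.add_chain(ch)
        st.add_model(model)
        st.setup_entities()
        path = Path(path)
        if path.suffix.lower() in (".cif", ".mmcif"):
            st.make_mmcif_document().write_file(str(path))
        else:
            st.write_pdb(str(path))

    @classmethod
    def from_file(cls, path: str | Path) -> "StructureRecord":
        """Read a paired-Fv PDB/mmCIF with chains H and L; residue numbers are
        interpreted as IMGT positions.  First conformer only."""
        st = gemmi.read_structure(str(path))
        st.setup_entities()
        residues: list[Residue] = []
        plddt: list[float] = []
        model = st[0]
        for chain_id in ("H", "L"):
            chain = model[chain_id]
            for res in chain:
                one = THREE_TO_ONE.get(res.name)
                if one is None:
                    continue
                atoms: dict[str, np.ndarray] = {}
                b = 0.0
                for at in res:
                    if at.name not in atoms:  # first conformer wins
                        atoms[at.name] = np.array(
                            [at.pos.x, at.pos.y, at.pos.z]
                        )
                        b = at.b_iso
                icode = res.seqid.icode.strip()
                residues.append(
                    Residue(
                        chain_id=chain_id,
                        aa=one,
                        imgt=res.seqid.num,
                        icode=icode,
                        atoms=atoms,
                    )
                )
                plddt.append(b)
        rec = cls(residues, plddt=np.asarray(plddt))
        for r, reg in zip(rec.residues, assign_imgt_regions(rec.sequence_pair)):
            r.region = reg
        return rec


@dataclass
class TorsionSet:
    """Per-residue side-chain chi angles, masked by residue type.

    ``angles`` is (n_res, 4) in radians within (-pi, pi]; ``mask`` is
    (n_res, 4) booleans with exactly the canonical chi count of each residue
    type set.
    """

    angles: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.angles.shape != self.mask.shape or self.angles.shape[-1] != 4:
            raise ValueError("angles and mask must both be (n_res, 4)")
        wrapped = np.where(
            self.mask,
            np.mod(self.angles + np.pi, 2 * np.pi) - np.pi,
            self.angles,
        )
        # represent the branch point -pi as +pi
        wrapped = np.where(
            self.mask & np.isclose(wrapped, -np.pi), np.pi, wrapped
        )
        self.angles = wrapped
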