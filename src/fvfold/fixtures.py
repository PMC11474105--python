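"""Deterministic synthetic fixtures: mini paired-Fv structures, controlled
perturbations, SAbDab-like curation tables with planted filter outcomes, and
calibration sets with known retention statistics.

Every generator is a pure function of its spec (seed included), so fixtures
are bitwise reproducible.  The mini-Fv uses a simple extended strand-like
backbone built from the idealized templates — valid stereochemistry plus
full IMGT region structure, with no attempt at real immunoglobulin topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curation import CDR_KEYS, CurationEntry
from .features import (
    IMGT_CDR_RANGES,
    RegionLabel,
    SequencePair,
    assign_imgt_regions,
)
from .geometry.reconstruct import nerf_place, reconstruct_all_atom
from .geometry.templates import (
    AA1,
    BACKBONE_ANGLES,
    BACKBONE_BONDS,
    CHI_COUNT,
    ONE_TO_THREE,
    PEPTIDE_BOND_LENGTH,
)
from .structure import Residue, StructureRecord, TorsionSet

__all__ = [
    "FixtureSpec",
    "make_mini_fv",
    "perturb",
    "CurationTableSpec",
    "make_curation_table",
    "make_calibration_set",
]

# framework segment position capacity under IMGT numbering
_FW_CAPS = (26, 17, 39, 11)  # fw1: ...26, fw2: 39-55, fw3: 66-104, fw4: 118-128
_FW_STARTS = (None, 39, 66, 118)  # fw1 is right-aligned against 26


@dataclass
class FixtureSpec:
    """Layout and randomness of a synthetic paired Fv."""

    n_heavy: int = 26
    n_light: int = 22
    cdr_lengths: tuple[int, ...] = (6, 5, 9, 5, 4, 7)  # H1 H2 H3 L1 L2 L3
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.cdr_lengths) != 6 or any(c < 1 for c in self.cdr_lengths):
            raise ValueError("need six positive CDR lengths")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _chain_numbering(n: int, cdrs: tuple[int, int, int]) -> list[tuple[int, str]]:
    """IMGT numbers plus insertion codes for one chain of length n."""
    c1, c2, c3 = cdrs
    for c, (lo, hi) in zip((c1, c2), (IMGT_CDR_RANGES[1], IMGT_CDR_RANGES[2])):
        if c > hi - lo + 1:
            raise ValueError(f"CDR length {c} exceeds numbering capacity")
    rem = n - c1 - c2 - c3
    if rem < 4:
        raise ValueError("chain too short for four framework segments")
    fw = [1, 1, 1, 1]
    rem -= 4
    i = 0
    while rem > 0:
        if fw[i] < _FW_CAPS[i]:
            fw[i] += 1
            rem -= 1
        i = (i + 1) % 4
        if all(f == c for f, c in zip(fw, _FW_CAPS)) and rem > 0:
            raise ValueError("chain length exceeds numbering capacity")
    numbering: list[tuple[int, str]] = []
    numbering += [(p, "") for p in range(27 - fw[0], 27)]  # fw1, right-aligned
    numbering += [(p, "") for p in range(27, 27 + c1)]
    numbering += [(p, "") for p in range(39, 39 + fw[1])]
    numbering += [(p, "") for p in range(56, 56 + c2)]
    numbering += [(p, "") for p in range(66, 66 + fw[2])]
    if c3 <= 13:
        numbering += [(p, "") for p in range(105, 105 + c3)]
    else:  # long CDR3: insertion codes at position 111
        numbering += [(p, "") for p in range(105, 112)]
        numbering += [(111, chr(ord("A") + k)) for k in range(c3 - 13)]
        numbering += [(p, "") for p in range(112, 118)]
    numbering += [(p, "") for p in range(118, 118 + fw[3])]
    assert len(numbering) == n
    return numbering


def _build_chain(
    residues: list[Residue], rng: np.random.Generator, origin: np.ndarray
) -> None:
    """Extended-strand backbone via NeRF with idealized stereochemistry."""
    phi = -139.0
    psi = 135.0
    jitter = 15.0  # deg, on torsions only: bond geometry stays ideal
    b_nc = BACKBONE_BONDS[("N", "CA")]
    b_cc = BACKBONE_BONDS[("CA", "C")]
    a_ncac = BACKBONE_ANGLES[("N", "CA", "C")]
    first = residues[0]
    first.atoms["N"] = origin + np.zeros(3)
    first.atoms["CA"] = origin + np.array([b_nc, 0.0, 0.0])
    ang = np.deg2rad(180.0 - a_ncac)
    first.atoms["C"] = first.atoms["CA"] + b_cc * np.array(
        [np.cos(ang), np.sin(ang), 0.0]
    )
    prev = first
    for res in residues[1:]:
        psi_i = np.deg2rad(psi + rng.uniform(-jitter, jitter))
        phi_i = np.deg2rad(phi + rng.uniform(-jitter, jitter))
        omega = np.pi
        res.atoms["N"] = nerf_place(
            prev.atoms["N"], prev.atoms["CA"], prev.atoms["C"],
            PEPTIDE_BOND_LENGTH, BACKBONE_ANGLES[("CA", "C", "N+")], psi_i,
        )
        res.atoms["CA"] = nerf_place(
            prev.atoms["CA"], prev.atoms["C"], res.atoms["N"],
            b_nc, BACKBONE_ANGLES[("C", "N+", "CA+")], omega,
        )
        res.atoms["C"] = nerf_place(
            prev.atoms["C"], res.atoms["N"], res.atoms["CA"],
            b_cc, a_ncac, phi_i,
        )
        prev = res


def make_mini_fv(spec: FixtureSpec | None = None) -> StructureRecord:
    """A synthetic paired Fv covering all eight regions.

    Idealized backbone geometry (template bond lengths/angles throughout),
    synthetic IMGT numbering, seeded sequence and side-chain chi angles,
    full atom set.  Deterministic per spec.
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    h_num = _chain_numbering(spec.n_heavy, spec.cdr_lengths[:3])
    l_num = _chain_numbering(spec.n_light, spec.cdr_lengths[3:])
    aa_pool = [a for a in AA1]
    residues: list[Residue] = []
    for chain_id, numbering in (("H", h_num), ("L", l_num)):
        for num, icode in numbering:
            residues.append(
                Residue(
                    chain_id=chain_id,
                    aa=aa_pool[rng.integers(len(aa_pool))],
                    imgt=num,
                    icode=icode,
                )
            )
    heavy = [r for r in residues if r.chain_id == "H"]
    light = [r for r in residues if r.chain_id == "L"]
    _build_chain(heavy, rng, origin=np.zeros(3))
    _build_chain(light, rng, origin=np.array([0.0, 14.0, 6.0]))
    record = StructureRecord(residues)
    for r, region in zip(record, assign_imgt_regions(record.sequence_pair)):
        r.region = region
    # seeded near-anti chi angles; side chains rebuilt from the templates
    n = len(record)
    angles = np.deg2rad(180.0 + rng.uniform(-25, 25, size=(n, 4)))
    mask = np.zeros((n, 4), dtype=bool)
    for i, r in enumerate(record):
        mask[i, : CHI_COUNT[r.resname]] = True
    record = reconstruct_all_atom(record, TorsionSet(angles, mask))
    if spec.noise_sd > 0:
        record = perturb(record, spec.noise_sd, seed=spec.seed + 1)
    return record


def perturb(
    record: StructureRecord,
    noise_sd: float,
    regions: list[RegionLabel | str] | None = None,
    seed: int = 0,
) -> StructureRecord:
    """Seeded isotropic Gaussian displacement of the selected regions' atoms.

    ``regions=None`` perturbs everything; ``noise_sd=0`` is the identity.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if regions is not None:
        regions = [RegionLabel(r) for r in regions]
    rng = np.random.default_rng(seed)
    new: list[Residue] = []
    for r in record:
        atoms = {}
        selected = regions is None or r.region in regions
        for name, xyz in r.atoms.items():
            if selected and noise_sd > 0:
                atoms[name] = xyz + rng.normal(0.0, noise_sd, size=3)
            else:
                atoms[name] = xyz.copy()
        new.append(
            Residue(
                chain_id=r.chain_id, aa=r.aa, imgt=r.imgt, icode=r.icode,
                region=r.region, atoms=atoms,
            )
        )
    return StructureRecord(
        new, None if record.plddt is None else record.plddt.copy()
    )


# -- curation table --------------------------------------------------------

_ORIENT_BASE = np.array([-60.0, 118.0, -52.0, 41.0, 8.0, 16.0])  # typical scales


@dataclass
class CurationTableSpec:
    """Synthetic SAbDab-like table with planted pass/fail per filter."""

    n_entries: int = 200
    planted: dict[str, int] = field(
        default_factory=lambda: {
            "nanobody": 5, "resolution": 5, "orientation": 4,
            "cdrh3_length": 4, "species": 18, "dedup": 7,
        }
    )
    n_validation_eligible: int = 20
    n_legacy_test: int = 4
    seed: int = 0

    def __post_init__(self):
        planted_total = sum(self.planted.values())
        if planted_total + self.n_validation_eligible + self.n_legacy_test > self.n_entries:
            raise ValueError("planted counts exceed table size")


def _random_cdr(rng: np.random.Generator, length: int) -> str:
    return "".join(AA1[rng.integers(20)] for _ in range(length))


def make_curation_table(
    spec: CurationTableSpec | None = None,
) -> tuple[list[CurationEntry], dict[str, str]]:
    """Entries plus an oracle mapping entry_id -> expected outcome.

    Oracle values are the filter stage expected to remove the entry
    (``nanobody``/``resolution``/``orientation``/``cdrh3_length``/
    ``species``/``dedup``), or ``clean``/``validation_eligible``/
    ``legacy_test`` for survivors.  Species-filter plants assume the literal
    (> threshold removed) reading; dedup plants share one CDR with a legacy
    test entry.
    """
    spec = spec or CurationTableSpec()
    rng = np.random.default_rng(spec.seed)
    entries: list[CurationEntry] = []
    oracle: dict[str, str] = {}
    counter = 0
    seen_cdrs: set[str] = set()

    def fresh_cdr(length: int) -> str:
        # unique across the whole table so only deliberate plants collide
        while True:
            s = _random_cdr(rng, length)
            if s not in seen_cdrs:
                seen_cdrs.add(s)
                return s

    def base_entry(tag: str, **overrides) -> CurationEntry:
        nonlocal counter
        counter += 1
        eid = f"syn{counter:04d}"
        oracle[eid] = tag
        stats = _ORIENT_BASE + (1.0 if counter % 2 else -1.0) * np.ones(6)
        fields = dict(
            entry_id=eid,
            species=f"species_{counter:04d}",  # unique: survives literal mode
            resolution=float(rng.uniform(1.5, 3.2)),
            has_light_chain=True,
            orientation_stats=tuple(stats),
            heavy_seq=_random_cdr(rng, 40),
            light_seq=_random_cdr(rng, 38),
            cdr_seqs={
                "cdrh1": fresh_cdr(8), "cdrh2": fresh_cdr(7),
                "cdrh3": fresh_cdr(12), "cdrl1": fresh_cdr(6),
                "cdrl2": fresh_cdr(5), "cdrl3": fresh_cdr(9),
            },
            human_annotated=False,
        )
        fields.update(overrides)
        return CurationEntry(**fields)

    legacy: list[CurationEntry] = []
    for _ in range(spec.n_legacy_test):
        e = base_entry("legacy_test", human_annotated=True)
        legacy.append(e)
        entries.append(e)
    for _ in range(spec.n_validation_eligible):
        entries.append(
            base_entry(
                "validation_eligible",
                human_annotated=True,
                resolution=float(rng.uniform(1.6, 2.4)),
                cdr_seqs={
                    **{k: fresh_cdr(7) for k in CDR_KEYS},
                    "cdrh3": fresh_cdr(24),  # long loop, <= 30
                },
            )
        )
    for _ in range(spec.planted.get("nanobody", 0)):
        entries.append(base_entry("nanobody", has_light_chain=False))
    for _ in range(spec.planted.get("resolution", 0)):
        entries.append(base_entry("resolution", resolution=float(rng.uniform(3.6, 4.5))))
    for _ in range(spec.planted.get("orientation", 0)):
        stats = _ORIENT_BASE.copy()
        stats[int(rng.integers(6))] += 50.0  # far outside 3.5 SD of the pool
        entries.append(base_entry("orientation", orientation_stats=tuple(stats)))
    for _ in range(spec.planted.get("cdrh3_length", 0)):
        entries.append(
            base_entry(
                "cdrh3_length",
                cdr_seqs={
                    **{k: fresh_cdr(7) for k in CDR_KEYS},
                    "cdrh3": fresh_cdr(31 + int(rng.integers(5))),
                },
            )
        )
    for _ in range(spec.planted.get("species", 0)):
        entries.append(base_entry("species", species="mus musculus"))
    for _ in range(spec.planted.get("dedup", 0)):
        shared_from = legacy[int(rng.integers(len(legacy)))]
        shared_key = CDR_KEYS[int(rng.integers(len(CDR_KEYS)))]
        entries.append(
            base_entry(
                "dedup",
                cdr_seqs={
                    **{k: fresh_cdr(7) for k in CDR_KEYS},
                    shared_key: shared_from.cdr_seqs[shared_key],
                },
            )
        )
    n_clean = spec.n_entries - len(entries)
    for _ in range(n_clean):
        entries.append(base_entry("clean"))
    order = rng.permutation(len(entries))
    return [entries[i] for i in order], oracle


def make_calibration_set(
    n: int = 100,
    n_retained: int = 32,
    n_good_retained: int = 26,
    plddt_threshold: float = 85.0,
    rmsd_cutoff: float = 2.0,
    anti_monotone: bool = False,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Planted (pLDDT, RMSD) pairs with known retention statistics.

    Exactly ``n_retained`` scores exceed the threshold and exactly
    ``n_good_retained`` of those have RMSD below the cutoff.  With
    ``anti_monotone`` the pairing is strictly rank-reversed (Spearman -1).
    """
    if not 0 <= n_good_retained <= n_retained <= n:
        raise ValueError("need 0 <= n_good_retained <= n_retained <= n")
    rng = np.random.default_rng(seed)
    hi = rng.uniform(plddt_threshold + 1, plddt_threshold + 12, size=n_retained)
    lo = rng.uniform(plddt_threshold - 30, plddt_threshold - 1, size=n - n_retained)
    good = rng.uniform(0.3 * rmsd_cutoff, 0.95 * rmsd_cutoff, size=n_good_retained)
    bad = rng.uniform(1.05 * rmsd_cutoff, 3 * rmsd_cutoff,
                      size=n_retained - n_good_retained)
    rest = rng.uniform(0.5 * rmsd_cutoff, 4 * rmsd_cutoff, size=n - n_retained)
    plddt = np.concatenate([hi, lo])
    rmsd = np.concatenate([good, bad, rest])
    if anti_monotone:
        plddt = np.sort(plddt)[::-1].copy()
        rmsd = np.sort(rmsd).copy()
        return plddt, rmsd
    order = rng.permutation(n)
    return plddt[order], rmsd[order]
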