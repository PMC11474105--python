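"""Sequence-side features for the paired Fv.

Covers IMGT region annotation, one-hot residue encoding with a chain
indicator, relative positional edge features, and the per-residue embedding
interface.  A deterministic mock embedder stands in for external protein
language models so the full pipeline runs without model downloads; real
embeddings can be supplied through the same ``EmbeddingMatrix`` interface.

Chain order is heavy-then-light everywhere.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
from Bio import SeqIO

__all__ = [
    "RegionLabel",
    "SequencePair",
    "IMGT_CDR_RANGES",
    "AA_ALPHABET",
    "assign_imgt_regions",
    "one_hot_encode",
    "concat_chain_embeddings",
    "mock_embedder",
    "relative_position_encoding",
    "read_fasta_pair",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"  # 20 canonical + X

#: IMGT CDR position ranges (inclusive), identical for both chains.
IMGT_CDR_RANGES = {1: (27, 38), 2: (56, 65), 3: (105, 117)}


class RegionLabel(str, Enum):
    """The eight variable-domain regions: three CDR loops plus the framework
    of each chain."""

    CDRH1 = "CDRH1"
    CDRH2 = "CDRH2"
    CDRH3 = "CDRH3"
    FWH = "FWH"
    CDRL1 = "CDRL1"
    CDRL2 = "CDRL2"
    CDRL3 = "CDRL3"
    FWL = "FWL"

    @property
    def chain(self) -> str:
        return "H" if "H" in self.value else "L"

    @property
    def is_cdr(self) -> bool:
        return self.value.startswith("CDR")


def _region_for(chain: str, imgt: int) -> RegionLabel:
    for cdr, (lo, hi) in IMGT_CDR_RANGES.items():
        if lo <= imgt <= hi:
            return RegionLabel[f"CDR{chain}{cdr}"]
    return RegionLabel[f"FW{chain}"]


@dataclass
class SequencePair:
    """Paired heavy/light variable-region sequences with IMGT numbering.

    ``numbering`` entries are (integer position, insertion code) per residue;
    insertion codes inherit the region of their integer position.
    """

    heavy: str
    light: str
    heavy_numbering: list[tuple[int, str]] = field(default_factory=list)
    light_numbering: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self):
        if not self.heavy or not self.light:
            raise ValueError("a paired Fv requires both a heavy and a light chain")
        for name, seq in (("heavy", self.heavy), ("light", self.light)):
            for i, aa in enumerate(seq):
                if aa not in AA_ALPHABET:
                    raise ValueError(
                        f"unknown amino-acid letter {aa!r} at {name} position {i}"
                    )
        if not self.heavy_numbering:
            self.heavy_numbering = [(i + 1, "") for i in range(len(self.heavy))]
        if not self.light_numbering:
            self.light_numbering = [(i + 1, "") for i in range(len(self.light))]
        if len(self.heavy_numbering) != len(self.heavy) or len(
            self.light_numbering
        ) != len(self.light):
            raise ValueError("numbering length must match sequence length")

    def __len__(self) -> int:
        return len(self.heavy) + len(self.light)

    @property
    def chain_ids(self) -> list[str]:
        return ["H"] * len(self.heavy) + ["L"] * len(self.light)

    @property
    def sequence(self) -> str:
        return self.heavy + self.light


def assign_imgt_regions(pair: SequencePair) -> list[RegionLabel]:
    """Region label per residue (heavy then light) from IMGT numbers.

    CDR1 = positions 27-38, CDR2 = 56-65, CDR3 = 105-117 of each chain;
    everything else is framework.
    """
    labels = [_region_for("H", num) for num, _ in pair.heavy_numbering]
    labels += [_region_for("L", num) for num, _ in pair.light_numbering]
    return labels


def one_hot_encode(pair: SequencePair) -> np.ndarray:
    """One-hot residue encoding plus a two-slot chain indicator.

    Rows are ordered heavy-then-light; width is ``len(AA_ALPHABET) + 2``.
    """
    n = len(pair)
    out = np.zeros((n, len(AA_ALPHABET) + 2))
    for i, (aa, chain) in enumerate(zip(pair.sequence, pair.chain_ids)):
        out[i, AA_ALPHABET.index(aa)] = 1.0
        out[i, len(AA_ALPHABET) + (0 if chain == "H" else 1)] = 1.0
    return out


def concat_chain_embeddings(
    heavy_emb: np.ndarray, light_emb: np.ndarray
) -> np.ndarray:
    """Row-stack separately computed chain embeddings, heavy first."""
    heavy_emb = np.asarray(heavy_emb, dtype=np.float64)
    light_emb = np.asarray(light_emb, dtype=np.float64)
    if heavy_emb.ndim != 2 or light_emb.ndim != 2:
        raise ValueError("embeddings must be 2-D (residues x width)")
    if heavy_emb.shape[1] != light_emb.shape[1]:
        raise ValueError(
            f"embedding widths differ: {heavy_emb.shape[1]} vs {light_emb.shape[1]}"
        )
    return np.vstack([heavy_emb, light_emb])


def _context_row(context: str, chain: str, width: int, seed: int) -> np.ndarray:
    key = f"{context}|{chain}|{width}|{seed}".encode()
    digest = hashlib.sha256(key).digest()
    rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
    return rng.standard_normal(width)

def mock_embedder(pair: SequencePair, width: int = 1024, seed: int = 0) -> np.ndarray:
    """Deterministic stand-in for a protein language-model embedder.

    Each residue's row is a hash-seeded Gaussian vector of its 5-mer sequence
    context within its chain (padded with ``-`` at the termini), so identical
    residues in identical local contexts receive identical rows — a cheap
    analogue of context-dependent embeddings.  Chains are embedded separately
    and concatenated, mirroring the single-chain language-model interface.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    rows = []
    for chain, seq in (("H", pair.heavy), ("L", pair.light)):
        padded = "--" + seq + "--"
        for i in range(len(seq)):
            rows.append(_context_row(padded[i : i + 5], chain, width, seed))
    return np.asarray(rows)


def relative_position_encoding(pair: SequencePair, clip: int = 32) -> np.ndarray:
    """Relative positional edge features.

    Within-chain pairs one-hot encode the sequence offset ``j - i`` clipped to
    ``[-clip, clip]``; every cross-chain pair maps to a dedicated final
    bucket.  Output shape is (n, n, 2*clip + 2).
    """
    if clip < 1:
        raise ValueError("clip must be >= 1")
    n = len(pair)
    chains = np.array([0 if c == "H" else 1 for c in pair.chain_ids])
    # position within the full concatenation; offsets are within-chain indices
    idx = np.concatenate(
        [np.arange(len(pair.heavy)), np.arange(len(pair.light))]
    )
    n_buckets = 2 * clip + 2
    out = np.zeros((n, n, n_buckets))
    same = chains[:, None] == chains[None, :]
    offset = np.clip(idx[None, :] - idx[:, None], -clip, clip) + clip
    ii, jj = np.nonzero(same)
    out[ii, jj, offset[ii, jj]] = 1.0
    ii, jj = np.nonzero(~same)
    out[ii, jj, n_buckets - 1] = 1.0
    return out


def read_numbering_csv(path: str | Path) -> dict[str, list[tuple[int, str]]]:
    """Read precomputed per-residue numbering from CSV.

    Expected columns: ``chain`` (H/L), ``imgt`` (integer), optional ``icode``
    (insertion code).  Rows must be in residue order within each chain.
    """
    import pandas as pd

    df = pd.read_csv(path, dtype={"chain": str, "imgt": int})
    if "icode" not in df.columns:
        df["icode"] = ""
    out: dict[str, list[tuple[int, str]]] = {"H": [], "L": []}
    for _, row in df.iterrows():
        icode = "" if pd.isna(row["icode"]) else str(row["icode"]).strip()
        out[row["chain"].strip().upper()].append((int(row["imgt"]), icode))
    return out


def read_fasta_pair(path: str | Path) -> SequencePair:
    """Read a paired Fv from FASTA: two records whose headers carry an H or L
    chain tag (e.g. ``>ab1|H`` / ``>ab1|L``, or ``heavy`` / ``light``)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    heavy = light = None
    for rec in records:
        ident = rec.description.upper()
        fields = ident.replace("|", " ").replace("_", " ").split()
        if "H" in fields or "HEAVY" in fields:
            heavy = str(rec.seq).upper()
        elif "L" in fields or "LIGHT" in fields:
            light = str(rec.seq).upper()
    if heavy is None or light is None:
        raise ValueError(
            f"{path}: need one heavy-tagged and one light-tagged record"
        )
    return SequencePair(heavy=heavy, light=light)
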