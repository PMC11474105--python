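"""Evaluation: lDDT-Cα, chain-aligned per-region backbone RMSD, pLDDT
aggregation, calibration correlations, and retention curves.

The region-RMSD protocol aligns the heavy and light chains separately onto
the reference structure (Kabsch on the chain's backbone atoms) and then
averages squared backbone-atom deviations over the residues of each CDR and
framework region under that chain's alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .features import RegionLabel
from .geometry.rigid import kabsch_superpose
from .structure import StructureRecord

__all__ = [
    "LddtConfig",
    "RegionReport",
    "lddt_ca",
    "region_rmsd",
    "expected_plddt",
    "aggregate_plddt",
    "calibration",
    "retention_curve",
]


@dataclass
class LddtConfig:
    """Parameters of the per-residue lDDT-Cα score.

    Defaults follow the canonical definition: a 15 A inclusion radius
    measured on the true structure, preservation thresholds 0.5/1/2/4 A,
    strict inequality at both the radius and the thresholds.
    """

    inclusion_radius: float = 15.0
    thresholds: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    include_cross_chain: bool = True

    def __post_init__(self):
        if self.inclusion_radius <= 0:
            raise ValueError("inclusion radius must be positive")
        t = tuple(self.thresholds)
        if any(x <= 0 for x in t) or list(t) != sorted(t):
            raise ValueError("thresholds must be positive ascending")
        self.thresholds = t


@dataclass
class RegionReport:
    """Per-region metric summary; regions without residues report None."""

    rmsd: dict[RegionLabel, float | None] = field(default_factory=dict)
    plddt: dict[RegionLabel, float | None] = field(default_factory=dict)
    counts: dict[RegionLabel, int] = field(default_factory=dict)


def _ca_matrix(record: StructureRecord) -> np.ndarray:
    try:
        return np.stack([r.atoms["CA"] for r in record])
    except KeyError as e:
        raise ValueError("every residue needs a CA atom for lDDT") from e


def lddt_ca(
    pred: StructureRecord, true: StructureRecord, cfg: LddtConfig | None = None
) -> np.ndarray:
    """Per-residue lDDT-Cα of ``pred`` against ``true`` (values in [0, 1]).

    Superposition-free: only inter-Cα distances enter.  For residue i, over
    all partners j with true distance strictly inside the inclusion radius,
    the score is the fraction of pairs whose distance deviation is strictly
    below each threshold, averaged over thresholds.  Residues with no
    neighbours inside the radius score NaN.
    """
    cfg = cfg or LddtConfig()
    if len(pred) != len(true):
        raise ValueError("structures have different residue counts")
    ca_p = _ca_matrix(pred)
    ca_t = _ca_matrix(true)
    d_p = np.linalg.norm(ca_p[:, None] - ca_p[None], axis=-1)
    d_t = np.linalg.norm(ca_t[:, None] - ca_t[None], axis=-1)
    n = len(true)
    mask = (d_t < cfg.inclusion_radius) & ~np.eye(n, dtype=bool)
    if not cfg.include_cross_chain:
        chains = np.array([r.chain_id for r in true])
        mask &= chains[:, None] == chains[None, :]
    dev = np.abs(d_p - d_t)
    frac = np.mean(
        [(dev < thr) for thr in cfg.thresholds], axis=0
    )  # (n, n) in {0, .25, .5, .75, 1}
    counts = mask.sum(axis=1)
    with np.errstate(invalid="ignore"):
        scores = np.where(
            counts > 0, (frac * mask).sum(axis=1) / np.maximum(counts, 1), np.nan
        )
    return scores


BACKBONE_RMSD_ATOMS = ("N", "CA", "C", "O")


def _chain_backbone(record: StructureRecord, chain: str, atoms) -> np.ndarray:
    pts = []
    for r in record.chain(chain):
        for a in atoms:
            if a in r.atoms:
                pts.append(r.atoms[a])
    return np.asarray(pts)


def region_rmsd(
    pred: StructureRecord,
    true: StructureRecord,
    atoms: tuple[str, ...] = BACKBONE_RMSD_ATOMS,
) -> RegionReport:
    """Backbone RMSD per region after per-chain alignment.

    Each chain of ``pred`` is Kabsch-aligned onto the corresponding chain of
    ``true`` using all its backbone atoms; the RMSD of each region is then
    measured over that region's backbone atoms under its chain's alignment.
    Residue correspondence is by order within each (IMGT-numbered) chain.
    """
    if len(pred) != len(true):
        raise ValueError("structures have different residue counts")
    for rp, rt in zip(pred, true):
        if (rp.chain_id, rp.imgt, rp.icode) != (rt.chain_id, rt.imgt, rt.icode):
            raise ValueError(
                f"residue numbering mismatch at {rp.chain_id}{rp.imgt}{rp.icode}"
            )
    report = RegionReport()
    sq_dev: dict[RegionLabel, list[float]] = {r: [] for r in RegionLabel}
    for chain in ("H", "L"):
        if not true.chain(chain):
            raise ValueError(f"empty chain {chain}")
        mob = _chain_backbone(pred, chain, atoms)
        tgt = _chain_backbone(true, chain, atoms)
        transform, _ = kabsch_superpose(mob, tgt)
        for rp, rt in zip(pred.chain(chain), true.chain(chain)):
            for a in atoms:
                if a in rp.atoms and a in rt.atoms:
                    moved = transform.apply(rp.atoms[a])
                    sq_dev[rt.region].append(float(np.sum((moved - rt.atoms[a]) ** 2)))
    for region in RegionLabel:
        devs = sq_dev[region]
        report.counts[region] = sum(
            1 for r in true if r.region == region
        )
        report.rmsd[region] = float(np.sqrt(np.mean(devs))) if devs else None
    return report


def expected_plddt(bins: np.ndarray) -> np.ndarray:
    """Expectation of the binned lDDT distribution, scaled to [0, 100].

    Bin k of n covers [k/n, (k+1)/n); its representative value is the
    midpoint (k + 0.5)/n.
    """
    bins = np.asarray(bins, dtype=np.float64)
    if bins.ndim != 2:
        raise ValueError("bins must be (n_res, n_bins)")
    if np.any(bins < 0) or np.any(np.abs(bins.sum(axis=1) - 1) > 1e-6):
        raise ValueError("rows must be probability distributions")
    n_bins = bins.shape[1]
    centers = (np.arange(n_bins) + 0.5) / n_bins
    return 100.0 * bins @ centers


def aggregate_plddt(
    per_residue: np.ndarray,
    regions: list[RegionLabel],
    scope: RegionLabel | None = None,
) -> float | None:
    """Unweighted mean pLDDT over a region (or the full domain when scope is
    None).  Empty scopes return None."""
    per_residue = np.asarray(per_residue, dtype=np.float64)
    if scope is None:
        sel = np.ones(len(per_residue), dtype=bool)
    else:
        sel = np.array([r == scope for r in regions])
    if not sel.any():
        return None
    return float(per_residue[sel].mean())


def calibration(scores: np.ndarray, rmsds: np.ndarray) -> tuple[float, float]:
    """Pearson and Spearman correlation between per-structure confidence
    scores and RMSDs.  Raises on degenerate (constant) input."""
    scores = np.asarray(scores, dtype=np.float64)
    rmsds = np.asarray(rmsds, dtype=np.float64)
    if scores.shape != rmsds.shape or scores.ndim != 1 or len(scores) < 3:
        raise ValueError("need >=3 paired values")
    if not (np.isfinite(scores).all() and np.isfinite(rmsds).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(scores) == 0 or np.ptp(rmsds) == 0:
        raise ValueError("correlation undefined for constant input")
    pearson = stats.pearsonr(scores, rmsds).statistic
    spearman = stats.spearmanr(scores, rmsds).statistic
    return float(pearson), float(spearman)


def retention_curve(
    plddt: np.ndarray,
    rmsd: np.ndarray,
    plddt_threshold: float = 85.0,
    rmsd_cutoff: float = 2.0,
) -> tuple[float, float | None]:
    """Retention statistics for confidence thresholding.

    Returns the fraction of structures with pLDDT strictly above the
    threshold, and — among those retained — the fraction with RMSD strictly
    below the cutoff (None when nothing is retained).
    """
    plddt = np.asarray(plddt, dtype=np.float64)
    rmsd = np.asarray(rmsd, dtype=np.float64)
    if plddt.shape != rmsd.shape or plddt.ndim != 1 or len(plddt) == 0:
        raise ValueError("need equal-length 1-D inputs")
    retained = plddt > plddt_threshold
    frac = float(retained.mean())
    if not retained.any():
        return frac, None
    return frac, float((rmsd[retained] < rmsd_cutoff).mean())
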