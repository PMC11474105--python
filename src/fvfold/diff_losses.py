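"""Tensor re-expressions of the training objectives.

The public loss functions in :mod:`fvfold.losses` are plain numpy for
oracle-testing; the optimizer needs the same quantities on the autodiff
tape.  These implementations share all constants with the numpy route, and
the test suite pins the two routes together on random inputs.

Gradients flow through the backbone frames and the raw torsion/pLDDT head
outputs.  The all-atom FAPE of the final reconstruction is evaluated on the
numpy route during training (logged, not differentiated): at desk scale the
backbone FAPE and torsion terms carry the geometry, and the idealized
reconstruction is a deterministic function of both.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, matmul, stack
from .geometry.templates import BACKBONE_ANGLES, BACKBONE_LOCAL, PEPTIDE_BOND_LENGTH
from .losses import BOND_SD, VIOLATION_N_SD, FAPE_SCALE
from .structure import TorsionSet

__all__ = [
    "fape_t",
    "backbone_points_t",
    "torsion_angle_loss_t",
    "plddt_loss_t",
    "backbone_violation_t",
]


def _invert_apply_pairwise(rot: Tensor, trans: Tensor, points: Tensor) -> Tensor:
    """Express points (m, 3) in every frame (n, ...): result (n, m, 3)."""
    rinv = rot.swapaxes(-1, -2).expand_dims(1)  # (n, 1, 3, 3)
    rel = points.expand_dims(0) - trans.expand_dims(1)  # (n, m, 3)
    return matmul(rinv, rel.expand_dims(-1)).reshape(rel.shape)


def fape_t(
    rot_pred: Tensor,
    trans_pred: Tensor,
    pred_points: Tensor,
    rot_true: np.ndarray,
    trans_true: np.ndarray,
    true_points: np.ndarray,
    clamp: np.ndarray | float,
    scale: float = FAPE_SCALE,
    eps: float = 1e-8,
) -> Tensor:
    """Clamped frame-aligned point error on the tape (truth is constant)."""
    x_pred = _invert_apply_pairwise(rot_pred, trans_pred, pred_points)
    rinv_true = np.swapaxes(rot_true, -1, -2)
    x_true = np.einsum(
        "nij,nmj->nmi", rinv_true, true_points[None] - trans_true[:, None]
    )
    diff = x_pred - Tensor(x_true)
    d = ((diff * diff).sum(axis=-1) + eps).sqrt()
    return (d.minimum(np.broadcast_to(clamp, d.shape)) * (1.0 / scale)).mean()


def backbone_points_t(rot: Tensor, trans: Tensor) -> Tensor:
    """N, CA, C positions (3n, 3, residue-major) from per-residue frames."""
    n = rot.shape[0]
    pts = []
    for name in ("N", "CA", "C"):
        local = Tensor(np.broadcast_to(BACKBONE_LOCAL[name], (n, 3)).copy())
        pts.append(
            matmul(rot, local.expand_dims(-1)).reshape(n, 3) + trans
        )
    return stack(pts, axis=1).reshape(n * 3, 3)


def torsion_angle_loss_t(
    raw: Tensor,
    true: TorsionSet,
    alt_true: TorsionSet,
    norm_weight: float = 0.02,
) -> Tensor:
    """Tensor version of the chi-angle loss (branch choice is data-driven
    and constant on the tape)."""
    mask = true.mask
    if not mask.any():
        return Tensor(0.0)
    norm = ((raw * raw).sum(axis=-1) + 1e-12).sqrt()  # (n, 4)
    unit = raw / norm.expand_dims(-1)
    v_true = np.stack([np.sin(true.angles), np.cos(true.angles)], axis=-1)
    v_alt = np.stack([np.sin(alt_true.angles), np.cos(alt_true.angles)], axis=-1)
    d_true = (((unit - Tensor(v_true)) ** 2).sum(axis=-1) + 1e-12).sqrt()
    d_alt = (((unit - Tensor(v_alt)) ** 2).sum(axis=-1) + 1e-12).sqrt()
    pick_true = (d_true.data <= d_alt.data).astype(float)
    angle = d_true * pick_true + d_alt * (1.0 - pick_true)
    w = mask.astype(float) / mask.sum()
    angle_term = (angle * w).sum()
    dev = norm - 1.0
    abs_dev = dev.relu() + (-dev).relu()
    return angle_term + norm_weight * (abs_dev * w).sum()


def plddt_loss_t(pred_bins: Tensor, true_lddt: np.ndarray) -> Tensor:
    """Cross-entropy against the one-hot bin of the true per-residue lDDT."""
    from .losses import lddt_bin_index

    n, n_bins = pred_bins.shape
    idx = lddt_bin_index(true_lddt, n_bins)
    p = pred_bins[np.arange(n), idx]
    return -((p + 1e-30).log().mean())


def backbone_violation_t(
    rot: Tensor,
    trans: Tensor,
    chain_ids: list[str],
    n_sd: float = VIOLATION_N_SD,
) -> Tensor:
    """Differentiable flat-bottom peptide-bond term between consecutive
    frames of the same chain (the backbone share of the violation loss)."""
    n = rot.shape[0]
    pts = backbone_points_t(rot, trans).reshape(n, 3, 3)  # (res, atom NCAC, 3)
    same_chain = np.array(
        [chain_ids[i] == chain_ids[i + 1] for i in range(n - 1)], dtype=float
    )
    if same_chain.sum() == 0:
        return Tensor(0.0)
    c_i = pts[:-1, 2]  # C of residue i
    n_next = pts[1:, 0]  # N of residue i+1
    diff = c_i - n_next
    d = ((diff * diff).sum(axis=-1) + 1e-12).sqrt()
    tol = n_sd * BOND_SD
    lo, hi = PEPTIDE_BOND_LENGTH - tol, PEPTIDE_BOND_LENGTH + tol
    over = (d - hi).relu() + (Tensor(np.full(n - 1, lo)) - d).relu()
    return (over * same_chain).sum() * (1.0 / same_chain.sum())
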