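"""The structure module: stacked invariant-point-attention blocks with
backbone updates, plus the torsion and pLDDT heads.

Eight sequential blocks (each with independent weights) update a per-residue
node representation and a per-residue rigid frame, starting from all frames
at the identity at the origin.  Node updates use invariant point attention
(IPA): attention logits combine a scalar query-key product, an edge bias,
and a distance term between query/key points expressed in global
coordinates through the current frames — a construction whose outputs are
invariant under any global rigid motion applied to all frames.  Each block
then composes a small rigid delta onto every frame, parametrised by a
quaternion with fixed unit first component and a local translation.

The final node representation feeds a chi-angle head (full-sequence one-hot
concatenated back in) and a 50-bin pLDDT head.  Everything runs on the
package's autodiff tensors in float64, so predictions are exactly
reproducible given (inputs, weights, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concatenate, matmul, stack
from .features import RegionLabel, SequencePair, assign_imgt_regions, one_hot_encode
from .geometry.reconstruct import reconstruct_all_atom
from .geometry.rigid import Rigid
from .geometry.templates import BACKBONE_LOCAL, CHI_COUNT, ONE_TO_THREE
from .structure import Residue, StructureRecord, TorsionSet

__all__ = [
    "ModelConfig",
    "Trajectory",
    "init_params",
    "ipa_layer",
    "backbone_update",
    "structure_module_forward",
    "torsion_head",
    "plddt_head",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    """Hyperparameters of the structure module.

    IPA channel counts follow the published defaults of the architectural
    family; the block count and bin count are the model's own headline
    settings (eight blocks, fifty pLDDT bins).
    """

    num_blocks: int = 8
    node_width: int = 64
    edge_width: int = 66  # matches relative_position_encoding(clip=32)
    embed_width: int = 23  # one-hot + chain indicator
    heads: int = 4
    scalar_qk: int = 16
    scalar_v: int = 16
    point_qk: int = 4
    point_v: int = 8
    plddt_bins: int = 50
    plddt_hidden: int = 64
    torsion_hidden: int = 64
    weight_init_seed: int = 0
    stop_rotation_gradient: bool = True

    def __post_init__(self):
        if self.num_blocks < 1:
            raise ValueError("num_blocks must be >= 1")
        if self.plddt_bins < 2:
            raise ValueError("plddt_bins must be >= 2")
        for name in ("node_width", "edge_width", "embed_width", "heads",
                     "scalar_qk", "scalar_v", "point_qk", "point_v",
                     "plddt_hidden", "torsion_hidden"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class Trajectory:
    """Per-block frames plus the final node representation."""

    frames: list[Rigid]
    final_nodes: np.ndarray
    # tensor-valued counterparts retained for gradient computation
    frames_t: list[tuple[Tensor, Tensor]] = field(default_factory=list)
    final_nodes_t: Tensor | None = None


# -- parameters -----------------------------------------------------------


def _linear_init(rng, n_in: int, n_out: int, zero: bool = False):
    w = np.zeros((n_in, n_out)) if zero else rng.normal(
        0.0, 1.0 / np.sqrt(n_in), size=(n_in, n_out)
    )
    return Tensor(w, requires_grad=True), Tensor(np.zeros(n_out), requires_grad=True)


def init_params(config: ModelConfig) -> dict[str, Tensor]:
    """Seeded weight initialisation.

    Every block has independent weights.  The backbone-update projection of
    each block is zero-initialised so an untrained model produces identity
    updates and the trajectory starts exactly at the origin.
    """
    rng = np.random.default_rng(config.weight_init_seed)
    p: dict[str, Tensor] = {}

    def add_linear(name, n_in, n_out, zero=False):
        p[f"{name}.w"], p[f"{name}.b"] = _linear_init(rng, n_in, n_out, zero)

    def add_layernorm(name, width):
        p[f"{name}.g"] = Tensor(np.ones(width), requires_grad=True)
        p[f"{name}.o"] = Tensor(np.zeros(width), requires_grad=True)

    add_linear("embed", config.embed_width, config.node_width)
    add_layernorm("embed_ln", config.node_width)
    h, c_qk, c_v = config.heads, config.scalar_qk, config.scalar_v
    pqk, pv = config.point_qk, config.point_v
    for b in range(config.num_blocks):
        pre = f"block{b}"
        add_linear(f"{pre}.q", config.node_width, h * c_qk)
        add_linear(f"{pre}.k", config.node_width, h * c_qk)
        add_linear(f"{pre}.v", config.node_width, h * c_v)
        add_linear(f"{pre}.qp", config.node_width, h * pqk * 3)
        add_linear(f"{pre}.kp", config.node_width, h * pqk * 3)
        add_linear(f"{pre}.vp", config.node_width, h * pv * 3)
        add_linear(f"{pre}.edge_bias", config.edge_width, h)
        p[f"{pre}.gamma"] = Tensor(np.full(h, np.log(np.e - 1)), requires_grad=True)
        concat_width = h * (c_v + config.edge_width + pv * 4)
        add_linear(f"{pre}.out", concat_width, config.node_width)
        add_layernorm(f"{pre}.ipa_ln", config.node_width)
        add_linear(f"{pre}.trans1", config.node_width, config.node_width)
        add_linear(f"{pre}.trans2", config.node_width, config.node_width)
        add_layernorm(f"{pre}.trans_ln", config.node_width)
        add_linear(f"{pre}.bb_update", config.node_width, 6, zero=True)
    add_linear("torsion1", config.node_width + config.embed_width,
               config.torsion_hidden)
    add_linear("torsion2", config.torsion_hidden, 8)
    add_linear("plddt1", config.node_width, config.plddt_hidden)
    add_linear("plddt2", config.plddt_hidden, config.plddt_bins)
    return p


def _linear(p, name, x: Tensor) -> Tensor:
    return matmul(x, p[f"{name}.w"]) + p[f"{name}.b"]


def _layernorm(p, name, x: Tensor, eps: float = 1e-6) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    var = ((x - mu) * (x - mu)).mean(axis=-1, keepdims=True)
    return (x - mu) / (var + eps).sqrt() * p[f"{name}.g"] + p[f"{name}.o"]


def _softplus(x: Tensor) -> Tensor:
    # stable form: relu(x) + log(1 + exp(-|x|)), with -|x| = x - 2 relu(x)
    return x.relu() + ((x - 2.0 * x.relu()).exp() + 1.0).log()


# -- tensor-valued rigid algebra -----------------------------------------


def quat_rot_tensor(bcd: Tensor) -> Tensor:
    """Rotation matrices (n,3,3) from quaternions (1, b, c, d), normalised."""
    n = bcd.shape[0]
    one = Tensor(np.ones((n, 1)))
    q = concatenate([one, bcd], axis=-1)  # (n, 4) = (a, b, c, d)
    norm = (q * q).sum(axis=-1, keepdims=True).sqrt()
    q = q / norm
    a, b, c, d = (q[:, k] for k in range(4))
    row = [
        a * a + b * b - c * c - d * d, 2 * (b * c - a * d), 2 * (b * d + a * c),
        2 * (b * c + a * d), a * a - b * b + c * c - d * d, 2 * (c * d - a * b),
        2 * (b * d - a * c), 2 * (c * d + a * b), a * a - b * b - c * c + d * d,
    ]
    return stack(row, axis=-1).reshape(n, 3, 3)


def frames_compose(
    r1: Tensor, t1: Tensor, r2: Tensor, t2: Tensor
) -> tuple[Tensor, Tensor]:
    """(r1,t1) ∘ (r2,t2): apply the second transform in the first's frame."""
    rot = matmul(r1, r2)
    trans = matmul(r1, t2.expand_dims(-1)).reshape(t1.shape) + t1
    return rot, trans


def frames_apply(r: Tensor, t: Tensor, points: Tensor) -> Tensor:
    """Apply per-residue frames (n,3,3)/(n,3) to points (n,...,3)."""
    extra = points.ndim - 2
    rr, tt = r, t
    for _ in range(extra):
        rr = rr.expand_dims(1)
        tt = tt.expand_dims(1)
    return matmul(rr, points.expand_dims(-1)).reshape(points.shape) + tt


def frames_invert_apply(r: Tensor, t: Tensor, points: Tensor) -> Tensor:
    extra = points.ndim - 2
    rr, tt = r, t
    for _ in range(extra):
        rr = rr.expand_dims(1)
        tt = tt.expand_dims(1)
    rinv = rr.swapaxes(-1, -2)
    return matmul(rinv, (points - tt).expand_dims(-1)).reshape(points.shape)


# -- layers ----------------------------------------------------------------


def ipa_layer(
    params: dict[str, Tensor],
    prefix: str,
    nodes: Tensor,
    edges: Tensor,
    rot: Tensor,
    trans: Tensor,
    config: ModelConfig,
) -> Tensor:
    """One invariant point attention update of the node features.

    Output is invariant to any global rigid transform applied jointly to all
    frames, because frames enter only through inter-point distances in
    global coordinates and through point outputs mapped back to local
    frames.
    """
    n = nodes.shape[0]
    h, c_qk, c_v = config.heads, config.scalar_qk, config.scalar_v
    pqk, pv = config.point_qk, config.point_v
    if edges.shape[:2] != (n, n) or edges.shape[2] != config.edge_width:
        raise ValueError("edge feature shape mismatch")

    q = _linear(params, f"{prefix}.q", nodes).reshape(n, h, c_qk)
    k = _linear(params, f"{prefix}.k", nodes).reshape(n, h, c_qk)
    v = _linear(params, f"{prefix}.v", nodes).reshape(n, h, c_v)
    qp = _linear(params, f"{prefix}.qp", nodes).reshape(n, h, pqk, 3)
    kp = _linear(params, f"{prefix}.kp", nodes).reshape(n, h, pqk, 3)
    vp = _linear(params, f"{prefix}.vp", nodes).reshape(n, h, pv, 3)
    qp_g = frames_apply(rot, trans, qp)
    kp_g = frames_apply(rot, trans, kp)
    vp_g = frames_apply(rot, trans, vp)

    # scalar term: (h, n, n)
    scal = matmul(q.transpose(1, 0, 2), k.transpose(1, 2, 0)) * (
        1.0 / np.sqrt(c_qk)
    )
    scal = scal.transpose(1, 2, 0)  # (n, n, h)
    bias = _linear(params, f"{prefix}.edge_bias", edges)  # (n, n, h)
    diff = qp_g.expand_dims(1) - kp_g.expand_dims(0)  # (n, n, h, pqk, 3)
    sqd = (diff * diff).sum(axis=-1).sum(axis=-1)  # (n, n, h)
    gamma = _softplus(params[f"{prefix}.gamma"])  # (h,)
    w_c = np.sqrt(2.0 / (9.0 * pqk))
    logits = (scal + bias - sqd * gamma * (w_c / 2.0)) * (1.0 / np.sqrt(3.0))
    att = logits.softmax(axis=1)  # over keys j

    att_h = att.transpose(2, 0, 1)  # (h, n, n)
    o_scal = matmul(att_h, v.transpose(1, 0, 2)).transpose(1, 0, 2)  # (n, h, c_v)
    o_edge = (att.expand_dims(-1) * edges.expand_dims(2)).sum(axis=1)  # (n, h, cz)
    o_pt_g = (
        att.expand_dims(-1).expand_dims(-1) * vp_g.expand_dims(0)
    ).sum(axis=1)  # (n, h, pv, 3)
    o_pt = frames_invert_apply(rot, trans, o_pt_g)
    o_pt_norm = ((o_pt * o_pt).sum(axis=-1) + 1e-8).sqrt()  # (n, h, pv)

    cat = concatenate(
        [
            o_scal.reshape(n, h * c_v),
            o_edge.reshape(n, h * config.edge_width),
            o_pt.reshape(n, h * pv * 3),
            o_pt_norm.reshape(n, h * pv),
        ],
        axis=-1,
    )
    update = _linear(params, f"{prefix}.out", cat)
    nodes = _layernorm(params, f"{prefix}.ipa_ln", nodes + update)
    hidden = _linear(params, f"{prefix}.trans1", nodes).relu()
    nodes = _layernorm(
        params, f"{prefix}.trans_ln",
        nodes + _linear(params, f"{prefix}.trans2", hidden),
    )
    return nodes


def backbone_update(
    params: dict[str, Tensor], prefix: str, nodes: Tensor
) -> tuple[Tensor, Tensor]:
    """Per-residue rigid delta from the node features.

    Six numbers per residue: a quaternion (1, b, c, d) and a local-frame
    translation.  Zero network output maps to the identity update.
    """
    out = _linear(params, f"{prefix}.bb_update", nodes)  # (n, 6)
    rot = quat_rot_tensor(out[:, :3])
    return rot, out[:, 3:]


def structure_module_forward(
    embeddings: np.ndarray | Tensor,
    edges: np.ndarray | Tensor,
    config: ModelConfig,
    params: dict[str, Tensor],
    initial_frames: tuple[np.ndarray, np.ndarray] | None = None,
) -> Trajectory:
    """Run all blocks from identity frames at the origin.

    Returns every block's frames (the FAPE objective averages over them) and
    the final node representation.  With ``stop_rotation_gradient`` the
    rotations passed between blocks are detached on the tape, matching the
    training practice of the architectural family.  ``initial_frames``
    overrides the identity start (used to verify equivariance: transforming
    the initial frames transforms every downstream frame identically).
    """
    emb = embeddings if isinstance(embeddings, Tensor) else Tensor(embeddings)
    edg = edges if isinstance(edges, Tensor) else Tensor(edges)
    n = emb.shape[0]
    if emb.shape[1] != config.embed_width:
        raise ValueError(
            f"embedding width {emb.shape[1]} != config.embed_width"
            f" {config.embed_width}"
        )
    nodes = _layernorm(params, "embed_ln", _linear(params, "embed", emb))
    if initial_frames is None:
        rot = Tensor(np.broadcast_to(np.eye(3), (n, 3, 3)).copy())
        trans = Tensor(np.zeros((n, 3)))
    else:
        rot = Tensor(np.asarray(initial_frames[0], dtype=np.float64).copy())
        trans = Tensor(np.asarray(initial_frames[1], dtype=np.float64).copy())
    frames_t: list[tuple[Tensor, Tensor]] = []
    for b in range(config.num_blocks):
        pre = f"block{b}"
        rot_in = rot.detach() if config.stop_rotation_gradient else rot
        nodes = ipa_layer(params, pre, nodes, edg, rot_in, trans, config)
        d_rot, d_trans = backbone_update(params, pre, nodes)
        rot, trans = frames_compose(rot, trans, d_rot, d_trans)
        frames_t.append((rot, trans))
    frames = [Rigid(r.data.copy(), t.data.copy()) for r, t in frames_t]
    return Trajectory(
        frames=frames, final_nodes=nodes.data.copy(),
        frames_t=frames_t, final_nodes_t=nodes,
    )


# -- heads -----------------------------------------------------------------


def torsion_head(
    params: dict[str, Tensor],
    final_nodes: np.ndarray | Tensor,
    pair: SequencePair,
    config: ModelConfig,
) -> tuple[Tensor, TorsionSet]:
    """Raw (sin, cos) chi predictions plus the angle set.

    The full sequence one-hot is concatenated back onto the final nodes.
    Returns the raw (n, 4, 2) tensor (for the torsion loss) and a masked
    ``TorsionSet`` with angles from the epsilon-guarded normalisation.
    """
    nodes = final_nodes if isinstance(final_nodes, Tensor) else Tensor(final_nodes)
    seq_feat = Tensor(one_hot_encode(pair))
    x = concatenate([nodes, seq_feat], axis=-1)
    hidden = _linear(params, "torsion1", x).relu()
    raw = _linear(params, "torsion2", hidden).reshape(nodes.shape[0], 4, 2)
    sincos = raw.data
    norm = np.sqrt((sincos**2).sum(-1, keepdims=True) + 1e-12)
    unit = sincos / norm
    angles = np.arctan2(unit[..., 0], unit[..., 1])
    mask = np.zeros(angles.shape, dtype=bool)
    resnames = [ONE_TO_THREE[a] for a in pair.sequence]
    for i, rn in enumerate(resnames):
        mask[i, : CHI_COUNT[rn]] = True
    return raw, TorsionSet(np.where(mask, angles, 0.0), mask)


def plddt_head(
    params: dict[str, Tensor],
    final_nodes: np.ndarray | Tensor,
    config: ModelConfig,
) -> Tensor:
    """Per-residue categorical distribution over the lDDT bins (softmax MLP)."""
    nodes = final_nodes if isinstance(final_nodes, Tensor) else Tensor(final_nodes)
    hidden = _linear(params, "plddt1", nodes).relu()
    logits = _linear(params, "plddt2", hidden)
    return logits.softmax(axis=-1)


def predict(
    pair: SequencePair,
    embeddings: np.ndarray,
    config: ModelConfig,
    params: dict[str, Tensor],
    edges: np.ndarray | None = None,
) -> tuple[StructureRecord, np.ndarray]:
    """Full inference: forward pass, chi prediction, idealized all-atom
    reconstruction, and per-residue pLDDT (written into the record).

    Deterministic: a pure function of (inputs, weights, config).
    """
    from .features import relative_position_encoding
    from .metrics import expected_plddt

    if len(pair) != np.asarray(embeddings).shape[0]:
        raise ValueError("sequence and embedding lengths differ")
    if edges is None:
        clip = (config.edge_width - 2) // 2
        edges = relative_position_encoding(pair, clip=clip)
    traj = structure_module_forward(embeddings, edges, config, params)
    final = traj.frames[-1]
    regions = assign_imgt_regions(pair)
    numbering = pair.heavy_numbering + pair.light_numbering
    residues = []
    for i, (aa, chain, (num, icode), region) in enumerate(
        zip(pair.sequence, pair.chain_ids, numbering, regions)
    ):
        frame = final[i]
        atoms = {name: frame.apply(local) for name, local in BACKBONE_LOCAL.items()}
        residues.append(
            Residue(chain_id=chain, aa=aa, imgt=num, icode=icode,
                    region=region, atoms=atoms)
        )
    backbone = StructureRecord(residues)
    _, torsions = torsion_head(params, traj.final_nodes, pair, config)
    record = reconstruct_all_atom(backbone, torsions)
    bins = plddt_head(params, traj.final_nodes, config).data
    plddt = expected_plddt(bins)
    record.plddt = plddt
    return record, plddt


# -- checkpointing ---------------------------------------------------------


def save_checkpoint(
    path, params: dict[str, Tensor], config: ModelConfig, seed: int | None = None
) -> None:
    """Weights + config (+ seed) in a single npz container."""
    import json

    arrays = {k: v.data for k, v in params.items()}
    arrays["__config__"] = np.frombuffer(
        json.dumps({"config": vars(config), "seed": seed}).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[dict[str, Tensor], ModelConfig, int | None]:
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["__config__"]).decode())
        params = {
            k: Tensor(data[k], requires_grad=True)
            for k in data.files
            if k != "__config__"
        }
    cfg_dict = meta["config"]
    return params, ModelConfig(**cfg_dict), meta["seed"]
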