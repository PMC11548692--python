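"""Parallel CNN deep-feature encoder for MRP images.

Three independent branches (one per modality: ECG, PCG, coupling) share the same
architecture: 13 convolutional layers (3x3 kernels, stride 1, zero padding that
preserves spatial size, ReLU) organized in 5 sections of (2, 64), (2, 128),
(3, 256), (3, 512), (3, 512) (conv count, kernels), each section closed by a 2x2
max-pool. A 224x224x3 input therefore shrinks 224 -> 112 -> 56 -> 28 -> 14 -> 7,
and the final 7x7x512 map is flattened and projected (ReLU dense layer) to a
2000-d deep code. Branch codes are concatenated in the fixed order
(ecg, pcg, coupling) to form the multi-modal feature.

All tensors are NumPy; convolution is im2col + matmul and the backward pass is
written out explicitly, so forward passes can be checked against naive loops.
``width_divisor`` scales every channel count down for desk-scale runs.

Weight modes:
  * ``random``  — seeded initialization, no training (fixed random features);
  * ``trained`` — per-branch supervised training with a temporary head
    (global average pool -> linear -> 2 classes, cross-entropy), head discarded;
  * ``pretrained`` — weights loaded from a checkpoint file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

MODALITIES = ("ecg", "pcg", "coupling")


@dataclass
class BranchSpec:
    sections: tuple = ((2, 64), (2, 128), (3, 256), (3, 512), (3, 512))
    kernel_size: int = 3
    pool_size: int = 2
    projection_dim: int = 2000
    width_divisor: int = 1

    def channel_plan(self, in_channels: int = 3) -> list[tuple[int, int]]:
        """(in, out) channel pairs for the 13 conv layers after width scaling."""
        plan = []
        c_in = in_channels
        for n_conv, n_kern in self.sections:
            c_out = max(1, n_kern // self.width_divisor)
            for _ in range(n_conv):
                plan.append((c_in, c_out))
                c_in = c_out
        return plan

    def n_conv_layers(self) -> int:
        return sum(n for n, _ in self.sections)

    def final_channels(self) -> int:
        return max(1, self.sections[-1][1] // self.width_divisor)


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    batch: int = 32
    epochs: int = 30
    seed: int = 0


@dataclass
class FeatureBlock:
    """Per-segment deep codes, latents, and the fused multi-modal vector."""

    seg_id: str
    label: int
    deep_code: dict = field(default_factory=dict)  # modality -> projection_dim vec
    latent: dict = field(default_factory=dict)  # modality -> latent vec
    multimodal: np.ndarray | None = None


# ---------------------------------------------------------------------------
# forward primitives


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """[B, C, H, W] -> [B, C*k*k, H*W] patches with zero padding (same size)."""
    B, C, H, W = x.shape
    p = k // 2
    xp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=x.dtype)
    xp[:, :, p : p + H, p : p + W] = x
    cols = np.empty((B, C, k, k, H, W), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + H, j : j + W]
    return cols.reshape(B, C * k * k, H * W)


def _col2im(dcols: np.ndarray, shape: tuple, k: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    B, C, H, W = shape
    p = k // 2
    dxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=dcols.dtype)
    d = dcols.reshape(B, C, k, k, H, W)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + H, j : j + W] += d[:, :, i, j]
    return dxp[:, :, p : p + H, p : p + W]


def conv_forward(
    feature_maps: np.ndarray, kernels: np.ndarray, bias: np.ndarray
) -> np.ndarray:
    """ReLU(3x3 cross-correlation + bias), spatial size preserved.

    ``feature_maps``: [C_in, H, W] or [B, C_in, H, W];
    ``kernels``: [C_out, C_in, k, k]; ``bias``: [C_out].
    """
    single = feature_maps.ndim == 3
    x = feature_maps[None] if single else feature_maps
    Cout, Cin, k, _ = kernels.shape
    if x.shape[1] != Cin:
        raise ValueError(f"channel mismatch: input {x.shape[1]}, kernels {Cin}")
    cols = _im2col(x, k)
    Wmat = kernels.reshape(Cout, Cin * k * k)
    out = np.matmul(Wmat, cols) + bias[:, None]
    out = np.maximum(out, 0.0).reshape(x.shape[0], Cout, x.shape[2], x.shape[3])
    return out[0] if single else out


def maxpool_forward(feature_maps: np.ndarray, pool: int = 2) -> np.ndarray:
    """Non-overlapping window maximum; spatial dims must divide the pool size."""
    single = feature_maps.ndim == 3
    x = feature_maps[None] if single else feature_maps
    B, C, H, W = x.shape
    if H % pool or W % pool:
        raise ValueError("spatial dims must be divisible by the pool size")
    out = x.reshape(B, C, H // pool, pool, W // pool, pool).max(axis=(3, 5))
    return out[0] if single else out


# ---------------------------------------------------------------------------
# branch weights


def init_branch_weights(
    spec: BranchSpec, rng: np.random.Generator, in_channels: int = 3
) -> dict:
    """Seeded uniform fan-in initialization for conv stack + projection layer."""
    k = spec.kernel_size
    convs = []
    for c_in, c_out in spec.channel_plan(in_channels):
        # He-uniform: keeps activation scale roughly constant through the
        # 13-layer ReLU stack (plain fan-in scaling attenuates to ~0 by layer 13)
        bound = np.sqrt(6.0 / (c_in * k * k))
        convs.append(
            {
                "W": rng.uniform(-bound, bound, size=(c_out, c_in, k, k)),
                "b": np.zeros(c_out),
            }
        )
    return {"convs": convs, "proj": None, "spec_meta": _spec_meta(spec)}


def _spec_meta(spec: BranchSpec) -> dict:
    return {
        "sections": [list(s) for s in spec.sections],
        "projection_dim": spec.projection_dim,
        "width_divisor": spec.width_divisor,
    }


def _ensure_projection(
    weights: dict, flat_dim: int, spec: BranchSpec, rng: np.random.Generator
) -> None:
    if weights["proj"] is None:
        bound = np.sqrt(1.0 / flat_dim)
        weights["proj"] = {
            "W": rng.uniform(-bound, bound, size=(spec.projection_dim, flat_dim)),
            "b": np.zeros(spec.projection_dim),
        }


def _branch_forward_maps(
    x: np.ndarray, spec: BranchSpec, weights: dict
) -> np.ndarray:
    """Conv/pool stack only: [B, 3, H, W] -> [B, C_f, H/32, W/32]."""
    layer = 0
    for n_conv, _ in spec.sections:
        for _ in range(n_conv):
            w = weights["convs"][layer]
            x = conv_forward(x, w["W"], w["b"])
            layer += 1
        x = maxpool_forward(x, spec.pool_size)
    return x


def encode_branch(
    image: np.ndarray, spec: BranchSpec, weights: dict, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Encode one HxWx3 image (values in [0, 1]) to a projection_dim deep code."""
    return encode_images(image[None], spec, weights, rng)[0]


def encode_images(
    images: np.ndarray,
    spec: BranchSpec,
    weights: dict,
    rng: np.random.Generator | None = None,
    chunk: int = 8,
) -> np.ndarray:
    """Batched deep codes for [B, H, W, 3] images (chunked to bound memory)."""
    images = np.asarray(images, dtype=float)
    codes = []
    for lo in range(0, len(images), chunk):
        x = images[lo : lo + chunk].transpose(0, 3, 1, 2)
        maps = _branch_forward_maps(x, spec, weights)
        flat = maps.reshape(maps.shape[0], -1)
        if weights["proj"] is None:
            _ensure_projection(
                weights, flat.shape[1], spec, rng or np.random.default_rng(0)
            )
        p = weights["proj"]
        codes.append(np.maximum(flat @ p["W"].T + p["b"], 0.0))
    return np.concatenate(codes, axis=0)


def fuse(codes: dict[str, np.ndarray] | list[np.ndarray]) -> np.ndarray:
    """Concatenate modality vectors in the fixed order (ecg, pcg, coupling)."""
    if isinstance(codes, dict):
        missing = [m for m in MODALITIES if m not in codes]
        if missing:
            raise ValueError(f"missing modality: {missing}")
        parts = [np.asarray(codes[m], dtype=float) for m in MODALITIES]
    else:
        if len(codes) != 3:
            raise ValueError("expected three modality vectors (ecg, pcg, coupling)")
        parts = [np.asarray(c, dtype=float) for c in codes]
    return np.concatenate(parts, axis=-1)


# ---------------------------------------------------------------------------
# training (temporary classification head, discarded after fitting)


def _forward_with_cache(x: np.ndarray, spec: BranchSpec, weights: dict):
    caches = []
    layer = 0
    for n_conv, _ in spec.sections:
        for _ in range(n_conv):
            w = weights["convs"][layer]
            Cout, Cin, k, _ = w["W"].shape
            cols = _im2col(x, k)
            pre = np.matmul(w["W"].reshape(Cout, -1), cols) + w["b"][:, None]
            out = np.maximum(pre, 0.0).reshape(x.shape[0], Cout, x.shape[2], x.shape[3])
            caches.append(("conv", layer, x.shape, cols, pre > 0))
            x = out
            layer += 1
        B, C, H, W = x.shape
        pr = spec.pool_size
        xr = (
            x.reshape(B, C, H // pr, pr, W // pr, pr)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(B, C, H // pr, W // pr, pr * pr)
        )
        idx = xr.argmax(axis=-1)
        caches.append(("pool", None, x.shape, idx, None))
        x = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return x, caches


def _backward(dmaps: np.ndarray, spec: BranchSpec, weights: dict, caches, grads):
    x = dmaps
    for kind, layer, shape, aux, mask in reversed(caches):
        if kind == "pool":
            B, C, H, W = shape
            pr = spec.pool_size
            dxr = np.zeros((B, C, H // pr, W // pr, pr * pr))
            np.put_along_axis(dxr, aux[..., None], x[..., None], axis=-1)
            x = (
                dxr.reshape(B, C, H // pr, W // pr, pr, pr)
                .transpose(0, 1, 2, 4, 3, 5)
                .reshape(B, C, H, W)
            )
        else:
            w = weights["convs"][layer]
            Cout, Cin, k, _ = w["W"].shape
            dpre = x.reshape(x.shape[0], Cout, -1) * mask
            grads[layer]["W"] += np.einsum("bof,bpf->op", dpre, aux).reshape(w["W"].shape)
            grads[layer]["b"] += dpre.sum(axis=(0, 2))
            dcols = np.matmul(w["W"].reshape(Cout, -1).T, dpre)
            x = _col2im(dcols, shape, k)
    return x


def train_branch(
    images: np.ndarray,
    labels: np.ndarray,
    spec: BranchSpec,
    cfg: TrainConfig | None = None,
) -> tuple[dict, list[float]]:
    """Fit one branch's conv weights with a temporary GAP->linear->2 head.

    The head is discarded; the returned weights are for feature extraction.
    Also returns the per-epoch mean cross-entropy trajectory.
    """
    cfg = cfg or TrainConfig()
    images = np.asarray(images, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("single-class training set")
    rng = np.random.default_rng(cfg.seed)
    weights = init_branch_weights(spec, rng)
    Cf = spec.final_channels()
    head_W = rng.uniform(-np.sqrt(1.0 / Cf), np.sqrt(1.0 / Cf), size=(2, Cf))
    head_b = np.zeros(2)
    n = len(images)
    losses = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for lo in range(0, n, cfg.batch):
            sel = order[lo : lo + cfg.batch]
            x = images[sel].transpose(0, 3, 1, 2)
            y = labels[sel]
            maps, caches = _forward_with_cache(x, spec, weights)
            g = maps.mean(axis=(2, 3))  # global average pool
            logits = g @ head_W.T + head_b
            z = logits - logits.max(axis=1, keepdims=True)
            p = np.exp(z)
            p /= p.sum(axis=1, keepdims=True)
            loss = -np.mean(np.log(p[np.arange(len(y)), y] + 1e-12))
            epoch_loss += loss
            n_batches += 1
            dlogits = p.copy()
            dlogits[np.arange(len(y)), y] -= 1.0
            dlogits /= len(y)
            dhead_W = dlogits.T @ g
            dhead_b = dlogits.sum(axis=0)
            dg = dlogits @ head_W
            dmaps = np.broadcast_to(
                dg[:, :, None, None] / (maps.shape[2] * maps.shape[3]), maps.shape
            ).copy()
            grads = [
                {"W": np.zeros_like(w["W"]), "b": np.zeros_like(w["b"])}
                for w in weights["convs"]
            ]
            _backward(dmaps, spec, weights, caches, grads)
            lr = cfg.learning_rate
            for w, gr in zip(weights["convs"], grads):
                w["W"] -= lr * gr["W"]
                w["b"] -= lr * gr["b"]
            head_W -= lr * dhead_W
            head_b -= lr * dhead_b
        losses.append(epoch_loss / max(n_batches, 1))
    weights["head"] = {"W": head_W, "b": head_b}  # kept only for evaluation/tests
    return weights, losses


def head_accuracy(
    images: np.ndarray, labels: np.ndarray, spec: BranchSpec, weights: dict
) -> float:
    """Accuracy of the (normally discarded) auxiliary head on given images."""
    x = np.asarray(images, dtype=float).transpose(0, 3, 1, 2)
    maps = _branch_forward_maps(x, spec, weights)
    g = maps.mean(axis=(2, 3))
    logits = g @ weights["head"]["W"].T + weights["head"]["b"]
    return float(np.mean(logits.argmax(axis=1) == np.asarray(labels, dtype=int)))


def train_branches(
    images_by_modality: dict[str, np.ndarray],
    labels: np.ndarray,
    spec: BranchSpec,
    cfg: TrainConfig | None = None,
) -> dict[str, dict]:
    """Train the three branches independently on training-fold images only."""
    cfg = cfg or TrainConfig()
    out = {}
    for i, mod in enumerate(MODALITIES):
        if mod not in images_by_modality:
            raise ValueError(f"missing modality: {mod}")
        branch_cfg = TrainConfig(
            cfg.learning_rate, cfg.batch, cfg.epochs, cfg.seed + i
        )
        out[mod], _ = train_branch(images_by_modality[mod], labels, spec, branch_cfg)
    return out


# ---------------------------------------------------------------------------
# checkpoints


def save_weights(path: str | Path, weights_by_modality: dict[str, dict], spec: BranchSpec) -> None:
    """Portable checkpoint: one .npz of arrays + a JSON sidecar with the spec."""
    path = Path(path)
    arrays = {}
    for mod, w in weights_by_modality.items():
        for i, layer in enumerate(w["convs"]):
            arrays[f"{mod}/conv{i}/W"] = layer["W"]
            arrays[f"{mod}/conv{i}/b"] = layer["b"]
        if w.get("proj") is not None:
            arrays[f"{mod}/proj/W"] = w["proj"]["W"]
            arrays[f"{mod}/proj/b"] = w["proj"]["b"]
    np.savez(path, **arrays)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(_spec_meta(spec), indent=2))


def load_weights(path: str | Path, spec: BranchSpec) -> dict[str, dict]:
    path = Path(path)
    data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    n_layers = spec.n_conv_layers()
    out: dict[str, dict] = {}
    for mod in MODALITIES:
        if f"{mod}/conv0/W" not in data:
            continue
        convs = [
            {"W": data[f"{mod}/conv{i}/W"], "b": data[f"{mod}/conv{i}/b"]}
            for i in range(n_layers)
        ]
        proj = None
        if f"{mod}/proj/W" in data:
            proj = {"W": data[f"{mod}/proj/W"], "b": data[f"{mod}/proj/b"]}
        out[mod] = {"convs": convs, "proj": proj, "spec_meta": _spec_meta(spec)}
    return out
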