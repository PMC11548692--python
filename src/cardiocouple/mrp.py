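"""Modified recurrence plot (MRP) imaging of 1-D segments.

A segment is delay-embedded into phase space (dimension m, delay tau; the
default m = tau = 1 keeps every sample), pairwise Euclidean distances between
phase-space vectors are computed, and — unlike the classic thresholded
recurrence plot — the raw distances are mapped to a color scale: dark pixels
mean near vectors, bright pixels far ones. Distance matrices from long segments
are made tractable by decimating the signal (anti-aliased polyphase resampling)
to ``target_len`` samples before embedding; the distance image is then resized
to the fixed 224 x 224 x 3 network input by bilinear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.spatial.distance import pdist, squareform
from skimage.transform import resize

IMAGE_SIZE = 224


@dataclass
class EmbeddingConfig:
    m: int = 1
    tau: int = 1
    target_len: int = 1000
    decimate: str = "subsample"  # 'subsample' | 'resample'

    def __post_init__(self) -> None:
        if self.m < 1 or self.tau < 1:
            raise ValueError("m and tau must be positive integers")
        if self.target_len < self.m * self.tau + 1:
            raise ValueError("target_len too small for the embedding")
        if self.decimate not in ("subsample", "resample"):
            raise ValueError("decimate must be 'subsample' or 'resample'")


@dataclass
class MRPImage:
    pixels: np.ndarray  # 224 x 224 x 3, values in [0, 1]
    modality: str  # 'ecg' | 'pcg' | 'coupling'
    seg_id: str


def embed(x: np.ndarray, cfg: EmbeddingConfig) -> np.ndarray:
    """Delay-embedding: row i = [x_i, x_{i+tau}, ..., x_{i+(m-1)tau}]."""
    x = np.asarray(x, dtype=float)
    n_vec = len(x) - (cfg.m - 1) * cfg.tau
    if n_vec < 1:
        raise ValueError("signal too short for embedding")
    idx = np.arange(n_vec)[:, None] + cfg.tau * np.arange(cfg.m)[None, :]
    return x[idx]


def distance_matrix(vectors: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances; symmetric with a zero diagonal."""
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    if vectors.shape[0] < 2:
        raise ValueError("need at least 2 vectors")
    return squareform(pdist(vectors, metric="euclidean"))


def classic_rp(vectors: np.ndarray, epsilon: float) -> np.ndarray:
    """Thresholded recurrence plot: R[i,j] = Theta(eps - d_ij), Theta(0) = 1."""
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    return (distance_matrix(vectors) <= epsilon).astype(int)


def decimate_to(x: np.ndarray, target_len: int, method: str = "subsample") -> np.ndarray:
    """Shorten x to exactly ``target_len`` samples.

    ``subsample`` (default) takes a uniform stride of raw samples. The distance
    matrix sees only sample amplitudes, so this preserves the amplitude
    structure of broadband content (heart-sound bursts, diastolic murmurs) that
    an anti-aliasing low-pass would remove outright — at 500 samples over 10 s
    the anti-aliased Nyquist is 25 Hz, below everything that distinguishes a
    murmur. ``resample`` is anti-aliased polyphase resampling, appropriate for
    smooth narrow-band channels.
    """
    x = np.asarray(x, dtype=float)
    if len(x) == target_len:
        return x.copy()
    if method == "subsample":
        idx = np.round(np.linspace(0, len(x) - 1, target_len)).astype(int)
        return x[idx]
    if method == "resample":
        return sps.resample_poly(x, target_len, len(x))
    raise ValueError("method must be 'subsample' or 'resample'")


def _normalize01(d: np.ndarray) -> np.ndarray:
    lo, hi = d.min(), d.max()
    if hi == lo:  # all-equal distances map to the darkest value
        return np.zeros_like(d)
    return (d - lo) / (hi - lo)


def colorize(norm: np.ndarray) -> np.ndarray:
    """Luminance-monotone 3-channel map: 0 darkest, 1 brightest (grayscale x3)."""
    return np.repeat(norm[..., None], 3, axis=-1)


def render_mrp(
    seg_channel: np.ndarray,
    cfg: EmbeddingConfig | None = None,
    modality: str = "ecg",
    seg_id: str = "",
) -> MRPImage:
    """Full MRP pipeline: decimate, embed, distances, normalize, colorize, resize."""
    cfg = cfg or EmbeddingConfig()
    x = decimate_to(np.asarray(seg_channel, dtype=float), cfg.target_len, cfg.decimate)
    d = distance_matrix(embed(x, cfg))
    img = colorize(_normalize01(d))
    if img.shape[0] != IMAGE_SIZE:
        img = resize(
            img,
            (IMAGE_SIZE, IMAGE_SIZE, 3),
            order=1,  # bilinear
            mode="edge",
            anti_aliasing=False,
            preserve_range=True,
        )
    return MRPImage(
        pixels=np.clip(img, 0.0, 1.0), modality=modality, seg_id=seg_id
    )
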