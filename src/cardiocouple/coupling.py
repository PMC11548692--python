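"""ECG-PCG coupling-signal estimation by circulant deconvolution.

The heart's electrical activity (ECG, x) is modelled as the input to an LTI
electromechanical system whose output is the heart sound (PCG, y):

    y(n) = x(n) * h(n)

h(n) — the coupling signal — is recovered by deconvolution. Padding x with N-1
zeros turns the linear convolution into a circular one of length L = 2N-1, so the
system matrix X with X[i, j] = x_pad[(i - j) mod L] is circulant and diagonalized
by the DFT. The default solver is regularized spectral division

    H(f) = Y(f) conj(X(f)) / (|X(f)|^2 + eps^2),   eps = reg_lambda * max_f |X(f)|

which is the exact Tikhonov solution of min ||Xh - y||^2 + eps^2 ||h||^2 in
O(L log L); a dense direct solver is kept for cross-checking at small L. The
first N samples of the length-L solution are reported as the coupling signal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import circulant

from .io_preprocess import SegmentTriplet, zscore

_DIRECT_MAX_L = 4096


@dataclass
class CouplingSolveConfig:
    """How the circulant system is solved.

    reg_lambda is a relative Tikhonov level: the absolute ridge is
    ``reg_lambda * max |X(f)|``. ``solver`` is ``"spectral"`` (FFT, any L) or
    ``"direct"`` (dense least squares, L <= 4096, used as an oracle).
    """

    reg_lambda: float = 1e-3
    solver: str = "spectral"

    def __post_init__(self) -> None:
        if self.reg_lambda < 0:
            raise ValueError("reg_lambda must be >= 0")
        if self.solver not in ("spectral", "direct"):
            raise ValueError("solver must be 'spectral' or 'direct'")


def pad_to_full(x: np.ndarray) -> np.ndarray:
    """Right-pad a length-N sequence with N-1 zeros to length L = 2N-1."""
    x = np.asarray(x, dtype=float)
    return np.concatenate([x, np.zeros(len(x) - 1)])


def build_convolution_matrix(x: np.ndarray) -> np.ndarray:
    """Circulant system matrix of the padded input: X[i, j] = x_pad[(i-j) mod L].

    Multiplying it by h padded to length L reproduces the linear convolution x*h.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 1:
        raise ValueError("x must be a non-empty 1-D sequence")
    return circulant(pad_to_full(x))


def prepare_target(pcg_seg: np.ndarray) -> np.ndarray:
    """Zero-extend a length-N PCG segment on the right to the length-2N-1 target."""
    y = np.asarray(pcg_seg, dtype=float)
    if y.ndim != 1 or len(y) < 1:
        raise ValueError("pcg_seg must be a non-empty 1-D sequence")
    return np.concatenate([y, np.zeros(len(y) - 1)])


def deconvolve_full(
    x: np.ndarray, y: np.ndarray, cfg: CouplingSolveConfig | None = None
) -> np.ndarray:
    """Length-L solution of the circulant system X h = y."""
    cfg = cfg or CouplingSolveConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    N = len(x)
    L = 2 * N - 1
    if len(y) != L:
        raise ValueError(f"target must have length 2N-1 = {L}, got {len(y)}")
    if not np.any(x):
        raise ValueError("degenerate input")

    xpad = pad_to_full(x)
    X = np.fft.fft(xpad)
    mag = np.abs(X)
    mmax = mag.max()
    if cfg.reg_lambda == 0 and mag.min() < 1e-12 * mmax:
        raise ValueError("ill-conditioned; increase reg_lambda")

    if cfg.solver == "spectral":
        eps = cfg.reg_lambda * mmax
        Y = np.fft.fft(y)
        H = Y * np.conj(X) / (mag**2 + eps**2)
        return np.fft.ifft(H).real
    if L > _DIRECT_MAX_L:
        raise ValueError(f"direct solver limited to L <= {_DIRECT_MAX_L}")
    C = circulant(xpad)
    eps = cfg.reg_lambda * mmax
    if eps == 0:
        return np.linalg.solve(C, y)
    A = C.T @ C + (eps**2) * np.eye(L)
    return np.linalg.solve(A, C.T @ y)


def deconvolve(
    x: np.ndarray, y: np.ndarray, cfg: CouplingSolveConfig | None = None
) -> np.ndarray:
    """First N samples of the circulant-system solution (the coupling signal)."""
    return deconvolve_full(x, y, cfg)[: len(x)]


def couple_segment(
    seg: SegmentTriplet, cfg: CouplingSolveConfig | None = None
) -> SegmentTriplet:
    """Fill ``coupling_seg`` with the z-scored deconvolution of the segment pair."""
    h = deconvolve(seg.ecg_seg, prepare_target(seg.pcg_seg), cfg)
    return replace(seg, coupling_seg=zscore(h))
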