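"""Independent naive-loop oracles used by several test modules."""

import numpy as np


def naive_conv(x, kernels, bias):
    """Explicit 6-loop zero-padded 3x3 cross-correlation + ReLU oracle."""
    Cin, H, W = x.shape
    Cout = kernels.shape[0]
    out = np.zeros((Cout, H, W))
    for o in range(Cout):
        for i in range(H):
            for j in range(W):
                acc = bias[o]
                for c in range(Cin):
                    for di in range(-1, 2):
                        for dj in range(-1, 2):
                            ii, jj = i + di, j + dj
                            if 0 <= ii < H and 0 <= jj < W:
                                acc += kernels[o, c, di + 1, dj + 1] * x[c, ii, jj]
                out[o, i, j] = max(acc, 0.0)
    return out


def naive_pool(x):
    """Brute-force 2x2 window-max scan."""
    C, H, W = x.shape
    out = np.zeros((C, H // 2, W // 2))
    for c in range(C):
        for i in range(0, H, 2):
            for j in range(0, W, 2):
                out[c, i // 2, j // 2] = x[c, i : i + 2, j : j + 2].max()
    return out
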