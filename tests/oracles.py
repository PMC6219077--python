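"""Brute-force reference implementations shared by the test modules.

Each oracle is an independent, direct-from-definition computation used to
check the package's vectorized implementations on small inputs.
"""

import numpy as np


def youden_sweep_oracle(scores, truth):
    """Exhaustive Youden-J maximization over all distinct score cut-points.

    Returns (threshold, J); ties go to the higher threshold.
    """
    best_j, best_th = -np.inf, None
    pos, neg = truth.sum(), (~truth).sum()
    for th in np.unique(scores):
        pred = scores >= th
        sens = (pred & truth).sum() / pos
        spec = (~pred & ~truth).sum() / neg
        j = sens + spec - 1
        if j > best_j + 1e-12 or (abs(j - best_j) <= 1e-12 and th > best_th):
            best_j, best_th = j, th
    return best_th, best_j


def erosion_oracle(mask, size, center):
    """Set definition: keep x iff every structuring-element pixel fits in A
    (pixels outside the frame count as background)."""
    h, w = mask.shape
    out = np.zeros_like(mask)
    offs = [(i - center[0], j - center[1]) for i in range(size) for j in range(size)]
    for r in range(h):
        for c in range(w):
            ok = True
            for dr, dc in offs:
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w) or not mask[rr, cc]:
                    ok = False
                    break
            out[r, c] = ok
    return out


def dilation_oracle(mask, size, center):
    """Set definition: union of structuring-element translates over A,
    clipped to the frame."""
    h, w = mask.shape
    out = np.zeros_like(mask)
    offs = [(i - center[0], j - center[1]) for i in range(size) for j in range(size)]
    for r in range(h):
        for c in range(w):
            if mask[r, c]:
                for dr, dc in offs:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w:
                        out[rr, cc] = True
    return out


def closing_oracle(mask, size, center):
    return erosion_oracle(dilation_oracle(mask, size, center), size, center)


def opening_oracle(mask, size, center):
    return dilation_oracle(erosion_oracle(mask, size, center), size, center)
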