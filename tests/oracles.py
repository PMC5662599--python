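"""Independent brute-force oracles shared across test modules."""

import numpy as np


def brute_force_ratio(donor, fret, mask, window, scale=1000.0):
    """Per-pixel double-loop oracle for the windowed masked FRET/donor
    ratio: sums accumulate in (dr, dc) raster order per pixel."""
    H, W = donor.shape
    h = window // 2
    values = np.full((H, W), np.nan)
    defined = np.zeros((H, W), dtype=bool)
    for r in range(H):
        for c in range(W):
            if not mask[r, c]:
                continue
            sum_f = 0.0
            sum_d = 0.0
            for dr in range(-h, h + 1):
                for dc in range(-h, h + 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < H and 0 <= cc < W and mask[rr, cc]:
                        sum_f += fret[rr, cc]
                        sum_d += donor[rr, cc]
            if sum_d > 0:
                values[r, c] = sum_f / sum_d * scale
                defined[r, c] = True
    return values, defined
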