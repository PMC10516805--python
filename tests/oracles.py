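"""Independent brute-force oracles used to cross-check the implementation."""

import numpy as np


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[frozenset]:
    """Connected components of a boolean mask by explicit stack-based flood fill.

    Returns the partition as a list of frozensets of (row, col) pixels,
    ordered by raster-scan position of each component's first pixel.
    """
    if connectivity == 4:
        steps = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    else:
        steps = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    components = []
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            stack = [(r0, c0)]
            seen[r0, c0] = True
            pixels = []
            while stack:
                r, c = stack.pop()
                pixels.append((r, c))
                for dr, dc in steps:
                    nr, nc = r + dr, c + dc
                    if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and not seen[nr, nc]:
                        seen[nr, nc] = True
                        stack.append((nr, nc))
            components.append(frozenset(pixels))
    return components


def grid_hits_by_enumeration(labels: np.ndarray, rows: int, cols: int, target: int) -> int:
    """Recount grid-point hits with explicitly recomputed lattice coordinates."""
    h, w = labels.shape
    hits = 0
    for i in range(rows):
        for j in range(cols):
            r = int((i + 0.5) * h / rows)
            c = int((j + 0.5) * w / cols)
            if labels[r, c] == target:
                hits += 1
    return hits
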