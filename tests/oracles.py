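"""Slow, independent reference implementations used as test oracles."""

import numpy as np


def exhaustive_otsu_uint8(image: np.ndarray) -> float:
    """Brute-force Otsu over all integer thresholds of an 8-bit image.

    Between-class variance is evaluated independently of the package's
    vectorized implementation; returns the (lowest) argmax threshold with
    foreground = image > t.
    """
    flat = np.asarray(image).ravel().astype(float)
    best_t, best_var = None, -1.0
    for t in range(int(flat.min()), int(flat.max())):
        lo = flat[flat <= t]
        hi = flat[flat > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size, hi.size
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var + 1e-9:
            best_var, best_t = var, t
    return float(best_t)


def flood_fill_components(mask: np.ndarray, connectivity: int = 8):
    """Iterative flood-fill labeling; returns (labels, n_components)."""
    mask = np.asarray(mask, bool)
    labels = np.zeros(mask.shape, int)
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    current = 0
    for r0 in range(mask.shape[0]):
        for c0 in range(mask.shape[1]):
            if mask[r0, c0] and labels[r0, c0] == 0:
                current += 1
                stack = [(r0, c0)]
                labels[r0, c0] = current
                while stack:
                    r, c = stack.pop()
                    for dr, dc in nbrs:
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1]
                                and mask[rr, cc] and labels[rr, cc] == 0):
                            labels[rr, cc] = current
                            stack.append((rr, cc))
    return labels, current


def brute_force_min_pixel_distance(pix_a: np.ndarray, pix_b: np.ndarray) -> float:
    """Minimum Euclidean distance between two pixel-coordinate sets."""
    diffs = pix_a[:, None, :] - pix_b[None, :, :]
    return float(np.sqrt((diffs ** 2).sum(axis=2)).min())


def hand_assembled_unit_square_stiffness(sigma: float = 1.0) -> np.ndarray:
    """FEM stiffness of a unit square split into two triangles, by hand.

    Nodes 0 (0,0), 1 (1,0), 2 (1,1), 3 (0,1); triangles (0,1,2), (0,2,3).
    The textbook element matrix for a unit right triangle with the right
    angle at the middle node is sigma/2 * [[1,-1,0],[-1,2,-1],[0,-1,1]];
    assembling the two elements gives diagonal 1, -1/2 on square edges and
    0 across the diagonal.  Hardcoded so it is independent of any code path.
    """
    return sigma * np.array([
        [1.0, -0.5, 0.0, -0.5],
        [-0.5, 1.0, -0.5, 0.0],
        [0.0, -0.5, 1.0, -0.5],
        [-0.5, 0.0, -0.5, 1.0],
    ])
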