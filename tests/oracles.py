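"""Independent brute-force oracles used by the texture-feature tests.

Deliberately naive (explicit Python loops, per-voxel scans) so the
implementations they check share no code path with the package.
"""

import numpy as np


def brute_glcm_matrix(levels, mask, offset, n_levels):
    """Exhaustive symmetric co-occurrence counting over all voxel pairs."""
    M = np.zeros((n_levels, n_levels))
    Z, Y, X = levels.shape
    for z in range(Z):
        for y in range(Y):
            for x in range(X):
                if not mask[z, y, x]:
                    continue
                z2, y2, x2 = z + offset[0], y + offset[1], x + offset[2]
                if 0 <= z2 < Z and 0 <= y2 < Y and 0 <= x2 < X and mask[z2, y2, x2]:
                    i, j = levels[z, y, x] - 1, levels[z2, y2, x2] - 1
                    M[i, j] += 1
                    M[j, i] += 1
    s = M.sum()
    return M / s if s else None


def _H(values):
    return -sum(v * np.log2(v) for v in values if v > 0)


def brute_glcm_features(p):
    ng = p.shape[0]
    idx = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    px = p.sum(axis=1)
    mux = float((idx * px).sum())
    sx = float(np.sqrt(((idx - mux) ** 2 * px).sum()))
    psum, pdiff = {}, {}
    for i in range(ng):
        for j in range(ng):
            psum[i + j + 2] = psum.get(i + j + 2, 0.0) + p[i, j]
            pdiff[abs(i - j)] = pdiff.get(abs(i - j), 0.0) + p[i, j]
    da = sum(k * v for k, v in pdiff.items())
    return {
        "Autocorrelation": float((ii * jj * p).sum()),
        "Joint Average": mux,
        "Joint Energy": float((p**2).sum()),
        "Joint Entropy": _H(p.ravel()),
        "Contrast": float((((ii - jj) ** 2) * p).sum()),
        "Correlation": (
            float(((ii - mux) * (jj - mux) * p).sum() / (sx * sx)) if sx > 0 else 1.0
        ),
        "Inverse Difference Moment": float((p / (1 + (ii - jj) ** 2)).sum()),
        "Sum Average": sum(k * v for k, v in psum.items()),
        "Sum Entropy": _H(psum.values()),
        "Difference Entropy": _H(pdiff.values()),
        "Difference Variance": sum((k - da) ** 2 * v for k, v in pdiff.items()),
        "Sum of Squares": float((((ii - mux) ** 2) * p).sum()),
        "Cluster Tendency": float((((ii + jj - 2 * mux) ** 2) * p).sum()),
    }


def brute_glrlm_matrix(levels, mask, direction, n_levels):
    """Exhaustive maximal-run enumeration along one direction."""
    Z, Y, X = levels.shape
    d = direction
    runs = []
    for z in range(Z):
        for y in range(Y):
            for x in range(X):
                if not mask[z, y, x]:
                    continue
                pz, py, px = z - d[0], y - d[1], x - d[2]
                if (
                    0 <= pz < Z
                    and 0 <= py < Y
                    and 0 <= px < X
                    and mask[pz, py, px]
                    and levels[pz, py, px] == levels[z, y, x]
                ):
                    continue  # not a run start
                length = 1
                cz, cy, cx = z, y, x
                while True:
                    nz, ny, nx = cz + d[0], cy + d[1], cx + d[2]
                    if (
                        0 <= nz < Z
                        and 0 <= ny < Y
                        and 0 <= nx < X
                        and mask[nz, ny, nx]
                        and levels[nz, ny, nx] == levels[z, y, x]
                    ):
                        length += 1
                        cz, cy, cx = nz, ny, nx
                    else:
                        break
                runs.append((int(levels[z, y, x]), length))
    max_len = max(length for _, length in runs)
    P = np.zeros((n_levels, max_len))
    for g, length in runs:
        P[g - 1, length - 1] += 1
    return P


def brute_glrlm_features(P, n_voxels):
    ng, lm = P.shape
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, lm + 1)[None, :]
    nr = P.sum()
    p = P / nr
    mu = float((p * i).sum())
    return {
        "Short Run Emphasis": float((P / j**2).sum() / nr),
        "Long Run Emphasis": float((P * j.astype(float) ** 2).sum() / nr),
        "Gray Level Non-Uniformity": float((P.sum(axis=1) ** 2).sum() / nr),
        "Run Length Non-Uniformity": float((P.sum(axis=0) ** 2).sum() / nr),
        "Run Length Non-Uniformity Normalized": float(
            (P.sum(axis=0) ** 2).sum() / nr**2
        ),
        "Run Percentage": float(nr / n_voxels),
        "Low Gray Level Run Emphasis": float((P / i.astype(float) ** 2).sum() / nr),
        "High Gray Level Run Emphasis": float((P * i.astype(float) ** 2).sum() / nr),
        "Gray Level Variance": float((p * (i - mu) ** 2).sum()),
        "Run Entropy": _H(p.ravel()),
    }


def dice_vs_truth(seg_labels, truth_labels, truth_id):
    """Dice of a ground-truth organoid against its best-overlap segment."""
    g = truth_labels == truth_id
    n_seg = int(seg_labels.max())
    if n_seg == 0:
        return 0.0
    overlap = np.bincount(seg_labels[g], minlength=n_seg + 1)
    best = int(overlap[1:].argmax()) + 1
    s = seg_labels == best
    return 2.0 * float((g & s).sum()) / float(g.sum() + s.sum())
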