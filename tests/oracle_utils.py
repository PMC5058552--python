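"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (nested loops, exhaustive enumeration,
pairwise counting) and shares no code with the package internals.
"""

from __future__ import annotations

import numpy as np


def window_offsets_bruteforce(radius_m: float, cell_size: float) -> set[tuple[int, int]]:
    k = int(np.ceil(radius_m / cell_size)) + 1
    out = set()
    for di in range(-k, k + 1):
        for dj in range(-k, k + 1):
            if np.hypot(di * cell_size, dj * cell_size) <= radius_m + 1e-9:
                out.add((di, dj))
    return out


def _window_cells(i, j, shape, offsets):
    ny, nx = shape
    for di, dj in offsets:
        ii, jj = i + di, j + dj
        if 0 <= ii < ny and 0 <= jj < nx:
            yield ii, jj


def focal_mean_oracle(values, mask, radius_m, cell_size):
    offsets = window_offsets_bruteforce(radius_m, cell_size)
    ny, nx = values.shape
    out = np.zeros((ny, nx))
    out_mask = np.zeros((ny, nx), dtype=bool)
    for i in range(ny):
        for j in range(nx):
            vals = [values[a, b] for a, b in _window_cells(i, j, values.shape, offsets) if not mask[a, b]]
            if vals:
                out[i, j] = float(np.mean(vals))
            else:
                out_mask[i, j] = True
    return out, out_mask


def focal_std_oracle(values, mask, radius_m, cell_size):
    offsets = window_offsets_bruteforce(radius_m, cell_size)
    ny, nx = values.shape
    out = np.zeros((ny, nx))
    out_mask = np.zeros((ny, nx), dtype=bool)
    for i in range(ny):
        for j in range(nx):
            vals = [values[a, b] for a, b in _window_cells(i, j, values.shape, offsets) if not mask[a, b]]
            if vals:
                out[i, j] = float(np.std(vals))
            else:
                out_mask[i, j] = True
    return out, out_mask


def focal_proportion_oracle(classes, mask, group, radius_m, cell_size):
    offsets = window_offsets_bruteforce(radius_m, cell_size)
    group = set(group)
    ny, nx = classes.shape
    out = np.zeros((ny, nx))
    out_mask = np.zeros((ny, nx), dtype=bool)
    for i in range(ny):
        for j in range(nx):
            cells = [(a, b) for a, b in _window_cells(i, j, classes.shape, offsets) if not mask[a, b]]
            if cells:
                out[i, j] = sum(1 for a, b in cells if classes[a, b] in group) / len(cells)
            else:
                out_mask[i, j] = True
    return out, out_mask


def focal_density_oracle(values, mask, radius_m, cell_size):
    offsets = window_offsets_bruteforce(radius_m, cell_size)
    cell_ha = cell_size**2 / 10_000.0
    ny, nx = values.shape
    out = np.zeros((ny, nx))
    out_mask = np.zeros((ny, nx), dtype=bool)
    for i in range(ny):
        for j in range(nx):
            cells = [(a, b) for a, b in _window_cells(i, j, values.shape, offsets) if not mask[a, b]]
            if cells:
                out[i, j] = sum(values[a, b] for a, b in cells) / (len(cells) * cell_ha)
            else:
                out_mask[i, j] = True
    return out, out_mask


def kappa_bruteforce(scores, labels, thresholds) -> tuple[float, float]:
    """Exhaustive Cohen's kappa over the given thresholds (score >= t rule)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n = len(labels)
    best_k, best_t = -np.inf, None
    for t in thresholds:
        pred = scores >= t
        tp = int((pred & labels).sum())
        fp = int((pred & ~labels).sum())
        fn = int((~pred & labels).sum())
        tn = int((~pred & ~labels).sum())
        po = (tp + tn) / n
        pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
        k = 0.0 if pe >= 1.0 else (po - pe) / (1.0 - pe)
        if k > best_k + 1e-12:
            best_k, best_t = k, t
    return best_k, best_t


def auc_bruteforce(scores, labels) -> float:
    """Pairwise Mann-Whitney count; ties contribute one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def max_ss_threshold_bruteforce(pres_scores, bg_scores) -> float:
    ps = np.asarray(pres_scores, dtype=float)
    bs = np.asarray(bg_scores, dtype=float)
    best_t, best_v = None, -np.inf
    for t in sorted(set(np.concatenate([ps, bs]))):
        v = (ps >= t).mean() + (bs < t).mean()
        if v > best_v + 1e-12:
            best_v, best_t = v, t
    return best_t


def homogeneous_patches_bruteforce(classes, mask, group, radius_m, cell_size, frac=0.5):
    """Selected-cell set and 8-connected component count, the slow way."""
    prop, pmask = focal_proportion_oracle(classes, mask, group, radius_m, cell_size)
    selected = (prop > frac) & ~pmask
    ny, nx = classes.shape
    seen = np.zeros((ny, nx), dtype=bool)
    components = []
    for i in range(ny):
        for j in range(nx):
            if selected[i, j] and not seen[i, j]:
                stack_ = [(i, j)]
                seen[i, j] = True
                comp = []
                while stack_:
                    a, b = stack_.pop()
                    comp.append((a, b))
                    for da in (-1, 0, 1):
                        for db in (-1, 0, 1):
                            aa, bb = a + da, b + db
                            if (
                                0 <= aa < ny
                                and 0 <= bb < nx
                                and selected[aa, bb]
                                and not seen[aa, bb]
                            ):
                                seen[aa, bb] = True
                                stack_.append((aa, bb))
                components.append(comp)
    return selected, components
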