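"""Independent reference implementations used only as test oracles.

These are deliberately naive (loops, textbook formulas) and share no code
with the package under test.
"""

import numpy as np


def naive_growcut_step(labels, strength, feature, offsets, max_norm=1.0):
    """Literal quadruple-loop transcription of the CA transition rule:
    copy the previous state, then let each neighbor attack; the first
    neighbor in scan order achieving the maximal winning force conquers."""
    rows, cols = labels.shape
    new_labels = labels.copy()
    new_strength = strength.copy()
    changed = 0
    for r in range(rows):
        for c in range(cols):
            best = strength[r, c]
            best_label = labels[r, c]
            won = False
            for dr, dc in offsets:
                q_r, q_c = r + dr, c + dc
                if 0 <= q_r < rows and 0 <= q_c < cols:
                    g = 1.0 - abs(feature[r, c] - feature[q_r, q_c]) / max_norm
                    force = g * strength[q_r, q_c]
                    if force > best:
                        best = force
                        best_label = labels[q_r, q_c]
                        won = True
            if won:
                new_labels[r, c] = best_label
                new_strength[r, c] = best
                changed += 1
    return new_labels, new_strength, changed


def naive_growcut(image, seeds, offsets, max_iter=500, max_norm=1.0):
    """Run the naive CA from the seeded initial state to convergence."""
    labels = seeds.astype(np.int8).copy()
    strength = (seeds != 0).astype(float)
    feature = np.asarray(image, dtype=float)
    for _ in range(max_iter):
        labels, strength, changed = naive_growcut_step(labels, strength, feature, offsets, max_norm)
        if changed == 0:
            break
    return labels, strength


def plain_fcm(x, c, m=2.0, max_iter=300, tol=1e-10, v0=None):
    """Textbook fuzzy c-means on a 1-D sample (squared Euclidean distance)."""
    x = np.asarray(x, dtype=float).ravel()
    if v0 is None:
        v = np.quantile(x, (np.arange(c) + 0.5) / c)
    else:
        v = np.asarray(v0, dtype=float).copy()
    u = None
    for _ in range(max_iter):
        d2 = (x[None, :] - v[:, None]) ** 2
        zero = d2 == 0
        any_zero = zero.any(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-1.0 / (m - 1.0))
            u = inv / inv.sum(axis=0, keepdims=True)
        if any_zero.any():
            u[:, any_zero] = zero[:, any_zero] / zero[:, any_zero].sum(axis=0, keepdims=True)
        um = u ** m
        v_new = (um * x[None, :]).sum(axis=1) / um.sum(axis=1)
        if np.max(np.abs(v_new - v)) < tol:
            v = v_new
            break
        v = v_new
    order = np.argsort(v)
    return u[order], v[order]


def neighbor_mean_loop(img):
    """8-neighbor mean (center excluded) with reflected borders, by loops."""
    rows, cols = img.shape
    out = np.zeros_like(img, dtype=float)
    for r in range(rows):
        for c in range(cols):
            acc = 0.0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    # scipy 'reflect' border: edge value duplicated
                    rr = -rr - 1 if rr < 0 else (2 * rows - rr - 1 if rr >= rows else rr)
                    cc = -cc - 1 if cc < 0 else (2 * cols - cc - 1 if cc >= cols else cc)
                    acc += img[rr, cc]
            out[r, c] = acc / 8.0
    return out


def bfs_components(mask, connectivity=8):
    """Connected components by explicit flood fill; returns list of pixel sets."""
    offsets = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    if connectivity == 8:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    rows, cols = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for r in range(rows):
        for c in range(cols):
            if mask[r, c] and not seen[r, c]:
                comp = set()
                stack = [(r, c)]
                seen[r, c] = True
                while stack:
                    pr, pc = stack.pop()
                    comp.add((pr, pc))
                    for dr, dc in offsets:
                        qr, qc = pr + dr, pc + dc
                        if 0 <= qr < rows and 0 <= qc < cols and mask[qr, qc] and not seen[qr, qc]:
                            seen[qr, qc] = True
                            stack.append((qr, qc))
                comps.append(comp)
    return comps


def bfs_fill_holes(mask):
    """Hole filling by flood-filling background from the border (4-connected)."""
    rows, cols = mask.shape
    outside = np.zeros_like(mask, dtype=bool)
    stack = [
        (r, c)
        for r in range(rows)
        for c in range(cols)
        if (r in (0, rows - 1) or c in (0, cols - 1)) and not mask[r, c]
    ]
    for r, c in stack:
        outside[r, c] = True
    while stack:
        pr, pc = stack.pop()
        for dr, dc in ((-1, 0), (0, -1), (0, 1), (1, 0)):
            qr, qc = pr + dr, pc + dc
            if 0 <= qr < rows and 0 <= qc < cols and not mask[qr, qc] and not outside[qr, qc]:
                outside[qr, qc] = True
                stack.append((qr, qc))
    return mask | ~outside
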