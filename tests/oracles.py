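"""Brute-force reference implementations used only by the tests.

Everything here is written as plain per-pixel / per-point loops, kept
deliberately independent of the library's vectorized code paths.
"""

import math

import numpy as np


def brute_confusion(pred, truth):
    tp = fp = fn = tn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            p, t = bool(pred[i, j]), bool(truth[i, j])
            if p and t:
                tp += 1
            elif p and not t:
                fp += 1
            elif not p and t:
                fn += 1
            else:
                tn += 1
    return tp, fp, fn, tn


def brute_overlap_metrics(pred, truth):
    tp, fp, fn, tn = brute_confusion(pred, truth)
    n = tp + fp + fn + tn
    out = {"accuracy": (tp + tn) / n}
    out["precision"] = tp / (tp + fp) if tp + fp else float("nan")
    out["recall"] = tp / (tp + fn) if tp + fn else float("nan")
    if tp + fp + fn:
        out["jaccard"] = tp / (tp + fp + fn)
        out["dice"] = 2 * tp / (2 * tp + fp + fn)
    else:
        out["jaccard"] = out["dice"] = 1.0
    return out


def brute_mae(pred, truth):
    total = 0.0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            total += abs(float(bool(pred[i, j])) - float(bool(truth[i, j])))
    return total / pred.size


def brute_boundary(mask):
    h, w = mask.shape
    pts = []
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            on_border = i in (0, h - 1) or j in (0, w - 1)
            has_bg_nbr = any(
                not mask[i + di, j + dj]
                for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1))
                if 0 <= i + di < h and 0 <= j + dj < w)
            if on_border or has_bg_nbr:
                pts.append((i, j))
    return pts


def brute_hausdorff(a_points, b_points):
    def directed(src, dst):
        worst = 0.0
        for p in src:
            best = min(math.dist(p, q) for q in dst)
            worst = max(worst, best)
        return worst

    return max(directed(a_points, b_points), directed(b_points, a_points))


def random_mask_pair(rng, shape=(16, 16)):
    """A random, non-empty binary mask pair with varying foreground rates."""
    p1, p2 = rng.uniform(0.2, 0.8, size=2)
    pred = (rng.random(shape) < p1).astype(np.uint8)
    truth = (rng.random(shape) < p2).astype(np.uint8)
    # guarantee non-empty so boundary distances are defined
    pred[tuple(rng.integers(0, shape[0], 2))] = 1
    truth[tuple(rng.integers(0, shape[0], 2))] = 1
    return pred, truth
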