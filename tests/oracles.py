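"""Independent brute-force reference implementations used only by tests.

Each oracle is deliberately written in the most literal way possible
(explicit loops, exhaustive scans) so that it shares no code path with the
package implementation it checks.
"""

from itertools import permutations

import numpy as np


def exhaustive_otsu(counts):
    """Smallest k in [0, 255] maximizing w1*w2*(m1-m2)^2, by explicit scan."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    best_k, best_var = 0, -1.0
    for k in range(256):
        n1 = counts[: k + 1].sum()
        n2 = counts[k + 1 :].sum()
        if n1 == 0 or n2 == 0:
            var = 0.0
        else:
            m1 = sum(i * counts[i] for i in range(k + 1)) / n1
            m2 = sum(i * counts[i] for i in range(k + 1, 256)) / n2
            var = (n1 / total) * (n2 / total) * (m1 - m2) ** 2
        if var > best_var:
            best_k, best_var = k, var
    return best_k


def class_means_direct(counts, k):
    """Conditional class means by direct double summation."""
    num1 = den1 = num2 = den2 = 0.0
    for i in range(256):
        if counts[i] == 0:
            continue
        if i <= k:
            num1 += i * counts[i]
            den1 += counts[i]
        else:
            num2 += i * counts[i]
            den2 += counts[i]
    m1 = num1 / den1 if den1 else 0.0
    m2 = num2 / den2 if den2 else 0.0
    return m1, m2


def pixel_confusion_loops(pred, truth, domain):
    """TP/FP/FN/TN by an explicit per-pixel loop."""
    tp = fp = fn = tn = 0
    h, w = pred.shape
    for r in range(h):
        for c in range(w):
            if not domain[r, c]:
                continue
            if pred[r, c] and truth[r, c]:
                tp += 1
            elif pred[r, c]:
                fp += 1
            elif truth[r, c]:
                fn += 1
            else:
                tn += 1
    return tp, fp, fn, tn


def best_assignment_tp(pred_masks, truth_masks, min_iou):
    """Maximum number of one-to-one matches with IoU >= min_iou (exhaustive)."""

    def iou(a, b):
        union = np.count_nonzero(a | b)
        return np.count_nonzero(a & b) / union if union else 0.0

    n_p, n_t = len(pred_masks), len(truth_masks)
    if n_p == 0 or n_t == 0:
        return 0
    best = 0
    if n_p <= n_t:
        for perm in permutations(range(n_t), n_p):
            best = max(best, sum(1 for i, j in zip(range(n_p), perm)
                                 if iou(pred_masks[i], truth_masks[j]) >= min_iou))
    else:
        for perm in permutations(range(n_p), n_t):
            best = max(best, sum(1 for i, j in zip(perm, range(n_t))
                                 if iou(pred_masks[i], truth_masks[j]) >= min_iou))
    return best


def ramanujan_perimeter(a, b):
    """Closed-form ellipse perimeter approximation (Ramanujan I)."""
    h = ((a - b) / (a + b)) ** 2
    return np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))
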