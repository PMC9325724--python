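"""Independent brute-force oracles for the texture-matrix features.

Everything here is written as the most literal possible enumeration over
pixels, pairs, runs and neighbourhoods — deliberately sharing no code with
the package implementations it checks.
"""

import numpy as np

ANGLES = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


def glcm_brute(levels, mask, n_levels, distance=1, angles=ANGLES):
    """Direction-averaged symmetric normalized GLCM by explicit pair loops."""
    h, w = levels.shape
    mats = []
    for dr, dc in angles:
        dr, dc = dr * distance, dc * distance
        counts = np.zeros((n_levels, n_levels))
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                    counts[levels[r, c] - 1, levels[r2, c2] - 1] += 1
                    counts[levels[r2, c2] - 1, levels[r, c] - 1] += 1
        if counts.sum() > 0:
            mats.append(counts / counts.sum())
    return np.mean(mats, axis=0)


def glrlm_brute(levels, mask, n_levels, direction):
    """Run-length counts by walking every scan line pixel by pixel."""
    h, w = levels.shape
    nr = max(h, w)
    counts = np.zeros((n_levels, nr))
    dr, dc = direction
    # starting points: pixels with no predecessor along (dr, dc)
    for r in range(h):
        for c in range(w):
            pr, pc = r - dr, c - dc
            if 0 <= pr < h and 0 <= pc < w:
                continue  # has a predecessor; not a line start
            rr, cc = r, c
            run_val, run_len = None, 0
            while 0 <= rr < h and 0 <= cc < w:
                v = levels[rr, cc] if mask[rr, cc] else None
                if v is not None and v == run_val:
                    run_len += 1
                else:
                    if run_val is not None:
                        counts[run_val - 1, run_len - 1] += 1
                    run_val, run_len = v, (1 if v is not None else 0)
                rr, cc = rr + dr, cc + dc
            if run_val is not None:
                counts[run_val - 1, run_len - 1] += 1
    return counts


def ngtdm_brute(levels, mask, n_levels):
    """Per-level tone-difference sums and counts by explicit neighbourhoods."""
    h, w = levels.shape
    s = np.zeros(n_levels)
    n = np.zeros(n_levels)
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            nbrs = []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < h and 0 <= c2 < w and mask[r2, c2]:
                        nbrs.append(levels[r2, c2])
            if not nbrs:
                continue
            i = levels[r, c]
            s[i - 1] += abs(i - np.mean(nbrs))
            n[i - 1] += 1
    return s, n


def auc_pairs_brute(scores, labels):
    """AUC as the fraction of positive-negative pairs ranked correctly,
    ties counted half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def icc_2_1_brute(Y):
    """ICC(2,1) from explicitly accumulated ANOVA sums of squares."""
    Y = np.asarray(Y, float)
    n, k = Y.shape
    grand = Y.sum() / (n * k)
    ss_rows = sum(k * (Y[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (Y[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((Y[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def binary_metrics_brute(y_true, y_pred):
    """Metric suite by literal counting loops."""
    tp = fp = fn = tn = 0
    for t, p in zip(y_true, y_pred):
        if t == 1 and p == 1:
            tp += 1
        elif t == 0 and p == 1:
            fp += 1
        elif t == 1 and p == 0:
            fn += 1
        else:
            tn += 1
    div = lambda a, b: a / b if b else None
    return {
        "sensitivity": div(tp, tp + fn),
        "specificity": div(tn, tn + fp),
        "accuracy": div(tp + tn, tp + fp + fn + tn),
        "ppv": div(tp, tp + fp),
        "npv": div(tn, tn + fn),
    }
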