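"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive (double loops, direct formula
evaluation) and shares no code with the package implementation.
"""

from __future__ import annotations

import numpy as np


def glcm_brute(levels: np.ndarray, offset: tuple[int, int], ng: int) -> np.ndarray:
    """Symmetrized co-occurrence counts by explicit pair enumeration.

    ``levels`` is (n_slices, nrow, ncol) with 0 = out of mask.
    """
    if levels.ndim == 2:
        levels = levels[None]
    dr, dc = offset
    counts = np.zeros((ng, ng), dtype=np.int64)
    for sl in levels:
        nrow, ncol = sl.shape
        for r in range(nrow):
            for c in range(ncol):
                a = sl[r, c]
                if a == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < nrow and 0 <= cc < ncol and sl[rr, cc] > 0:
                    b = sl[rr, cc]
                    counts[a - 1, b - 1] += 1
                    counts[b - 1, a - 1] += 1
    return counts


def glcm_features_naive(p: np.ndarray) -> dict[str, float]:
    """Direct double-loop evaluation of the co-occurrence statistics."""
    ng = p.shape[0]
    mu_x = sum((i + 1) * p[i, j] for i in range(ng) for j in range(ng))
    mu_y = sum((j + 1) * p[i, j] for i in range(ng) for j in range(ng))
    var_x = sum((i + 1 - mu_x) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    var_y = sum((j + 1 - mu_y) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    sx, sy = np.sqrt(var_x), np.sqrt(var_y)
    mu = 0.5 * (mu_x + mu_y)
    out = {
        "contrast": sum(
            (i - j) ** 2 * p[i, j] for i in range(ng) for j in range(ng)
        ),
        "variance": sum(
            (i + 1 - mu) ** 2 * p[i, j] for i in range(ng) for j in range(ng)
        ),
        "energy": sum(p[i, j] ** 2 for i in range(ng) for j in range(ng)),
        "entropy": -sum(
            p[i, j] * np.log2(p[i, j])
            for i in range(ng)
            for j in range(ng)
            if p[i, j] > 0
        ),
    }
    if sx * sy == 0:
        out["correlation"] = np.nan
    else:
        out["correlation"] = (
            sum(
                (i + 1 - mu_x) * (j + 1 - mu_y) * p[i, j]
                for i in range(ng)
                for j in range(ng)
            )
            / (sx * sy)
        )
    return out


#: direction_index -> step (d_row, d_col); must mirror the package convention
RL_STEPS = {1: (0, 1), 2: (-1, 1), 3: (1, 0)}


def rlm_brute(levels: np.ndarray, direction: int, ng: int) -> np.ndarray:
    """Maximal-run counting by walking every line voxel by voxel."""
    if levels.ndim == 2:
        levels = levels[None]
    dr, dc = RL_STEPS[direction]
    nrow, ncol = levels.shape[1], levels.shape[2]
    out = np.zeros((ng, max(nrow, ncol)), dtype=np.int64)

    def inside(r, c):
        return 0 <= r < nrow and 0 <= c < ncol

    for sl in levels:
        for r in range(nrow):
            for c in range(ncol):
                lvl = sl[r, c]
                if lvl == 0:
                    continue
                pr, pc = r - dr, c - dc
                # run starts here iff the predecessor does not continue it
                if inside(pr, pc) and sl[pr, pc] == lvl:
                    continue
                length = 1
                rr, cc = r + dr, c + dc
                while inside(rr, cc) and sl[rr, cc] == lvl:
                    length += 1
                    rr += dr
                    cc += dc
                out[lvl - 1, length - 1] += 1
    return out


def rlm_features_naive(r: np.ndarray) -> dict[str, float]:
    nr = r.sum()
    ng, ml = r.shape
    sre = lre = lrlge = lrhge = energy = 0.0
    for i in range(ng):
        for j in range(ml):
            if r[i, j] == 0:
                continue
            sre += r[i, j] / (j + 1) ** 2
            lre += (j + 1) ** 2 * r[i, j]
            lrlge += (j + 1) ** 2 * r[i, j] / (i + 1) ** 2
            lrhge += (i + 1) ** 2 * (j + 1) ** 2 * r[i, j]
            energy += (r[i, j] / nr) ** 2
    return {
        "SRE": sre / nr,
        "LRE": lre / nr,
        "LRLGE": lrlge / nr,
        "LRHGE": lrhge / nr,
        "energy": energy,
    }


def cox_partial_loglik(beta: float, times, events, x) -> float:
    """Breslow partial log-likelihood for one covariate (no tied events)."""
    ll = 0.0
    for i in range(len(times)):
        if events[i] != 1:
            continue
        risk = [j for j in range(len(times)) if times[j] >= times[i]]
        ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
    return ll


def icc21_naive(a, b) -> float:
    """ICC(2,1) from the raw two-way ANOVA sums of squares."""
    y = np.column_stack([np.asarray(a, float), np.asarray(b, float)])
    n, k = y.shape
    grand = y.mean()
    ss_rows = k * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_tot = ((y - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
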