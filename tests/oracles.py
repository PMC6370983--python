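"""Independent brute-force oracles for the texture, distance and AUC code.

Everything here is deliberately written as plain double loops over matrix
entries and pixel pairs, sharing no code with the package's vectorized
implementations, so agreement is a meaningful check.
"""

from __future__ import annotations

import math

import numpy as np

OFFSETS = ((0, 1), (-1, 0), (0, -1), (1, 0))


def glcm_brute(levels: np.ndarray, G: int, offset) -> np.ndarray:
    dr, dc = offset
    nr, nc = levels.shape
    P = np.zeros((G, G))
    for r in range(nr):
        for c in range(nc):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < nr and 0 <= c2 < nc:
                P[levels[r, c] - 1, levels[r2, c2] - 1] += 1
    return P / P.sum()


def haralick_brute(P: np.ndarray) -> dict[str, float]:
    """All 14 statistics of one normalized matrix, by explicit loops."""
    G = P.shape[0]
    px = [sum(P[i, j] for j in range(G)) for i in range(G)]
    py = [sum(P[i, j] for i in range(G)) for j in range(G)]
    mux = sum((i + 1) * px[i] for i in range(G))
    muy = sum((j + 1) * py[j] for j in range(G))
    sx = math.sqrt(sum((i + 1 - mux) ** 2 * px[i] for i in range(G)))
    sy = math.sqrt(sum((j + 1 - muy) ** 2 * py[j] for j in range(G)))
    psum = [0.0] * (2 * G + 1)   # index by k = i+j, 2..2G
    pdif = [0.0] * G             # index by k = |i-j|
    for i in range(G):
        for j in range(G):
            psum[i + j + 2] += P[i, j]
            pdif[abs(i - j)] += P[i, j]

    def ent(ps):
        return -sum(p * math.log(p) for p in ps if p > 0)

    asm = sum(P[i, j] ** 2 for i in range(G) for j in range(G))
    contrast = sum(k * k * pdif[k] for k in range(G))
    if sx > 0 and sy > 0:
        corr = (sum((i + 1) * (j + 1) * P[i, j]
                    for i in range(G) for j in range(G)) - mux * muy) / (sx * sy)
    else:
        corr = 0.0
    var = sum((i + 1 - mux) ** 2 * P[i, j] for i in range(G) for j in range(G))
    idm = sum(P[i, j] / (1 + (i - j) ** 2) for i in range(G) for j in range(G))
    sa = sum(k * psum[k] for k in range(2, 2 * G + 1))
    sv = sum((k - sa) ** 2 * psum[k] for k in range(2, 2 * G + 1))
    se = ent(psum)
    e = ent(P.ravel())
    da = sum(k * pdif[k] for k in range(G))
    dv = sum((k - da) ** 2 * pdif[k] for k in range(G))
    de = ent(pdif)
    hx, hy = ent(px), ent(py)
    hxy1 = -sum(P[i, j] * math.log(px[i] * py[j])
                for i in range(G) for j in range(G) if px[i] * py[j] > 0)
    hxy2 = -sum(px[i] * py[j] * math.log(px[i] * py[j])
                for i in range(G) for j in range(G) if px[i] * py[j] > 0)
    imc1 = (e - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - e))))

    rows = [i for i in range(G) if px[i] > 0]
    cols = [k for k in range(G) if py[k] > 0]
    if len(rows) < 2:
        mcc = 0.0
    else:
        Q = np.zeros((len(rows), len(rows)))
        for a, i in enumerate(rows):
            for b, j in enumerate(rows):
                Q[a, b] = sum(P[i, k] * P[j, k] / (px[i] * py[k])
                              for k in cols)
        ev = sorted(np.linalg.eigvals(Q).real, reverse=True)
        mcc = math.sqrt(max(0.0, ev[1])) if len(ev) >= 2 else 0.0
    return {
        "angular_second_moment": asm, "contrast": contrast,
        "correlation": corr, "glcm_variance": var,
        "inverse_difference_moment": idm, "sum_average": sa,
        "sum_variance": sv, "sum_entropy": se, "entropy": e,
        "difference_variance": dv, "difference_entropy": de,
        "info_measure_correlation_1": imc1, "info_measure_correlation_2": imc2,
        "maximal_correlation_coefficient": mcc,
    }


def haralick_brute_mean(levels: np.ndarray, G: int) -> dict[str, float]:
    per = [haralick_brute(glcm_brute(levels, G, off)) for off in OFFSETS]
    return {k: float(np.mean([d[k] for d in per])) for k in per[0]}


def rlm_brute(levels: np.ndarray, G: int, direction) -> np.ndarray:
    """Run-length matrix by walking each scan line pixel by pixel."""
    lines = levels if direction[0] == 0 else levels.T
    if direction in ((0, -1), (1, 0)):
        lines = lines[:, ::-1]
    lmax = lines.shape[1]
    R = np.zeros((G, lmax))
    for line in lines:
        run_level, run_len = line[0], 1
        for v in line[1:]:
            if v == run_level:
                run_len += 1
            else:
                R[run_level - 1, run_len - 1] += 1
                run_level, run_len = v, 1
        R[run_level - 1, run_len - 1] += 1
    return R


def glrl_brute(levels: np.ndarray, G: int, direction) -> dict[str, float]:
    R = rlm_brute(levels, G, direction)
    lmax = R.shape[1]
    n_r = R.sum()
    n_p = levels.size
    s = {k: 0.0 for k in ("sre", "lre", "gln", "rln", "lglre", "hglre",
                          "srlgle", "srhgle", "lrlgle", "lrhgle")}
    for i in range(1, G + 1):
        for j in range(1, lmax + 1):
            r = R[i - 1, j - 1]
            s["sre"] += r / j ** 2
            s["lre"] += r * j ** 2
            s["lglre"] += r / i ** 2
            s["hglre"] += r * i ** 2
            s["srlgle"] += r / (i ** 2 * j ** 2)
            s["srhgle"] += r * i ** 2 / j ** 2
            s["lrlgle"] += r * j ** 2 / i ** 2
            s["lrhgle"] += r * i ** 2 * j ** 2
    gln = sum(sum(R[i - 1, j - 1] for j in range(1, lmax + 1)) ** 2
              for i in range(1, G + 1))
    rln = sum(sum(R[i - 1, j - 1] for i in range(1, G + 1)) ** 2
              for j in range(1, lmax + 1))
    out = {
        "short_run_emphasis": s["sre"] / n_r,
        "long_run_emphasis": s["lre"] / n_r,
        "gray_level_nonuniformity": gln / n_r,
        "run_length_nonuniformity": rln / n_r,
        "run_percentage": n_r / n_p,
        "low_gray_level_run_emphasis": s["lglre"] / n_r,
        "high_gray_level_run_emphasis": s["hglre"] / n_r,
        "short_run_low_gray_level_emphasis": s["srlgle"] / n_r,
        "short_run_high_gray_level_emphasis": s["srhgle"] / n_r,
        "long_run_low_gray_level_emphasis": s["lrlgle"] / n_r,
        "long_run_high_gray_level_emphasis": s["lrhgle"] / n_r,
    }
    return out


def glrl_brute_mean(levels: np.ndarray, G: int) -> dict[str, float]:
    per = [glrl_brute(levels, G, d) for d in OFFSETS]
    return {k: float(np.mean([d[k] for d in per])) for k in per[0]}


def auc_all_pairs(scores, labels) -> float:
    """All positive-negative pairs, ties half a win."""
    scores = list(scores)
    labels = list(labels)
    wins = 0.0
    n_pos = n_neg = 0
    for sp, lp in zip(scores, labels):
        if lp != 1:
            continue
        n_pos += 1
        for sn, ln in zip(scores, labels):
            if ln != 0:
                continue
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    n_neg = labels.count(0)
    return wins / (n_pos * n_neg)


def knn_vote_brute(train_X, train_y, x, k) -> float:
    """Nearest-neighbor vote using an independent per-pair distance.

    Correlation distance per pair via explicit formula (or absolute
    difference for single-feature vectors), sorted with index tie-break.
    """
    dists = []
    for i, row in enumerate(train_X):
        if len(x) < 2:
            d = abs(float(x[0]) - float(row[0]))
        else:
            u = np.asarray(x, float) - np.mean(x)
            v = np.asarray(row, float) - np.mean(row)
            nu, nv = np.sqrt((u * u).sum()), np.sqrt((v * v).sum())
            d = 1.0 if nu == 0 or nv == 0 else 1.0 - float(u @ v) / (nu * nv)
        dists.append((d, i))
    dists.sort()
    return sum(train_y[i] for _, i in dists[:k]) / k
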