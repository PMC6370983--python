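"""The 38-feature texture/histogram panel computed from one ROI fragment.

Panel composition (canonical order, 1-based numbering used throughout the
outputs):

* 1-11   gray-level run-length statistics (Galloway and extensions),
* 12-25  Haralick co-occurrence statistics,
* 26-38  first-order histogram statistics.

Texture features are computed on a 128-level min-max quantization of the
fragment and averaged over the four axis directions 0, 90, 180 and 270
degrees. Histogram statistics use the raw (pre-quantization) intensities,
except Energy, which is the sum of squared bin probabilities of the
quantized histogram. All features are finite for every valid fragment;
degenerate (constant) fragments follow the documented conventions below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_preprocess import ROIFragment

__all__ = [
    "DEFAULT_GRAY_LEVELS",
    "FEATURE_NAMES",
    "N_FEATURES",
    "OFFSETS",
    "QuantizedROI",
    "CooccurrenceMatrix",
    "RunLengthMatrix",
    "FeatureVector",
    "quantize",
    "cooccurrence",
    "haralick_features",
    "run_length_matrix",
    "glrl_features",
    "histogram_features",
    "extract_features",
]

DEFAULT_GRAY_LEVELS = 128

#: direction offsets as (drow, dcol): 0, 90, 180, 270 degrees.
#: 0/180 and 90/270 give transposed co-occurrence matrices and identical
#: run-length matrices; all four are computed and averaged regardless.
OFFSETS = ((0, 1), (-1, 0), (0, -1), (1, 0))

GLRL_NAMES = (
    "short_run_emphasis",
    "long_run_emphasis",
    "gray_level_nonuniformity",
    "run_length_nonuniformity",
    "run_percentage",
    "low_gray_level_run_emphasis",
    "high_gray_level_run_emphasis",
    "short_run_low_gray_level_emphasis",
    "short_run_high_gray_level_emphasis",
    "long_run_low_gray_level_emphasis",
    "long_run_high_gray_level_emphasis",
)
HARALICK_NAMES = (
    "angular_second_moment",
    "contrast",
    "correlation",
    "glcm_variance",
    "inverse_difference_moment",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "info_measure_correlation_1",
    "info_measure_correlation_2",
    "maximal_correlation_coefficient",
)
HISTOGRAM_NAMES = (
    "hist_mean",
    "hist_variance",
    "hist_skewness",
    "hist_kurtosis",
    "hist_energy",
    "hist_min",
    "hist_max",
    "hist_median",
    "hist_p10",
    "hist_p20",
    "hist_p30",
    "hist_p40",
    "hist_p75",
)
FEATURE_NAMES: tuple[str, ...] = GLRL_NAMES + HARALICK_NAMES + HISTOGRAM_NAMES
N_FEATURES = len(FEATURE_NAMES)
assert N_FEATURES == 38


@dataclass(frozen=True)
class QuantizedROI:
    """Fragment re-expressed as integer gray levels in 1..G."""

    levels: np.ndarray
    G: int

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels)
        if lv.min() < 1 or lv.max() > self.G:
            raise ValueError("quantized levels must lie in [1, G]")
        object.__setattr__(self, "levels", lv.astype(np.int64))


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Normalized joint distribution p(i, j) of level pairs at one offset."""

    P: np.ndarray
    offset: tuple[int, int]

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if np.any(P < 0) or abs(P.sum() - 1.0) > 1e-12:
            raise ValueError("co-occurrence matrix must be a distribution")
        object.__setattr__(self, "P", P)


@dataclass(frozen=True)
class RunLengthMatrix:
    """R(i, j): count of maximal runs of level i with length j, one direction."""

    R: np.ndarray
    direction: tuple[int, int]
    n_pixels: int

    def __post_init__(self) -> None:
        R = np.asarray(self.R)
        if np.any(R < 0):
            raise ValueError("run counts must be non-negative")
        object.__setattr__(self, "R", R.astype(np.int64))


@dataclass(frozen=True)
class FeatureVector:
    """The ordered 38-value panel for one lesion."""

    values: np.ndarray
    patient_id: str = ""
    lesion_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_FEATURES,):
            raise ValueError(f"feature vector must have length {N_FEATURES}")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature values must be finite")
        object.__setattr__(self, "values", v)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values))


def quantize(roi: ROIFragment | np.ndarray,
             G: int = DEFAULT_GRAY_LEVELS) -> QuantizedROI:
    """Uniform min-max binning into G gray levels (1..G).

    v maps to floor(G*(v-min)/(max-min)) + 1 with max -> G; a constant
    fragment maps everywhere to level 1. Invariant to positive affine
    intensity maps, which is what makes the texture panel scanner-scale
    free.
    """
    if G < 2:
        raise ValueError("number of gray levels must be >= 2")
    px = roi.pixels if isinstance(roi, ROIFragment) else np.asarray(roi, float)
    lo, hi = px.min(), px.max()
    if hi == lo:
        return QuantizedROI(np.ones_like(px, dtype=np.int64), G)
    lv = np.floor(G * (px - lo) / (hi - lo)).astype(np.int64) + 1
    np.clip(lv, 1, G, out=lv)
    return QuantizedROI(lv, G)


# ---------------------------------------------------------------------------
# Co-occurrence (Haralick)

def cooccurrence(q: QuantizedROI, offset: tuple[int, int]) -> CooccurrenceMatrix:
    """Single-offset, non-symmetric, normalized gray-level co-occurrence.

    P(i, j) is the fraction of in-bounds ordered pixel pairs (a, a + offset)
    with level(a) = i and level(a + offset) = j.
    """
    if offset not in OFFSETS:
        raise ValueError(f"offset must be one of {OFFSETS}")
    dr, dc = offset
    lv = q.levels
    nr, nc = lv.shape
    if (dr != 0 and nr < 2) or (dc != 0 and nc < 2):
        raise ValueError("fragment too thin along the offset axis")
    # source and destination windows for the ordered pair (a, a+offset)
    src = lv[max(0, -dr):nr - max(0, dr), max(0, -dc):nc - max(0, dc)]
    dst = lv[max(0, dr):nr + min(0, dr), max(0, dc):nc + min(0, dc)]
    i = src.ravel() - 1
    j = dst.ravel() - 1
    P = np.zeros((q.G, q.G), dtype=float)
    np.add.at(P, (i, j), 1.0)
    P /= P.sum()
    return CooccurrenceMatrix(P, offset)


def _entropy(p: np.ndarray) -> float:
    """-sum p log p with the 0*log0 := 0 convention, natural log."""
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def _haralick_one(P: np.ndarray) -> np.ndarray:
    """The 14 Haralick statistics of one normalized G x G matrix."""
    G = P.shape[0]
    i = np.arange(1, G + 1, dtype=float)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mux = float(i @ px)
    muy = float(i @ py)
    sx = float(np.sqrt(((i - mux) ** 2) @ px))
    sy = float(np.sqrt(((i - muy) ** 2) @ py))

    ii = i[:, None]
    jj = i[None, :]
    # p_{x+y}(k), k = 2..2G and p_{|x-y|}(k), k = 0..G-1
    ks = np.arange(2, 2 * G + 1, dtype=float)
    kd = np.arange(0, G, dtype=float)
    psum = np.zeros(2 * G - 1)
    pdiff = np.zeros(G)
    sidx = (ii + jj - 2).astype(int)
    didx = np.abs(ii - jj).astype(int)
    np.add.at(psum, sidx.ravel(), P.ravel())
    np.add.at(pdiff, didx.ravel(), P.ravel())

    asm = float((P ** 2).sum())
    contrast = float((kd ** 2) @ pdiff)
    if sx > 0 and sy > 0:
        correlation = float(((ii * jj * P).sum() - mux * muy) / (sx * sy))
    else:
        correlation = 0.0
    variance = float((((ii - mux) ** 2) * P).sum())
    idm = float((P / (1.0 + (ii - jj) ** 2)).sum())
    sum_avg = float(ks @ psum)
    sum_var = float(((ks - sum_avg) ** 2) @ psum)
    sum_ent = _entropy(psum)
    ent = _entropy(P.ravel())
    diff_avg = float(kd @ pdiff)
    diff_var = float(((kd - diff_avg) ** 2) @ pdiff)
    diff_ent = _entropy(pdiff)

    # information measures of correlation
    hx = _entropy(px)
    hy = _entropy(py)
    pxpy = np.outer(px, py)
    mask = pxpy > 0
    hxy1 = float(-(P[mask] * np.log(pxpy[mask])).sum())
    hxy2 = float(-(pxpy[mask] * np.log(pxpy[mask])).sum())
    denom = max(hx, hy)
    imc1 = (ent - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - ent)))))

    mcc = _max_correlation_coefficient(P, px, py)
    return np.array([asm, contrast, correlation, variance, idm, sum_avg,
                     sum_var, sum_ent, ent, diff_var, diff_ent, imc1, imc2,
                     mcc])


def _max_correlation_coefficient(P: np.ndarray, px: np.ndarray,
                                 py: np.ndarray) -> float:
    """sqrt of the second-largest eigenvalue of Q(i,j) = sum_k p(i,k)p(j,k)/(px_i py_k).

    Zero-marginal rows/columns are dropped first; a single surviving level
    yields 0 by convention.
    """
    rows = px > 0
    cols = py > 0
    Pr = P[np.ix_(rows, cols)]
    if Pr.shape[0] < 2 or Pr.shape[1] < 1:
        return 0.0
    A = Pr / px[rows][:, None]
    B = Pr / py[cols][None, :]
    Q = A @ B.T
    ev = np.linalg.eigvals(Q)
    ev = np.sort(ev.real)[::-1]
    if len(ev) < 2:
        return 0.0
    return float(np.sqrt(max(0.0, ev[1])))


def haralick_features(q: QuantizedROI) -> np.ndarray:
    """The 14 Haralick statistics, each averaged over the four offsets."""
    per = [_haralick_one(cooccurrence(q, off).P) for off in OFFSETS]
    return np.mean(per, axis=0)


# ---------------------------------------------------------------------------
# Run lengths (Galloway)

def _runs_1d(line: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(levels, lengths) of the maximal runs in one scan line."""
    n = line.size
    if n == 0:
        return line, np.empty(0, dtype=np.int64)
    boundaries = np.flatnonzero(line[1:] != line[:-1]) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [n]))
    return line[starts], ends - starts


def run_length_matrix(q: QuantizedROI,
                      direction: tuple[int, int]) -> RunLengthMatrix:
    """Counts of maximal equal-level runs along one scan direction.

    Runs are undirected, so opposite directions (0 vs 180, 90 vs 270
    degrees) produce identical matrices; each is still computed so the
    four-direction average matches the stated protocol literally.
    """
    if direction not in OFFSETS:
        raise ValueError(f"direction must be one of {OFFSETS}")
    lv = q.levels
    lines = lv if direction[0] == 0 else lv.T
    if direction in ((0, -1), (1, 0)):
        lines = lines[:, ::-1]
    lmax = lines.shape[1]
    R = np.zeros((q.G, lmax), dtype=np.int64)
    for line in lines:
        levels, lengths = _runs_1d(line)
        np.add.at(R, (levels - 1, lengths - 1), 1)
    return RunLengthMatrix(R, direction, n_pixels=lv.size)


def _glrl_one(rl: RunLengthMatrix) -> np.ndarray:
    R = rl.R.astype(float)
    G, lmax = R.shape
    i2 = np.arange(1, G + 1, dtype=float)[:, None] ** 2
    j2 = np.arange(1, lmax + 1, dtype=float)[None, :] ** 2
    n_r = R.sum()
    n_p = rl.n_pixels
    sre = (R / j2).sum() / n_r
    lre = (R * j2).sum() / n_r
    gln = (R.sum(axis=1) ** 2).sum() / n_r
    rln = (R.sum(axis=0) ** 2).sum() / n_r
    rp = n_r / n_p
    lglre = (R / i2).sum() / n_r
    hglre = (R * i2).sum() / n_r
    srlgle = (R / (i2 * j2)).sum() / n_r
    srhgle = (R * i2 / j2).sum() / n_r
    lrlgle = (R * j2 / i2).sum() / n_r
    lrhgle = (R * i2 * j2).sum() / n_r
    return np.array([sre, lre, gln, rln, rp, lglre, hglre, srlgle, srhgle,
                     lrlgle, lrhgle])


def glrl_features(q: QuantizedROI) -> np.ndarray:
    """The 11 run-length statistics, averaged over the four directions."""
    per = [_glrl_one(run_length_matrix(q, d)) for d in OFFSETS]
    return np.mean(per, axis=0)


# ---------------------------------------------------------------------------
# Histogram

def histogram_features(roi: ROIFragment | np.ndarray,
                       q: QuantizedROI) -> np.ndarray:
    """The 13 first-order statistics.

    All on raw intensities with population (1/N) moments and
    linear-interpolation percentiles, except Energy = sum of squared bin
    probabilities of the G-level quantized histogram. A constant fragment
    has variance 0 and, by convention, skewness and kurtosis 0.
    """
    px = roi.pixels if isinstance(roi, ROIFragment) else np.asarray(roi, float)
    x = px.ravel()
    mean = float(x.mean())
    m2 = float(((x - mean) ** 2).mean())
    if m2 > 0:
        m3 = float(((x - mean) ** 3).mean())
        m4 = float(((x - mean) ** 4).mean())
        skew = m3 / m2 ** 1.5
        kurt = m4 / m2 ** 2
    else:
        skew = kurt = 0.0
    counts = np.bincount(q.levels.ravel(), minlength=q.G + 1)[1:]
    p = counts / counts.sum()
    energy = float((p ** 2).sum())
    pct = np.percentile(x, [10, 20, 30, 40, 75], method="linear")
    return np.array([mean, m2, skew, kurt, energy, float(x.min()),
                     float(x.max()), float(np.median(x)), *pct])


def extract_features(roi: ROIFragment,
                     G: int = DEFAULT_GRAY_LEVELS) -> FeatureVector:
    """Full 38-value panel in canonical order: run-length, Haralick, histogram."""
    q = quantize(roi, G)
    values = np.concatenate([glrl_features(q), haralick_features(q),
                             histogram_features(roi, q)])
    return FeatureVector(values, patient_id=roi.patient_id,
                         lesion_id=roi.lesion_id)
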