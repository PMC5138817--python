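"""Gray-level co-occurrence and run-length textures, and the feature catalog.

Matrix textures are computed on a quantized ROI (``Ng`` equal-width gray
levels over the in-mask intensity range). Matrices are accumulated per
slice and pooled by summing counts over all slices BEFORE normalization and
feature computation — this count-weighted pooling keeps features well
defined for thin ROIs.

Offsets ``(d_row, d_col)`` are in-plane voxel displacements; co-occurrence
matrices are symmetrized by also counting the reversed offset. Run-length
directions are the three in-plane directions RL1 = 0 deg (along columns),
RL2 = 45 deg (anti-diagonal) and RL3 = 90 deg (along rows); runs are maximal
same-level segments truncated at the mask boundary.

``extract_all`` assembles the full per-patient feature row: histogram,
co-occurrence and run-length features on the original ROI and on each
one-level wavelet sub-band (LL/LH/HL/HH), Gabor magnitude/phase statistics
on the LL band, and 3D shape descriptors. The enumeration of feature names
is given by :func:`catalog` and is stable for a fixed configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import ImageVolume, ROIMask
from .shape import histogram_stats, shape_features
from .transforms import default_orientations, gabor_bank, wavelet_decompose

__all__ = [
    "QuantizedROI",
    "CooccurrenceMatrix",
    "RunLengthMatrix",
    "ExtractionConfig",
    "quantize",
    "glcm",
    "glcm_features",
    "rlm",
    "rlm_features",
    "catalog",
    "extract_all",
]

logger = logging.getLogger(__name__)

GLCM_FEATURES = ("correlation", "contrast", "variance", "energy", "entropy")
RLM_FEATURES = ("SRE", "LRE", "LRLGE", "LRHGE", "energy")
HIST_FEATURES = ("mean", "variance", "skewness", "kurtosis", "energy", "entropy")
SHAPE_FEATURES = ("volume_mm3", "surface_area_mm2", "sphericity", "compactness")
GABOR_STATS = ("MTR_mean", "MTR_variance", "MTR_entropy", "PTR_entropy",
               "PTR_variance")

#: direction_index -> in-plane step (d_row, d_col)
RL_DIRECTIONS = {1: (0, 1), 2: (-1, 1), 3: (1, 0)}


@dataclass
class QuantizedROI:
    """Masked voxels mapped to discrete gray levels 1..Ng (0 outside mask)."""

    levels: np.ndarray  # int array, 0 = out of mask
    Ng: int
    binning: tuple  # (min, max, rule)

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels)
        in_mask = self.levels[self.levels > 0]
        if in_mask.size and (in_mask.min() < 1 or in_mask.max() > self.Ng):
            raise ValueError("in-mask levels must lie in 1..Ng")

    @property
    def mask(self) -> np.ndarray:
        return self.levels > 0


@dataclass
class CooccurrenceMatrix:
    """Symmetrized, normalized gray-level co-occurrence matrix."""

    offset: tuple[int, int]
    counts: np.ndarray  # (Ng, Ng) integer counts
    p: np.ndarray = field(init=False)
    p_x: np.ndarray = field(init=False)
    p_y: np.ndarray = field(init=False)
    mean_x: float = field(init=False)
    mean_y: float = field(init=False)
    std_x: float = field(init=False)
    std_y: float = field(init=False)

    def __post_init__(self) -> None:
        total = self.counts.sum()
        if total == 0:
            raise ValueError(
                f"no valid in-mask voxel pairs at offset {self.offset}"
            )
        self.p = self.counts / total
        ng = self.counts.shape[0]
        levels = np.arange(1, ng + 1, dtype=float)
        self.p_x = self.p.sum(axis=1)
        self.p_y = self.p.sum(axis=0)
        self.mean_x = float(levels @ self.p_x)
        self.mean_y = float(levels @ self.p_y)
        self.std_x = float(np.sqrt((levels - self.mean_x) ** 2 @ self.p_x))
        self.std_y = float(np.sqrt((levels - self.mean_y) ** 2 @ self.p_y))


@dataclass
class RunLengthMatrix:
    """Counts r(i, j) of maximal runs of level i and length j."""

    direction_index: int
    r: np.ndarray  # (Ng, max_len) integer counts

    @property
    def N_r(self) -> int:
        return int(self.r.sum())

    @property
    def max_len(self) -> int:
        return self.r.shape[1]


def quantize(values: np.ndarray, mask: np.ndarray, Ng: int = 32) -> QuantizedROI:
    """Equal-width quantization of in-mask intensities into levels 1..Ng.

    Bin edges span the in-mask [min, max]; the maximum maps to level Ng.
    A constant ROI maps every voxel to level 1. Invariant to positive affine
    rescaling of the intensities.
    """
    if Ng < 2:
        raise ValueError(f"Ng must be >= 2, got {Ng}")
    values = np.asarray(values, dtype=np.float64)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != values.shape:
        raise ValueError("values and mask shapes differ")
    if not mask.any():
        raise ValueError("mask is empty")
    vmin = values[mask].min()
    vmax = values[mask].max()
    levels = np.zeros(values.shape, dtype=np.int32)
    if vmax == vmin:
        levels[mask] = 1
    else:
        scaled = (values[mask] - vmin) / (vmax - vmin)
        levels[mask] = np.minimum((scaled * Ng).astype(np.int32) + 1, Ng)
    return QuantizedROI(levels, Ng, (float(vmin), float(vmax), "equal-width"))


def glcm(q: QuantizedROI, offset: tuple[int, int]) -> CooccurrenceMatrix:
    """Pooled in-plane co-occurrence matrix at ``offset = (d_row, d_col)``.

    Pairs with both endpoints in-mask are counted in every slice, symmetrized
    by adding the transposed counts, pooled over slices, then normalized.
    """
    dr, dc = int(offset[0]), int(offset[1])
    if dr == 0 and dc == 0:
        raise ValueError("offset must be nonzero")
    lv = q.levels
    if lv.ndim == 2:
        lv = lv[None]
    ng = q.Ng
    counts = np.zeros((ng, ng), dtype=np.int64)
    nrow, ncol = lv.shape[1], lv.shape[2]
    r0, r1 = max(0, -dr), min(nrow, nrow - dr)
    c0, c1 = max(0, -dc), min(ncol, ncol - dc)
    if r0 < r1 and c0 < c1:
        a = lv[:, r0:r1, c0:c1]
        b = lv[:, r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        valid = (a > 0) & (b > 0)
        if valid.any():
            pair = (a[valid].astype(np.int64) - 1) * ng + (b[valid] - 1)
            counts += np.bincount(pair, minlength=ng * ng).reshape(ng, ng)
    counts = counts + counts.T  # symmetrize: accumulate the reversed offset
    return CooccurrenceMatrix((dr, dc), counts)


def glcm_features(m: CooccurrenceMatrix) -> dict[str, float]:
    """Correlation, contrast, variance, energy and entropy of a GLCM.

    correlation = sum_ij (i - mu_x)(j - mu_y) p(i,j) / (sigma_x sigma_y);
    reported as NaN (flat-texture flag) when either marginal SD is zero.
    variance uses the grand mean level mu = (mu_x + mu_y)/2.
    """
    ng = m.p.shape[0]
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    j = np.arange(1, ng + 1, dtype=float)[None, :]
    p = m.p
    contrast = float(np.sum((i - j) ** 2 * p))
    mu = 0.5 * (m.mean_x + m.mean_y)
    variance = float(np.sum((i - mu) ** 2 * p))
    energy = float(np.sum(p**2))
    pz = p[p > 0]
    entropy = float(-np.sum(pz * np.log2(pz)))
    if m.std_x * m.std_y == 0:
        correlation = np.nan
    else:
        correlation = float(
            np.sum((i - m.mean_x) * (j - m.mean_y) * p) / (m.std_x * m.std_y)
        )
    return {
        "correlation": correlation,
        "contrast": contrast,
        "variance": variance,
        "energy": energy,
        "entropy": entropy,
    }


def _run_lengths(line: np.ndarray, ng: int, out: np.ndarray) -> None:
    """Accumulate maximal-run counts from a 1D level line (0 breaks runs)."""
    if line.size == 0:
        return
    change = np.flatnonzero(line[1:] != line[:-1])
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [line.size]))
    levels = line[starts]
    lengths = ends - starts
    keep = levels > 0
    for lvl, ln in zip(levels[keep], lengths[keep]):
        if ln > out.shape[1]:
            raise ValueError("run longer than matrix width")
        out[lvl - 1, ln - 1] += 1


def rlm(q: QuantizedROI, direction_index: int) -> RunLengthMatrix:
    """Pooled in-plane run-length matrix along RL1/RL2/RL3.

    Every in-mask voxel belongs to exactly one maximal run per direction, so
    sum_j j * r(i,j) equals the in-mask voxel count.
    """
    if direction_index not in RL_DIRECTIONS:
        raise ValueError(f"direction_index must be in {sorted(RL_DIRECTIONS)}")
    lv = q.levels
    if lv.ndim == 2:
        lv = lv[None]
    if not (lv > 0).any():
        raise ValueError("mask is empty")
    nrow, ncol = lv.shape[1], lv.shape[2]
    max_len = max(nrow, ncol)
    out = np.zeros((q.Ng, max_len), dtype=np.int64)
    brk = np.array([0], dtype=lv.dtype)
    for sl in lv:
        if direction_index == 1:  # 0 deg: along columns (horizontal lines)
            lines = [row for row in sl]
        elif direction_index == 3:  # 90 deg: along rows (vertical lines)
            lines = [col for col in sl.T]
        else:  # 45 deg: anti-diagonals (up-right)
            flipped = sl[::-1]
            lines = [
                np.diagonal(flipped, off) for off in range(-nrow + 1, ncol)
            ]
        joined = np.concatenate(
            [x for pair in ((ln, brk) for ln in lines) for x in pair]
        )
        _run_lengths(joined, q.Ng, out)
    return RunLengthMatrix(direction_index, out)


def rlm_features(m: RunLengthMatrix) -> dict[str, float]:
    """Galloway-style run emphasis statistics.

    SRE = (1/N_r) sum r/j^2; LRE = (1/N_r) sum j^2 r;
    LRLGE = (1/N_r) sum j^2 r / i^2; LRHGE = (1/N_r) sum i^2 j^2 r;
    energy = sum (r/N_r)^2.
    """
    nr = m.N_r
    if nr == 0:
        raise ValueError("run-length matrix has no runs")
    ng, ml = m.r.shape
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    j = np.arange(1, ml + 1, dtype=float)[None, :]
    r = m.r.astype(float)
    return {
        "SRE": float(np.sum(r / j**2) / nr),
        "LRE": float(np.sum(j**2 * r) / nr),
        "LRLGE": float(np.sum(j**2 * r / i**2) / nr),
        "LRHGE": float(np.sum(i**2 * j**2 * r) / nr),
        "energy": float(np.sum((r / nr) ** 2)),
    }


# ---------------------------------------------------------------------------
# Full-catalog extraction
# ---------------------------------------------------------------------------

@dataclass
class ExtractionConfig:
    """What :func:`extract_all` computes.

    The defaults enumerate the descriptor families on the original ROI and
    the four wavelet sub-bands, plus a 30-orientation Gabor bank on the LL
    band and four 3D shape descriptors.
    """

    n_levels: int = 32
    glcm_offsets: tuple = ((1, 1), (1, 2), (2, 1), (2, 2), (3, 2), (3, 3))
    rl_directions: tuple = (1, 2, 3)
    wavelet: str = "haar"
    gabor_frequencies: tuple = (0.15,)
    gabor_n_orientations: int = 30
    gabor_image: str = "LL"
    include_gabor: bool = True
    include_shape: bool = True
    hist_bins: int = 64

    @property
    def images(self) -> tuple[str, ...]:
        return ("orig", "LL", "LH", "HL", "HH")


def catalog(config: ExtractionConfig | None = None) -> list[str]:
    """The stable, documented enumeration of canonical feature names."""
    cfg = config or ExtractionConfig()
    names: list[str] = []
    for img in cfg.images:
        for f in HIST_FEATURES:
            names.append(f"hist_{f}_{img}")
        for (a, b) in cfg.glcm_offsets:
            for f in GLCM_FEATURES:
                names.append(f"CO_{f}_d{a}_a{b}_{img}")
        for d in cfg.rl_directions:
            for f in RLM_FEATURES:
                names.append(f"RL{d}_{f}_{img}")
    if cfg.include_gabor:
        for si in range(1, len(cfg.gabor_frequencies) + 1):
            for oi in range(cfg.gabor_n_orientations):
                for stat in GABOR_STATS:
                    names.append(
                        f"gabor_{stat}_s{si}_o{oi}_{cfg.gabor_image}"
                    )
    if cfg.include_shape:
        for f in SHAPE_FEATURES:
            names.append(f"shape_{f}")
    return names


def _bounding_box(mask: np.ndarray) -> tuple[slice, slice, slice]:
    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    return tuple(slice(a, b) for a, b in zip(lo, hi))  # type: ignore[return-value]


def _matrix_block(values, mask, img_name, cfg, row) -> None:
    """Histogram + GLCM + RLM features of one image into the row dict."""
    sample = values[mask] if mask is not None else values.ravel()
    hs = histogram_stats(sample, n_bins=cfg.hist_bins)
    for f in HIST_FEATURES:
        row[f"hist_{f}_{img_name}"] = hs[f]
    q = quantize(values, np.ones_like(values, bool) if mask is None else mask,
                 cfg.n_levels)
    for (a, b) in cfg.glcm_offsets:
        try:
            feats = glcm_features(glcm(q, (a, b)))
        except ValueError as exc:
            logger.warning("GLCM (%d,%d) on %s failed: %s", a, b, img_name, exc)
            feats = {f: np.nan for f in GLCM_FEATURES}
        for f in GLCM_FEATURES:
            row[f"CO_{f}_d{a}_a{b}_{img_name}"] = feats[f]
    for d in cfg.rl_directions:
        try:
            feats = rlm_features(rlm(q, d))
        except ValueError as exc:
            logger.warning("RLM %d on %s failed: %s", d, img_name, exc)
            feats = {f: np.nan for f in RLM_FEATURES}
        for f in RLM_FEATURES:
            row[f"RL{d}_{f}_{img_name}"] = feats[f]


def _entropy(values: np.ndarray, n_bins: int) -> float:
    if np.ptp(values) == 0:
        return 0.0
    counts, _ = np.histogram(values, bins=n_bins)
    p = counts[counts > 0] / values.size
    return float(-np.sum(p * np.log2(p)))


def extract_all(
    volume: ImageVolume,
    mask: ROIMask,
    config: ExtractionConfig | None = None,
) -> dict[str, float]:
    """Compute every catalog feature for one patient.

    The ROI bounding-box patch is the substrate: original-image features use
    only in-mask voxels; wavelet-band features use the full (half-size) band
    patch after out-of-mask voxels are replaced by the in-mask mean, which
    avoids artificial tumor/background edges dominating the detail bands.
    Matrix features pool per-slice matrices by summed counts, so they are
    invariant to slice-order permutations. Any sub-feature error is logged
    and recorded as NaN; the row is always emitted with the full catalog.
    """
    cfg = config or ExtractionConfig()
    mask.check_matches(volume)
    if mask.n_voxels == 0:
        raise ValueError("mask is empty")
    row: dict[str, float] = {}
    box = _bounding_box(mask.voxels)
    patch = volume.intensities[box]
    mpatch = mask.voxels[box]

    _matrix_block(patch, mpatch, "orig", cfg, row)

    filled = patch.copy()
    filled[~mpatch] = patch[mpatch].mean()
    if filled.shape[1] >= 2 and filled.shape[2] >= 2:
        bands = wavelet_decompose(filled, wavelet=cfg.wavelet).bands
        for name in ("LL", "LH", "HL", "HH"):
            _matrix_block(bands[name], None, name, cfg, row)
        if cfg.include_gabor:
            responses = gabor_bank(
                bands[cfg.gabor_image],
                frequencies=cfg.gabor_frequencies,
                orientations=default_orientations(cfg.gabor_n_orientations),
            )
            for resp in responses:
                mag = resp.magnitude.ravel()
                ph = resp.phase.ravel()
                pre = f"s{resp.scale_index}_o{resp.orientation_index}_{cfg.gabor_image}"
                row[f"gabor_MTR_mean_{pre}"] = float(mag.mean())
                row[f"gabor_MTR_variance_{pre}"] = float(mag.var())
                row[f"gabor_MTR_entropy_{pre}"] = _entropy(mag, cfg.hist_bins)
                row[f"gabor_PTR_entropy_{pre}"] = _entropy(ph, cfg.hist_bins)
                row[f"gabor_PTR_variance_{pre}"] = float(ph.var())
    else:
        logger.warning("ROI too small for wavelet bands; band features NaN")
        for name in catalog(cfg):
            if name not in row and not name.startswith("shape_"):
                row[name] = np.nan

    if cfg.include_shape:
        try:
            sf = shape_features(mask.voxels, mask.spacing)
        except ValueError as exc:
            logger.warning("shape features failed: %s", exc)
            sf = {f: np.nan for f in SHAPE_FEATURES}
        for f in SHAPE_FEATURES:
            row[f"shape_{f}"] = sf[f]

    # emit the complete catalog, missing entries as NaN
    return {name: row.get(name, np.nan) for name in catalog(cfg)}
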