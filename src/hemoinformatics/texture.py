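"""Gray-level texture features for hemodynamic images, in 2D and 3D.

Quantizes magnitude/direction images to integer gray levels and computes
first-order statistics plus co-occurrence (GLCM), run-length (GLRLM) and
size-zone (GLSZM) matrix features, following the standard IBSI-style
definitions.  Includes the two direction-sensitive emphases central to the
analysis:

* ``lalgle`` — large-area low-gray-level emphasis of a size-zone matrix.
  Two variants are computed: the conventional definition
  ``[sum_ij m_ij * j^2 / i^2] / Nz`` and a "printed" variant
  ``[sum_ij m_ij^2 / i^2] / Nz`` that squares the matrix entry and omits
  the zone-size weight.  On the DWSS image, low gray levels are
  upstream-pointing (reversed) WSS, so both emphasize recirculation.
* ``gln`` — gray-level non-uniformity ``[sum_i (sum_j m_ij)^2] / Nz`` of a
  run-length or size-zone matrix; on DVelocity it responds to how velocity
  directions concentrate on few sphere regions versus spread over many.

Higher-order variants apply a single-level stationary wavelet transform
(sub-bands tagged L/H per axis) or a Laplacian-of-Gaussian filter with
physical sigma before the first-order statistics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import ndimage

from .velocity_imaging import ScalarImage

__all__ = [
    "GrayLevelImage",
    "TextureMatrix",
    "FeatureConfig",
    "quantize",
    "glcm",
    "glrlm",
    "glszm",
    "first_order",
    "matrix_features",
    "lalgle",
    "gln",
    "wavelet_subbands",
    "log_filter",
    "extract_feature_vector",
]

_EPS = np.finfo(float).tiny


@dataclass
class GrayLevelImage:
    """Integer gray-level image; level 0 marks background (outside mask)."""

    array: np.ndarray  # int, levels 0..n_levels
    n_levels: int
    spacing: np.ndarray
    provenance: str = "original"

    def __post_init__(self):
        self.array = np.asarray(self.array, dtype=np.int64)
        self.spacing = np.atleast_1d(np.asarray(self.spacing, dtype=float))
        if self.n_levels < 1:
            raise ValueError("need at least one gray level")
        inside = self.array[self.array > 0]
        if inside.size and inside.max() > self.n_levels:
            raise ValueError("levels exceed n_levels")

    @property
    def mask(self) -> np.ndarray:
        return self.array > 0

    @property
    def ndim(self) -> int:
        return self.array.ndim


@dataclass
class TextureMatrix:
    """GLCM / GLRLM / GLSZM counts merged over directions.

    ``counts[i-1, j-1]`` indexes gray level i and (co-occurring level | run
    length | zone size) j.  ``n_entities`` is the total number of counted
    co-occurrences, runs or zones.
    """

    kind: str  # "glcm" | "glrlm" | "glszm"
    counts: np.ndarray
    n_levels: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n_entities(self) -> float:
        return float(self.counts.sum())

    def probabilities(self) -> np.ndarray:
        tot = self.counts.sum()
        return self.counts / tot if tot > 0 else self.counts


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------


def quantize(img: ScalarImage, n_bins: int = 32) -> GrayLevelImage:
    """Quantize a [0, 1] magnitude image into equal-width gray levels 1..n_bins.

    Interior bin edges are left-closed and the top bin is right-closed
    (value 1.0 falls in bin ``n_bins``).  Integer-label images (direction
    images) pass through unchanged with ``n_levels = max label``.
    """
    arr = np.asarray(img.array)
    mask = img.mask
    if np.issubdtype(arr.dtype, np.integer):
        out = np.where(mask, arr, 0)
        n_levels = int(out.max()) if out.max() > 0 else 1
        return GrayLevelImage(out, n_levels=n_levels, spacing=img.spacing, provenance="labels")
    vals = arr[mask]
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite masked values")
    levels = np.minimum(np.floor(arr * n_bins).astype(np.int64) + 1, n_bins)
    out = np.where(mask, levels, 0)
    return GrayLevelImage(out, n_levels=n_bins, spacing=img.spacing)


def _offsets(ndim: int) -> list[tuple[int, ...]]:
    """Unique direction offsets: 13 in 3D, 4 in 2D (half of the neighbourhood)."""
    offs = []
    for off in itertools.product((-1, 0, 1), repeat=ndim):
        if off == (0,) * ndim:
            continue
        if off > (0,) * ndim:  # lexicographic half-space
            offs.append(off)
    return offs


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------


def _shift_pairs(arr, mask, off):
    """Index slices pairing each voxel with its neighbour at offset `off`."""
    src = []
    dst = []
    for d, o in enumerate(off):
        n = arr.shape[d]
        if o == 0:
            src.append(slice(None))
            dst.append(slice(None))
        elif o > 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return tuple(src), tuple(dst)


def glcm(img: GrayLevelImage, distance: int = 1, symmetric: bool = True) -> TextureMatrix:
    """Gray-level co-occurrence matrix, merged (summed) over all directions.

    Counts voxel pairs at Chebyshev ``distance`` along each unique offset;
    pairs with either voxel outside the mask are skipped; symmetric
    accumulation doubles every pair (i,j) and (j,i).
    """
    ng = img.n_levels
    a = img.array
    counts = np.zeros((ng, ng), dtype=float)
    for off in _offsets(img.ndim):
        off_d = tuple(o * distance for o in off)
        src, dst = _shift_pairs(a, None, off_d)
        x = a[src].ravel()
        y = a[dst].ravel()
        ok = (x > 0) & (y > 0)
        if not ok.any():
            continue
        np.add.at(counts, (x[ok] - 1, y[ok] - 1), 1.0)
    if symmetric:
        counts = counts + counts.T
    return TextureMatrix("glcm", counts, ng, meta={"distance": distance, "symmetric": symmetric})


def _line_index_cache() -> dict:
    return {}


_LINE_CACHE: dict = {}


def _line_indices(shape: tuple, off: tuple) -> np.ndarray:
    """Flat indices of all maximal lattice lines along `off`, padded with -1.

    Rows are lines; the final column of every row is -1 so a flattened scan
    never merges runs across lines.
    """
    key = (shape, off)
    if key in _LINE_CACHE:
        return _LINE_CACHE[key]
    coords = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1)
    coords = coords.reshape(-1, len(shape))
    prev = coords - np.array(off)
    outside = np.zeros(len(coords), dtype=bool)
    for d, n in enumerate(shape):
        outside |= (prev[:, d] < 0) | (prev[:, d] >= n)
    starts = coords[outside]
    max_len = 0
    for d, o in enumerate(off):
        if o != 0:
            span = shape[d]
            max_len = max(max_len, span)
    max_len = max(max_len, 1)
    steps = np.arange(max_len)
    pos = starts[:, None, :] + steps[None, :, None] * np.array(off)[None, None, :]
    valid = np.ones(pos.shape[:2], dtype=bool)
    for d, n in enumerate(shape):
        valid &= (pos[..., d] >= 0) & (pos[..., d] < n)
    flat = np.zeros(pos.shape[:2], dtype=np.int64)
    stride = 1
    mult = np.ones(len(shape), dtype=np.int64)
    for d in range(len(shape) - 1, -1, -1):
        mult[d] = stride
        stride *= shape[d]
    flat = (np.clip(pos, 0, None) * mult).sum(axis=-1)
    flat[~valid] = -1
    # append a separator column
    sep = np.full((len(starts), 1), -1, dtype=np.int64)
    out = np.concatenate([flat, sep], axis=1)
    _LINE_CACHE[key] = out
    return out


def glrlm(img: GrayLevelImage) -> TextureMatrix:
    """Gray-level run-length matrix over all 13 (3D) / 4 (2D) directions.

    A run is a maximal streak of equal nonzero gray level along a lattice
    direction; background (mask) breaks runs.  Matrices are summed over
    directions.
    """
    ng = img.n_levels
    a = img.array.ravel()
    shape = img.array.shape
    max_run = max(shape)
    counts = np.zeros((ng, max_run), dtype=float)
    pad = np.concatenate([a, [-1]])  # index -1 reads the sentinel
    for off in _offsets(img.ndim):
        lines = _line_indices(shape, off)
        vals = pad[lines.ravel()]
        # run-length encode the concatenated lines (separators = -1)
        change = np.nonzero(np.diff(vals) != 0)[0]
        bounds = np.concatenate([[-1], change, [len(vals) - 1]])
        run_vals = vals[bounds[1:]]
        run_lens = np.diff(bounds)
        keep = run_vals > 0
        if keep.any():
            np.add.at(counts, (run_vals[keep] - 1, run_lens[keep] - 1), 1.0)
    # trim trailing all-zero run-length columns (keep at least one)
    last = max(int(np.nonzero(counts.sum(axis=0))[0].max()) + 1, 1) if counts.sum() else 1
    return TextureMatrix("glrlm", counts[:, :last], ng, meta={"n_voxels": int((img.array > 0).sum())})


def glszm(img: GrayLevelImage) -> TextureMatrix:
    """Gray-level size-zone matrix (26-connectivity in 3D, 8 in 2D)."""
    ng = img.n_levels
    a = img.array
    structure = np.ones((3,) * img.ndim, dtype=int)
    zones: list[tuple[int, int]] = []  # (level, size)
    max_size = 1
    for level in np.unique(a[a > 0]):
        lab, n_lab = ndimage.label(a == level, structure=structure)
        if n_lab == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            zones.append((int(level), int(s)))
            max_size = max(max_size, int(s))
    counts = np.zeros((ng, max_size), dtype=float)
    for level, s in zones:
        counts[level - 1, s - 1] += 1.0
    return TextureMatrix("glszm", counts, ng, meta={"n_voxels": int((a > 0).sum())})


# ---------------------------------------------------------------------------
# first-order features
# ---------------------------------------------------------------------------


def first_order(img: ScalarImage, n_bins: int = 32, prefix: str = "") -> dict:
    """First-order intensity statistics over the masked voxels.

    Kurtosis is the non-excess (Pearson) convention; entropy and uniformity
    are computed on an equal-width ``n_bins`` histogram of the masked
    values (entropy in bits).
    """
    v = np.asarray(img.masked_values(), dtype=float)
    if v.size == 0:
        raise ValueError("empty mask")
    mean = float(v.mean())
    var = float(v.var())
    std = np.sqrt(var)
    if std > 0:
        z = (v - mean) / std
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4))
    else:
        skew, kurt = 0.0, 0.0
    hist, _ = np.histogram(v, bins=n_bins)
    p = hist / hist.sum()
    p_nz = p[p > 0]
    out = {
        "Mean": mean,
        "Median": float(np.median(v)),
        "Maximum": float(v.max()),
        "Minimum": float(v.min()),
        "90Percentile": float(np.percentile(v, 90)),
        "Variance": var,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Entropy": float(-(p_nz * np.log2(p_nz)).sum()),
        "Uniformity": float((p**2).sum()),
    }
    return {prefix + k: val for k, val in out.items()}


# ---------------------------------------------------------------------------
# matrix features
# ---------------------------------------------------------------------------


def _glcm_features(m: TextureMatrix) -> dict:
    P = m.probabilities()
    ng = m.n_levels
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    joint_avg = float((ii * P).sum())

    # p(x+y): distribution of i + j, k = 2..2*ng
    k_sum = np.arange(2, 2 * ng + 1, dtype=float)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel() - 2, P.ravel())

    nz = P > 0
    joint_entropy = float(-(P[nz] * np.log2(P[nz])).sum())
    hx = -(px[px > 0] * np.log2(px[px > 0])).sum()
    hy = -(py[py > 0] * np.log2(py[py > 0])).sum()
    pxy = np.outer(px, py)
    both = (P > 0) | (pxy > 0)
    hxy2 = float(-(pxy[both] * np.log2(pxy[both] + _EPS)).sum())
    imc2_arg = 1.0 - np.exp(-2.0 * (hxy2 - joint_entropy))
    sigma_x = np.sqrt(((i - mu_x) ** 2 * px).sum())
    sigma_y = np.sqrt(((i - mu_y) ** 2 * py).sum())
    if sigma_x > 0 and sigma_y > 0:
        correlation = float(((ii * jj * P).sum() - mu_x * mu_y) / (sigma_x * sigma_y))
    else:
        correlation = 1.0
    p_sum_nz = p_sum[p_sum > 0]

    feats = {
        "Autocorrelation": float((ii * jj * P).sum()),
        "JointAverage": joint_avg,
        "SumAverage": float((k_sum * p_sum).sum()),
        "ClusterShade": float((((ii + jj) - mu_x - mu_y) ** 3 * P).sum()),
        "ClusterTendency": float((((ii + jj) - mu_x - mu_y) ** 2 * P).sum()),
        "ClusterProminence": float((((ii + jj) - mu_x - mu_y) ** 4 * P).sum()),
        "JointEnergy": float((P**2).sum()),
        "JointEntropy": joint_entropy,
        "MaximumProbability": float(P.max()),
        "SumEntropy": float(-(p_sum_nz * np.log2(p_sum_nz)).sum()),
        "Contrast": float(((ii - jj) ** 2 * P).sum()),
        "Correlation": correlation,
        "Imc2": float(np.sqrt(max(imc2_arg, 0.0))),
        "Idm": float((P / (1.0 + (ii - jj) ** 2)).sum()),
        "HighGrayLevelEmphasis": float((P * jj**2).sum()),
        "LowGrayLevelEmphasis": float((P / jj**2).sum()),
    }
    return feats


def _rlm_szm_features(m: TextureMatrix) -> dict:
    """Shared run-length / size-zone feature formulas (j = length or size)."""
    C = m.counts
    nz_total = C.sum()
    if nz_total == 0:
        raise ValueError("empty matrix")
    ng, nj = C.shape
    i = np.arange(1, ng + 1, dtype=float)
    j = np.arange(1, nj + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    P = C / nz_total
    ci = C.sum(axis=1)
    cj = C.sum(axis=0)
    mu_i = float((ii * P).sum())
    mu_j = float((jj * P).sum())
    p_nz = P[P > 0]

    long_tag = "LongRun" if m.kind == "glrlm" else "LargeArea"
    short_tag = "ShortRun" if m.kind == "glrlm" else "SmallArea"
    run_or_zone_var = "RunVariance" if m.kind == "glrlm" else "ZoneVariance"
    entropy_tag = "RunEntropy" if m.kind == "glrlm" else "ZoneEntropy"
    gl_emph = "Run" if m.kind == "glrlm" else "Zone"

    feats = {
        "GrayLevelNonUniformity": float((ci**2).sum() / nz_total),
        "GrayLevelNonUniformityNormalized": float((ci**2).sum() / nz_total**2),
        f"{'RunLength' if m.kind == 'glrlm' else 'SizeZone'}NonUniformity": float(
            (cj**2).sum() / nz_total
        ),
        f"HighGrayLevel{gl_emph}Emphasis": float((P * ii**2).sum()),
        f"LowGrayLevel{gl_emph}Emphasis": float((P / ii**2).sum()),
        f"{long_tag}Emphasis": float((P * jj**2).sum()),
        f"{short_tag}Emphasis": float((P / jj**2).sum()),
        f"{long_tag}HighGrayLevelEmphasis": float((P * ii**2 * jj**2).sum()),
        f"{long_tag}LowGrayLevelEmphasis": float((P * jj**2 / ii**2).sum()),
        f"{short_tag}HighGrayLevelEmphasis": float((P * ii**2 / jj**2).sum()),
        f"{short_tag}LowGrayLevelEmphasis": float((P / (ii**2 * jj**2)).sum()),
        "GrayLevelVariance": float((P * (ii - mu_i) ** 2).sum()),
        run_or_zone_var: float((P * (jj - mu_j) ** 2).sum()),
        entropy_tag: float(-(p_nz * np.log2(p_nz)).sum()),
    }
    return feats


def matrix_features(m: TextureMatrix, prefix: str = "") -> dict:
    """Named features for a texture matrix per standard definitions."""
    if m.kind == "glcm":
        feats = _glcm_features(m)
    elif m.kind in ("glrlm", "glszm"):
        feats = _rlm_szm_features(m)
    else:
        raise ValueError(f"unknown matrix kind {m.kind!r}")
    return {f"{prefix}{m.kind}.{k}": v for k, v in feats.items()}


def lalgle(m: TextureMatrix, variant: str = "standard") -> float:
    """Large-area low-gray-level emphasis of a size-zone matrix.

    ``standard``: ``[sum_ij m_ij * j^2 / i^2] / Nz`` (conventional).
    ``printed``: ``[sum_ij m_ij^2 / i^2] / Nz`` — squares the raw count and
    drops the zone-size weight.
    """
    if m.kind != "glszm":
        raise ValueError("lalgle is defined on size-zone matrices")
    nz = m.n_entities
    if nz == 0:
        raise ValueError("empty matrix (Nz == 0)")
    C = m.counts
    i = np.arange(1, C.shape[0] + 1, dtype=float)[:, None]
    j = np.arange(1, C.shape[1] + 1, dtype=float)[None, :]
    if variant == "printed":
        return float((C**2 / i**2).sum() / nz)
    if variant == "standard":
        return float((C * j**2 / i**2).sum() / nz)
    raise ValueError(f"unknown variant {variant!r}")


def gln(m: TextureMatrix) -> float:
    """Gray-level non-uniformity ``[sum_i (sum_j m_ij)^2] / Nz``."""
    if m.kind not in ("glrlm", "glszm"):
        raise ValueError("gln is defined on run-length or size-zone matrices")
    nz = m.n_entities
    if nz == 0:
        raise ValueError("empty matrix (Nz == 0)")
    ci = m.counts.sum(axis=1)
    return float((ci**2).sum() / nz)


# ---------------------------------------------------------------------------
# higher-order filters
# ---------------------------------------------------------------------------


def wavelet_subbands(img: ScalarImage, wavelet: str = "coif1") -> dict[str, ScalarImage]:
    """Single-level stationary (undecimated) wavelet decomposition.

    Returns 8 sub-bands in 3D (LLL..HHH) or 4 in 2D (LL..HH); the tag
    letter at position k is the filter (L=low-pass, H=high-pass) applied
    along array axis k.  Sub-bands keep the original shape and mask.
    """
    arr = np.zeros(img.mask.shape, dtype=float)
    arr[img.mask] = np.asarray(img.array, dtype=float)[img.mask]
    wav = pywt.Wavelet(wavelet)
    if min(arr.shape) < len(wav.dec_lo):
        raise ValueError("image smaller than the wavelet filter support")
    # swtn needs even dimensions: pad with edge values, crop after
    pads = [(0, (-n) % 2) for n in arr.shape]
    padded = np.pad(arr, pads, mode="edge")
    coeffs = pywt.swtn(padded, wav, level=1, norm=False)[0]
    out = {}
    crop = tuple(slice(0, n) for n in arr.shape)
    for key, band in coeffs.items():
        tag = key.upper().replace("A", "L").replace("D", "H")
        out[tag] = ScalarImage(
            array=band[crop], spacing=img.spacing, origin=img.origin, mask=img.mask.copy()
        )
    return out


def log_filter(img: ScalarImage, sigma_mm: float) -> ScalarImage:
    """Laplacian-of-Gaussian with a physical sigma (converted per-axis)."""
    if sigma_mm <= 0:
        raise ValueError("sigma must be positive")
    arr = np.zeros(img.mask.shape, dtype=float)
    arr[img.mask] = np.asarray(img.array, dtype=float)[img.mask]
    sig_vox = sigma_mm / img.spacing
    filtered = ndimage.gaussian_laplace(arr, sigma=sig_vox, mode="mirror")
    return ScalarImage(array=filtered, spacing=img.spacing, origin=img.origin, mask=img.mask.copy())


# ---------------------------------------------------------------------------
# feature battery
# ---------------------------------------------------------------------------


@dataclass
class FeatureConfig:
    """Which feature families and filtered variants to compute."""

    n_bins: int = 32
    first_order: bool = True
    glcm: bool = True
    glrlm: bool = True
    glszm: bool = True
    wavelet: bool = True
    wavelet_name: str = "coif1"
    log_sigmas_mm: tuple = (1.0,)
    filter_direction_images: bool = False  # labels are categorical by default
    direction_rebin: int | None = None  # optionally coarsen direction levels


def _matrix_battery(gray: GrayLevelImage, cfg: FeatureConfig, prefix: str) -> dict:
    feats = {}
    if cfg.glcm:
        feats.update(matrix_features(glcm(gray), prefix))
    if cfg.glrlm:
        m = glrlm(gray)
        feats.update(matrix_features(m, prefix))
        feats[f"{prefix}glrlm.GLN.printed"] = gln(m)
    if cfg.glszm:
        m = glszm(gray)
        feats.update(matrix_features(m, prefix))
        feats[f"{prefix}glszm.GLN.printed"] = gln(m)
        feats[f"{prefix}glszm.LALGLE.standard"] = lalgle(m, "standard")
        feats[f"{prefix}glszm.LALGLE.printed"] = lalgle(m, "printed")
    return feats


def _rebin_labels(img: ScalarImage, n_coarse: int) -> ScalarImage:
    arr = np.asarray(img.array, dtype=np.int64)
    n = int(arr.max())
    coarse = np.where(arr > 0, ((arr - 1) * n_coarse) // max(n, 1) + 1, 0)
    return ScalarImage(array=coarse, spacing=img.spacing, origin=img.origin, mask=img.mask)


def extract_feature_vector(images: dict, config: FeatureConfig | None = None) -> dict:
    """Full feature battery for a magnitude/direction image pair.

    ``images`` maps image names (e.g. ``MVelocity``, ``DVelocity``) to
    ScalarImages.  Magnitude images (float-valued) get first-order + matrix
    features on the original and on each wavelet/LoG derivative; direction
    images (integer labels) get matrix features on the original only,
    unless ``filter_direction_images`` is set (labels then treated as
    ordinal integers).  Output order is deterministic.
    """
    cfg = config or FeatureConfig()
    feats: dict = {}
    for name in sorted(images):
        img = images[name]
        is_direction = np.issubdtype(np.asarray(img.array).dtype, np.integer)
        prefix = f"{name}."
        if is_direction:
            work = _rebin_labels(img, cfg.direction_rebin) if cfg.direction_rebin else img
            gray = quantize(work, cfg.n_bins)
            feats.update(_matrix_battery(gray, cfg, prefix))
            if cfg.first_order:
                feats.update(first_order(work, cfg.n_bins, prefix))
            if cfg.filter_direction_images:
                as_float = ScalarImage(
                    array=np.asarray(work.array, dtype=float),
                    spacing=work.spacing,
                    origin=work.origin,
                    mask=work.mask,
                )
                feats.update(_filtered_battery(as_float, cfg, prefix))
        else:
            gray = quantize(img, cfg.n_bins)
            if cfg.first_order:
                feats.update(first_order(img, cfg.n_bins, prefix))
            feats.update(_matrix_battery(gray, cfg, prefix))
            feats.update(_filtered_battery(img, cfg, prefix))
    bad = {k for k, v in feats.items() if not np.isfinite(v)}
    if bad:
        raise ValueError(f"non-finite features: {sorted(bad)[:10]}")
    return feats


def _filtered_battery(img: ScalarImage, cfg: FeatureConfig, prefix: str) -> dict:
    feats: dict = {}
    if cfg.wavelet:
        for tag, band in sorted(wavelet_subbands(img, cfg.wavelet_name).items()):
            feats.update(first_order(band, cfg.n_bins, f"{prefix}wavelet.{tag}."))
    for s in cfg.log_sigmas_mm or ():
        tagged = f"{prefix}log.sigma.{s:g}.mm."
        feats.update(first_order(log_filter(img, s), cfg.n_bins, tagged))
    return feats
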