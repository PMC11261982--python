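"""Density estimation and landmark (peak/valley) detection per marker x batch.

The unit of work is one marker in one batch: arcsinh-transformed values are
smoothed with a Gaussian kernel on a shared grid, local maxima become peaks,
minima between adjacent peaks become valleys, and a sequence of cleanup rules
removes discreteness artifacts near zero and flags cross-batch outliers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .core_data import RunConfig, ValidationError

MAD_CONSTANT = 1.4826  # consistency constant for the median-based scaled MAD


# --------------------------------------------------------------------------
# transform & density
# --------------------------------------------------------------------------

def arcsinh_transform(counts, cofactor: float = 5.0) -> np.ndarray:
    """``asinh(x / cofactor)``: strictly increasing, maps 0 to 0."""
    x = np.asarray(counts, dtype=float)
    if not np.isfinite(x).all():
        raise ValidationError("non-finite values in counts")
    if cofactor <= 0:
        raise ValidationError("cofactor must be positive")
    return np.arcsinh(x / cofactor)


@dataclass
class DensityCurve:
    """Kernel density estimate on a fixed grid (arcsinh scale)."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth_used: float
    n_cells: int

    @property
    def t_start(self) -> float:
        return float(self.grid[0])

    @property
    def t_end(self) -> float:
        return float(self.grid[-1])

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def make_grid(t_start: float, t_end: float, grid_size: int) -> np.ndarray:
    if t_end <= t_start:
        t_end = t_start + 1.0
    return np.linspace(t_start, t_end, grid_size)


def estimate_density(values, bandwidth: float, grid) -> DensityCurve:
    """Gaussian-kernel density of ``values`` evaluated on ``grid``.

    The result is renormalized to integrate to 1 over the grid (kernel mass
    falling outside — mainly below 0 for near-zero background peaks — is
    folded back by rescaling).
    """
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if values.size < 2:
        raise ValidationError("need at least 2 values for density estimation")
    if bandwidth <= 0:
        raise ValidationError("bandwidth must be positive")
    # chunk over cells to bound memory for large batches
    dens = np.zeros_like(grid)
    norm = 1.0 / (values.size * bandwidth * np.sqrt(2.0 * np.pi))
    for start in range(0, values.size, 4096):
        chunk = values[start:start + 4096]
        z = (grid[:, None] - chunk[None, :]) / bandwidth
        dens += np.exp(-0.5 * z * z).sum(axis=1)
    dens *= norm
    total = np.trapezoid(dens, grid)
    if total > 0:
        dens = dens / total
    return DensityCurve(grid, dens, float(bandwidth), int(values.size))


# --------------------------------------------------------------------------
# landmarks
# --------------------------------------------------------------------------

@dataclass
class Landmark:
    location: float
    height: float
    provenance: str = "detected"  # detected|merged|imputed|slope-derived|prior-override
    outlier: bool = False


@dataclass
class LandmarkSet:
    """Ordered, interleaved peaks and valleys for one (marker, batch)."""

    peaks: list[Landmark] = field(default_factory=list)
    valleys: list[Landmark] = field(default_factory=list)
    positive_only: bool = False

    def validate(self) -> None:
        locs = [p.location for p in self.peaks]
        if any(b <= a for a, b in zip(locs, locs[1:])):
            raise ValidationError("peak locations must be strictly increasing")
        vlocs = [v.location for v in self.valleys]
        if any(b <= a for a, b in zip(vlocs, vlocs[1:])):
            raise ValidationError("valley locations must be strictly increasing")
        # interleaving: between adjacent peaks exactly one valley
        if len(self.peaks) >= 2:
            for (a, b) in zip(locs, locs[1:]):
                inside = [v for v in vlocs if a < v < b]
                if len(inside) != 1:
                    raise ValidationError(
                        f"interleaving violated between peaks {a:.3f} and {b:.3f}"
                    )

    @property
    def n_landmarks(self) -> int:
        return len(self.peaks) + len(self.valleys)


def detect_peaks(curve: DensityCurve, min_height_frac: float = 0.01) -> list[Landmark]:
    """Grid-local maxima with height >= min_height_frac * max(density).

    Plateaus of equal maximal values yield one peak at the plateau's
    leftmost grid point; boundary modes count.
    """
    if not 0 < min_height_frac < 1:
        raise ValidationError("min_height_frac must be in (0, 1)")
    d = curve.density
    g = curve.grid
    n = d.size
    floor = min_height_frac * d.max()
    peaks: list[Landmark] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and d[j + 1] == d[i]:
            j += 1
        left_ok = i == 0 or d[i - 1] < d[i]
        right_ok = j == n - 1 or d[j + 1] < d[i]
        if left_ok and right_ok and d[i] >= floor and d[i] > 0:
            peaks.append(Landmark(float(g[i]), float(d[i])))
        i = j + 1
    return peaks


def _slope_valley(curve: DensityCurve, peak_loc: float, slope_frac: float,
                  direction: int = +1) -> Landmark | None:
    """Valley where |slope| drops below ``slope_frac`` of the steepest
    descent on the chosen side of the peak."""
    g, d = curve.grid, curve.density
    slope = np.gradient(d, g)
    pi = int(np.argmin(np.abs(g - peak_loc)))
    if direction > 0:
        seg = slope[pi:]
        if seg.size < 2:
            return None
        k = int(np.argmin(seg))  # steepest descent
        steepest = -seg[k]
        if steepest <= 0:
            return None
        rel = np.nonzero(np.abs(seg[k:]) < slope_frac * steepest)[0]
        idx = pi + k + (int(rel[0]) if rel.size else seg.size - 1 - k)
    else:
        seg = slope[:pi + 1]
        if seg.size < 2:
            return None
        k = int(np.argmax(seg))  # steepest ascent (left flank)
        steepest = seg[k]
        if steepest <= 0:
            return None
        rel = np.nonzero(np.abs(seg[:k + 1][::-1]) < slope_frac * steepest)[0]
        idx = k - (int(rel[0]) if rel.size else k)
    return Landmark(float(g[idx]), float(d[idx]), provenance="slope-derived")


def detect_valleys(curve: DensityCurve, peaks: list[Landmark],
                   slope_frac: float = 0.1) -> list[Landmark]:
    """Minimum-density grid point strictly between adjacent peaks.

    Ties resolve to the midpoint grid index of the minimal plateau.  With a
    single peak the valley is slope-derived on the right flank.
    """
    if not peaks:
        raise ValidationError("need at least one peak")
    g, d = curve.grid, curve.density
    if len(peaks) == 1:
        v = _slope_valley(curve, peaks[0].location, slope_frac, direction=+1)
        return [v] if v is not None else []
    valleys: list[Landmark] = []
    for a, b in zip(peaks, peaks[1:]):
        ia = int(np.argmin(np.abs(g - a.location)))
        ib = int(np.argmin(np.abs(g - b.location)))
        inner = slice(ia + 1, ib)
        seg = d[inner]
        lo = seg.min()
        tied = np.nonzero(seg == lo)[0]
        idx = ia + 1 + int(tied[len(tied) // 2])
        valleys.append(Landmark(float(g[idx]), float(d[idx])))
    return valleys


def select_bandwidth(values, ladder, grid, peak_count_prior: int | None = None,
                     min_height_frac: float = 0.01):
    """Walk a decreasing bandwidth ladder until enough peaks resolve.

    Returns the first (widest) rung whose curve yields >= 2 peaks — or, when
    ``peak_count_prior`` k is given, >= k peaks — falling back to the
    narrowest rung.
    """
    ladder = tuple(ladder)
    if not ladder:
        raise ValidationError("bandwidth ladder is empty")
    want = peak_count_prior if peak_count_prior is not None else 2
    best = None
    for bw in ladder:
        curve = estimate_density(values, bw, grid)
        n_peaks = len(detect_peaks(curve, min_height_frac))
        best = (bw, curve, n_peaks)
        if n_peaks >= want:
            return best
    return best


# --------------------------------------------------------------------------
# cleanup rules
# --------------------------------------------------------------------------

def _reinterleave(peaks: list[Landmark], valleys: list[Landmark]) -> list[Landmark]:
    """Keep, for each adjacent peak pair, the lowest valley strictly between."""
    kept: list[Landmark] = []
    for a, b in zip(peaks, peaks[1:]):
        inside = [v for v in valleys if a.location < v.location < b.location]
        if not inside:
            raise ValidationError(
                f"no valley available between peaks at {a.location:.3f} and "
                f"{b.location:.3f}"
            )
        kept.append(min(inside, key=lambda v: v.height))
    return kept


def merge_low_peaks(landmarks: LandmarkSet, neg_candidate_thres: float) -> LandmarkSet:
    """Collapse all peaks below ``neg_candidate_thres`` into a single negative
    peak at the tallest one's location; intervening valleys are removed."""
    below = [p for p in landmarks.peaks if p.location < neg_candidate_thres]
    if len(below) <= 1:
        return landmarks
    keep = max(below, key=lambda p: p.height)
    keep = replace(keep, provenance="merged")
    peaks = [keep] + [p for p in landmarks.peaks if p.location >= neg_candidate_thres]
    peaks.sort(key=lambda p: p.location)
    valleys = _reinterleave(peaks, landmarks.valleys) if len(peaks) >= 2 else []
    out = LandmarkSet(peaks, valleys, landmarks.positive_only)
    out.validate()
    return out


def drop_spurious_zero_peak(landmarks: LandmarkSet, curve: DensityCurve,
                            neg_candidate_thres: float,
                            minor_peak_frac: float = 1.0 / 3.0) -> LandmarkSet:
    """Drop a minor leftmost peak sitting below ``neg_candidate_thres`` in
    front of the true negative peak (empty-droplet artifact).  The sole peak
    is never deleted and neither is a leftmost peak that is not minor."""
    peaks = landmarks.peaks
    if len(peaks) < 2:
        return landmarks
    first, second = peaks[0], peaks[1]
    if first.location >= neg_candidate_thres:
        return landmarks
    if first.height >= minor_peak_frac * second.height:
        return landmarks
    new_peaks = peaks[1:]
    valleys = (_reinterleave(new_peaks, landmarks.valleys)
               if len(new_peaks) >= 2 else [])
    out = LandmarkSet(new_peaks, valleys, landmarks.positive_only)
    out.validate()
    return out


def apply_positive_peak_prior(landmarks: LandmarkSet, is_positive_only: bool,
                              curve: DensityCurve | None = None,
                              slope_frac: float = 0.1) -> LandmarkSet:
    """Mark the sole peak of a positive-only batch as positive and place its
    slope-derived valley on the *left* flank (mirrored criterion)."""
    if not is_positive_only:
        return landmarks
    if len(landmarks.peaks) >= 2:
        warnings.warn(
            "positive_peak_only set but >=2 peaks detected; "
            "treating the rightmost as positive"
        )
        return replace(landmarks, positive_only=False)
    if not landmarks.peaks:
        return landmarks
    peak = replace(landmarks.peaks[0], provenance="prior-override")
    valleys: list[Landmark] = []
    if curve is not None:
        v = _slope_valley(curve, peak.location, slope_frac, direction=-1)
        if v is not None and v.location < peak.location:
            valleys = [v]
    out = LandmarkSet([peak], valleys, positive_only=True)
    return out


def clean_landmarks(curve: DensityCurve, landmarks: LandmarkSet,
                    config: RunConfig, positive_only: bool = False) -> LandmarkSet:
    """Full per-(marker, batch) cleanup: spurious-zero drop, near-zero merge,
    slope-valley recovery, and the positive-only prior."""
    lm = drop_spurious_zero_peak(
        landmarks, curve, config.neg_candidate_thres, config.minor_peak_frac)
    lm = merge_low_peaks(lm, config.neg_candidate_thres)
    if len(lm.peaks) == 1 and not lm.valleys and not positive_only:
        v = _slope_valley(curve, lm.peaks[0].location, config.slope_valley_frac)
        if v is not None:
            lm = LandmarkSet(lm.peaks, [v], lm.positive_only)
    lm = apply_positive_peak_prior(lm, positive_only, curve, config.slope_valley_frac)
    lm.validate()
    return lm


def detect_landmarks(values, config: RunConfig, grid,
                     positive_only: bool = False,
                     peak_count_prior: int | None = None):
    """Bandwidth search + peak/valley detection + cleanup for one batch.

    Returns ``(curve, LandmarkSet)``.
    """
    bw, curve, _ = select_bandwidth(
        values, config.bandwidth_ladder, grid, peak_count_prior,
        config.min_height_frac)
    peaks = detect_peaks(curve, config.min_height_frac)
    if not peaks:  # pathological flat density; fall back to global max
        i = int(np.argmax(curve.density))
        peaks = [Landmark(float(curve.grid[i]), float(curve.density[i]))]
    valleys = detect_valleys(curve, peaks, config.slope_valley_frac)
    lm = LandmarkSet(peaks, valleys)
    return curve, clean_landmarks(curve, lm, config, positive_only)


# --------------------------------------------------------------------------
# cross-batch outlier handling
# --------------------------------------------------------------------------

def scaled_mad_flags(values, mad_multiplier: float) -> np.ndarray:
    """Boolean flags: |x - median| / (1.4826 * MAD) > multiplier.

    Fewer than 3 finite values -> no flags (insufficient support).  A zero
    MAD flags any value different from the median.
    """
    v = np.asarray(values, dtype=float)
    flags = np.zeros(v.shape, dtype=bool)
    ok = np.isfinite(v)
    if ok.sum() < 3:
        return flags
    med = np.median(v[ok])
    mad = MAD_CONSTANT * np.median(np.abs(v[ok] - med))
    dev = np.abs(v - med)
    if mad == 0:
        flags[ok] = dev[ok] > 0
    else:
        with np.errstate(over="ignore", divide="ignore"):
            flags[ok] = dev[ok] / mad > mad_multiplier
    return flags


def flag_outlier_positive_peaks(locations, mad_multiplier: float = 3.0) -> np.ndarray:
    """MAD-flag per-batch rightmost (positive) peak locations for one marker.

    Flagged peaks are excluded from target computation and warp pinning.
    """
    return scaled_mad_flags(locations, mad_multiplier)


def compute_emd_matrix(curves: dict[str, DensityCurve]) -> "EMDMatrix":
    """Pairwise 1-D earth mover's distance between batch densities of one
    marker: the integral of |CDF_a - CDF_b| over the shared grid."""
    names = list(curves)
    grids = [curves[n].grid for n in names]
    for g in grids[1:]:
        if g.shape != grids[0].shape or not np.allclose(g, grids[0]):
            raise ValidationError("EMD requires curves on a shared grid")
    grid = grids[0]
    cdfs = {}
    for n in names:
        d = curves[n].density
        cdf = np.concatenate([[0.0], np.cumsum(np.diff(grid) * (d[:-1] + d[1:]) / 2.0)])
        if cdf[-1] > 0:
            cdf = cdf / cdf[-1]
        cdfs[n] = cdf
    k = len(names)
    mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            mat[i, j] = mat[j, i] = float(
                np.trapezoid(np.abs(cdfs[names[i]] - cdfs[names[j]]), grid))
    return EMDMatrix(names, mat)


@dataclass
class EMDMatrix:
    batches: list[str]
    distances: np.ndarray

    def neighbors(self, batch: str, exclude: set[str] = frozenset()) -> list[str]:
        i = self.batches.index(batch)
        order = np.argsort(self.distances[i], kind="stable")
        return [self.batches[j] for j in order
                if self.batches[j] != batch and self.batches[j] not in exclude]


def impute_outlier_valleys(valley_locs: np.ndarray, emd: EMDMatrix,
                           mad_multiplier: float = 3.0,
                           k_neighbors: int = 2,
                           min_deviation: float = 0.0):
    """Replace MAD-flagged valleys with the mean over the k nearest
    (EMD) non-flagged batches.

    ``valley_locs`` is (n_batches, n_valley_slots) with NaN for absent
    valleys; rows are ordered as ``emd.batches``.  Returns the imputed
    matrix and a boolean mask of imputed entries.
    """
    locs = np.array(valley_locs, dtype=float, copy=True)
    imputed = np.zeros(locs.shape, dtype=bool)
    n_batches, n_slots = locs.shape
    if n_batches < 3:
        return locs, imputed
    for s in range(n_slots):
        flags = scaled_mad_flags(locs[:, s], mad_multiplier)
        if min_deviation > 0 and flags.any():
            med = np.nanmedian(np.where(np.isfinite(locs[:, s]), locs[:, s], np.nan))
            flags &= np.abs(locs[:, s] - med) > min_deviation
        if not flags.any():
            continue
        flagged_batches = {emd.batches[i] for i in np.nonzero(flags)[0]}
        for i in np.nonzero(flags)[0]:
            neigh = [b for b in emd.neighbors(emd.batches[i], exclude=flagged_batches)
                     if np.isfinite(locs[emd.batches.index(b), s])]
            if not neigh:
                warnings.warn(
                    f"no clean neighbor to impute valley slot {s} for batch "
                    f"{emd.batches[i]!r}; keeping detected location")
                continue
            take = neigh[:k_neighbors]
            locs[i, s] = float(np.mean(
                [valley_locs[emd.batches.index(b), s] for b in take]))
            imputed[i, s] = True
    return locs, imputed
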