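"""Cross-batch landmark alignment via monotone warping functions.

Per marker: landmark sets are harmonized into canonical slots
(neg_peak, valley_1, pos_peak_1, valley_2, pos_peak_2, ...), targets are the
per-slot means over clean batches, and each batch gets a strictly monotone
warp h with fixed endpoints pinning h(target_j) = detected_j.  Cell values
are moved by the inverse warp, so each batch's landmarks land on the shared
targets while within-batch rank order is untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .core_data import ADTDataset, RunConfig, ValidationError
from .landmark_detection import (
    DensityCurve,
    LandmarkSet,
    arcsinh_transform,
    compute_emd_matrix,
    detect_landmarks,
    flag_outlier_positive_peaks,
    impute_outlier_valleys,
    make_grid,
)

_ENDPOINT_EPS = 1e-9


def slot_names(n_slots: int) -> list[str]:
    names = ["neg_peak"]
    k = 1
    while len(names) < n_slots:
        names += [f"valley_{k}", f"pos_peak_{k}"]
        k += 1
    return names[:n_slots]


def harmonize_landmark_counts(landmark_sets: dict[str, LandmarkSet]):
    """Assign each batch's landmarks to canonical slots, NA where absent.

    With P = max peak count, slots alternate peak/valley (2P - 1 total).
    The leftmost peak fills the negative slot, the rightmost peak always
    fills the rightmost positive slot when a batch has >= 2 peaks, interior
    peaks fill positive slots left-to-right, and each valley lands in the
    slot immediately preceding the peak on its right.  Positive-only batches
    map their sole peak to pos_peak_1.

    Returns ``(locations, heights, slot_names)`` where the first two are
    (n_batches, n_slots) arrays ordered by dict insertion.
    """
    batches = list(landmark_sets)
    if not batches:
        raise ValidationError("no batches to harmonize")
    max_p = max(len(lm.peaks) for lm in landmark_sets.values())
    if max_p < 1:
        raise ValidationError("every batch needs at least one peak")
    n_slots = 2 * max_p - 1
    if max_p == 1 and any(lm.valleys for lm in landmark_sets.values()):
        n_slots = 2  # m = 2: one peak plus its slope-derived valley
    if any(lm.positive_only for lm in landmark_sets.values()):
        n_slots = max(n_slots, 3)  # need a pos slot even if all others unimodal
    locs = np.full((len(batches), n_slots), np.nan)
    hts = np.full((len(batches), n_slots), np.nan)

    for bi, b in enumerate(batches):
        lm = landmark_sets[b]
        p = len(lm.peaks)
        if p == 0:
            continue
        if lm.positive_only and p == 1:
            peak_slots = [2]  # pos_peak_1
        elif p == 1:
            peak_slots = [0]
        else:
            peak_slots = [0] + [2 * k for k in range(1, p - 1)] + [n_slots - 1]
        for peak, s in zip(lm.peaks, peak_slots):
            locs[bi, s] = peak.location
            hts[bi, s] = peak.height
        # valley i sits immediately left of the slot of the peak on its right
        if lm.positive_only and p == 1:
            if lm.valleys:
                locs[bi, 1] = lm.valleys[0].location
                hts[bi, 1] = lm.valleys[0].height
        elif p == 1:
            if lm.valleys:  # slope-derived, right of the sole (negative) peak
                locs[bi, 1] = lm.valleys[0].location
                hts[bi, 1] = lm.valleys[0].height
        else:
            for i, v in enumerate(lm.valleys):
                right_peak_slot = peak_slots[i + 1]
                locs[bi, right_peak_slot - 1] = v.location
                hts[bi, right_peak_slot - 1] = v.height
    return locs, hts, slot_names(n_slots)


@dataclass
class TargetLandmarks:
    """Per-marker target locations, one per canonical slot."""

    locations: np.ndarray
    slots: list[str]
    source: str = "mean-of-batches"  # or "user-specified"

    def __post_init__(self) -> None:
        t = np.asarray(self.locations, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValidationError(
                f"target landmarks must be strictly increasing, got {t}")
        self.locations = t


def compute_targets(locations: np.ndarray, outlier_mask: np.ndarray | None,
                    slots: list[str],
                    user_targets=None) -> TargetLandmarks:
    """Per-slot mean over non-NA, non-outlier batch values; or the user's
    vector verbatim after monotonicity validation."""
    if user_targets is not None:
        t = np.asarray(user_targets, dtype=float)
        if t.size != len(slots):
            raise ValidationError(
                f"user targets have {t.size} entries, expected {len(slots)}")
        return TargetLandmarks(t, slots, source="user-specified")
    locs = np.asarray(locations, dtype=float)
    mask = np.zeros(locs.shape, bool) if outlier_mask is None else outlier_mask
    out = np.full(len(slots), np.nan)
    for s in range(len(slots)):
        clean = locs[~mask[:, s], s]
        clean = clean[np.isfinite(clean)]
        if clean.size == 0:
            fallback = locs[np.isfinite(locs[:, s]), s]
            if fallback.size == 0:
                raise ValidationError(f"no batch provides landmark slot {slots[s]!r}")
            warnings.warn(f"all values for slot {slots[s]!r} flagged; using all")
            clean = fallback
        out[s] = clean.mean()
    return TargetLandmarks(out, slots)


# --------------------------------------------------------------------------
# warping
# --------------------------------------------------------------------------

class WarpFunction:
    """Strictly monotone map with fixed endpoints, pinned at landmark knots.

    ``h`` maps target locations to the batch's detected locations
    (h(t0_j) = t_ij); normalization therefore applies ``h^{-1}`` to cell
    values.  The interpolant is a shape-preserving monotone cubic (PCHIP),
    inverted by vectorized bisection.
    """

    def __init__(self, knots_x, knots_y, t_start: float, t_end: float,
                 lambda_penalty: float = 1e-6):
        x = np.asarray(knots_x, dtype=float)
        y = np.asarray(knots_y, dtype=float)
        keep = ((x > t_start + _ENDPOINT_EPS) & (x < t_end - _ENDPOINT_EPS)
                & (y > t_start + _ENDPOINT_EPS) & (y < t_end - _ENDPOINT_EPS))
        x, y = x[keep], y[keep]
        if np.any(np.diff(x) <= 0) or np.any(np.diff(y) <= 0):
            raise ValidationError(
                "landmark ordering violated: knots must be strictly increasing "
                f"(x={x}, y={y})")
        self.t_start = float(t_start)
        self.t_end = float(t_end)
        self.lambda_penalty = float(lambda_penalty)
        self.knots_x = np.concatenate([[t_start], x, [t_end]])
        self.knots_y = np.concatenate([[t_start], y, [t_end]])
        if self.knots_x.size == 2:
            self._h = lambda t: np.asarray(t, dtype=float)
            self._identity = True
        else:
            # curvature penalty: large lambda pulls the shape-preserving
            # cubic toward the zero-curvature (piecewise-linear) interpolant
            cubic = PchipInterpolator(self.knots_x, self.knots_y)
            w = self.lambda_penalty / (1.0 + self.lambda_penalty)
            kx, ky = self.knots_x, self.knots_y

            def _h(t, _cubic=cubic, _w=w):
                lin = np.interp(t, kx, ky)
                return (1.0 - _w) * np.asarray(_cubic(t), dtype=float) + _w * lin

            self._h = _h
            self._identity = False

    def __call__(self, t):
        t = np.clip(np.asarray(t, dtype=float), self.t_start, self.t_end)
        out = np.asarray(self._h(t), dtype=float)
        # endpoints are exact fixed points
        out = np.where(t == self.t_start, self.t_start, out)
        out = np.where(t == self.t_end, self.t_end, out)
        return out

    def inverse(self, y):
        y = np.clip(np.asarray(y, dtype=float), self.t_start, self.t_end)
        if self._identity:
            return y.copy()
        scalar = y.ndim == 0
        y = np.atleast_1d(y)
        lo = np.full_like(y, self.t_start)
        hi = np.full_like(y, self.t_end)
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            below = self._h(mid) < y
            lo = np.where(below, mid, lo)
            hi = np.where(below, hi, mid)
        out = 0.5 * (lo + hi)
        out = np.where(y == self.t_start, self.t_start, out)
        out = np.where(y == self.t_end, self.t_end, out)
        return out[0] if scalar else out


def fit_warp(batch_landmarks, targets, t_start: float, t_end: float,
             lambda_penalty: float = 1e-6) -> WarpFunction:
    """Fit the monotone warp through ((t0_j, t_ij)) plus fixed endpoints.

    NaN slots are skipped; outlier-flagged landmarks should be removed by the
    caller before fitting.
    """
    t_i = np.asarray(batch_landmarks, dtype=float)
    t0 = np.asarray(targets, dtype=float)
    if t_i.shape != t0.shape:
        raise ValidationError("landmark/target length mismatch")
    ok = np.isfinite(t_i) & np.isfinite(t0)
    return WarpFunction(t0[ok], t_i[ok], t_start, t_end, lambda_penalty)


def normalize_values(values, warp: WarpFunction) -> np.ndarray:
    """Move one batch's arcsinh values onto the target axis via h^{-1}."""
    return warp.inverse(values)


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

@dataclass
class MarkerResult:
    marker: str
    grid: np.ndarray
    curves: dict[str, DensityCurve]
    landmarks: dict[str, LandmarkSet]
    slot_locations: np.ndarray
    slot_names: list[str]
    outlier_mask: np.ndarray
    targets: TargetLandmarks
    warps: dict[str, WarpFunction]

    def valley_location(self, index: int = 1) -> float:
        name = f"valley_{index}"
        if name not in self.slot_names:
            raise ValidationError(f"marker {self.marker!r} has no {name}")
        return float(self.targets.locations[self.slot_names.index(name)])


@dataclass
class NormalizationResult:
    normalized: pd.DataFrame          # cells x markers, arcsinh target scale
    markers: dict[str, MarkerResult]
    landmarks_pre: pd.DataFrame
    landmarks_post: pd.DataFrame
    config: RunConfig
    failures: dict[str, str] = field(default_factory=dict)

    def target_table(self) -> pd.DataFrame:
        rows = []
        for m, res in self.markers.items():
            for s, loc in zip(res.slot_names, res.targets.locations):
                rows.append({"marker": m, "slot": s, "location": loc,
                             "source": res.targets.source})
        return pd.DataFrame(rows)

    def warp_knot_table(self) -> pd.DataFrame:
        rows = []
        for m, res in self.markers.items():
            for b, w in res.warps.items():
                for x, y in zip(w.knots_x, w.knots_y):
                    rows.append({"marker": m, "batch": b, "target": x,
                                 "detected": y})
        return pd.DataFrame(rows)


class NormalizationError(RuntimeError):
    def __init__(self, failures: dict[str, str], partial: NormalizationResult):
        super().__init__(
            "normalization failed for markers: "
            + "; ".join(f"{m}: {e}" for m, e in failures.items()))
        self.failures = failures
        self.partial_result = partial


def _landmark_rows(marker, batch, lm: LandmarkSet, slots=None):
    rows = []
    n_p = len(lm.peaks)
    for i, p in enumerate(lm.peaks):
        if lm.positive_only and n_p == 1:
            ltype = "pos_peak"
        elif i == 0:
            ltype = "neg_peak"
        else:
            ltype = "pos_peak"
        rows.append({"marker": marker, "batch": batch, "landmark_type": ltype,
                     "index": i, "location": p.location, "height": p.height,
                     "provenance": p.provenance, "outlier_flag": p.outlier})
    for i, v in enumerate(lm.valleys):
        rows.append({"marker": marker, "batch": batch, "landmark_type": "valley",
                     "index": i, "location": v.location, "height": v.height,
                     "provenance": v.provenance, "outlier_flag": v.outlier})
    return rows


def normalize_marker(values_by_batch: dict[str, np.ndarray], config: RunConfig,
                     marker: str,
                     user_targets=None) -> MarkerResult:
    """Run detect -> clean -> harmonize -> targets -> warp for one marker.

    ``values_by_batch`` holds arcsinh-transformed values per batch.
    """
    vmax = max(float(np.max(v)) for v in values_by_batch.values())
    grid = make_grid(0.0, vmax + 3.0 * config.bandwidth_ladder[0], config.grid_size)
    t_start, t_end = float(grid[0]), float(grid[-1])

    curves: dict[str, DensityCurve] = {}
    lms: dict[str, LandmarkSet] = {}
    prior = config.peak_count_prior.get(marker)
    for b, vals in values_by_batch.items():
        pos_only = (b, marker) in config.positive_peak_only
        curve, lm = detect_landmarks(vals, config, grid, pos_only, prior)
        curves[b] = curve
        lms[b] = lm

    locs, hts, slots = harmonize_landmark_counts(lms)
    batches = list(lms)
    n_slots = len(slots)

    # MAD-flag rightmost positive peaks across batches
    outlier = np.zeros((len(batches), n_slots), dtype=bool)
    if n_slots >= 3:
        right = locs[:, n_slots - 1]
        flags = flag_outlier_positive_peaks(right, config.mad_multiplier)
        if config.mad_min_deviation > 0 and flags.any():
            # guard: never flag peaks within an absolute jitter band of the
            # median, however tight the MAD (re-runs on aligned data)
            med = np.nanmedian(right)
            flags &= np.abs(right - med) > config.mad_min_deviation
        outlier[:, n_slots - 1] = flags
        for bi, f in enumerate(flags):
            if f and lms[batches[bi]].peaks:
                lms[batches[bi]].peaks[-1].outlier = True

    # impute outlier valleys from EMD-nearest batches
    valley_cols = [i for i, s in enumerate(slots) if s.startswith("valley")]
    if valley_cols and len(batches) >= 3:
        emd = compute_emd_matrix(curves)
        sub = locs[:, valley_cols]
        imputed, mask = impute_outlier_valleys(
            sub, emd, config.mad_multiplier, config.k_neighbors,
            config.mad_min_deviation)
        locs[:, valley_cols] = imputed
        for bi, ci in zip(*np.nonzero(mask)):
            lm = lms[batches[bi]]
            v_idx = valley_cols.index(valley_cols[ci])
            if v_idx < len(lm.valleys):
                lm.valleys[v_idx].location = imputed[bi, ci]
                lm.valleys[v_idx].provenance = "imputed"

    targets = compute_targets(locs, outlier, slots, user_targets)

    warps: dict[str, WarpFunction] = {}
    for bi, b in enumerate(batches):
        ok = np.isfinite(locs[bi]) & ~outlier[bi]
        warps[b] = fit_warp(locs[bi][ok], targets.locations[ok],
                            t_start, t_end, config.lambda_penalty)
    return MarkerResult(marker, grid, curves, lms, locs, slots, outlier,
                        targets, warps)


def run_normalization(ds: ADTDataset, config: RunConfig | None = None,
                      landmark_override: pd.DataFrame | None = None,
                      redetect: bool = True) -> NormalizationResult:
    """Normalize every marker independently across batches.

    Markers absent in a batch (per availability) are skipped for that batch
    and their cells receive NA.  Per-marker failures are aggregated and
    raised at the end rather than fail-fast.
    """
    if config is None:
        config = RunConfig()
    if ds.batch_of_cell is None:
        raise ValidationError("attach batch labels before normalizing")
    batches = ds.batches
    norm = np.full(ds.counts.shape, np.nan)
    marker_results: dict[str, MarkerResult] = {}
    failures: dict[str, str] = {}
    pre_rows: list[dict] = []
    post_rows: list[dict] = []

    for j, marker in enumerate(ds.marker_names):
        try:
            vals_by_batch = {}
            masks = {}
            for b in batches:
                if not ds.marker_available(marker, b):
                    continue
                mask = ds.batch_mask(b)
                masks[b] = mask
                vals_by_batch[b] = arcsinh_transform(
                    ds.counts[mask, j], config.arcsinh_cofactor)
            if not vals_by_batch:
                raise ValidationError("marker absent in every batch")
            user_t = config.target_landmark_location.get(marker)
            res = normalize_marker(vals_by_batch, config, marker, user_t)
            if landmark_override is not None:
                res = _apply_override(res, landmark_override, marker, config)
            for b in vals_by_batch:
                norm[masks[b], j] = normalize_values(
                    vals_by_batch[b], res.warps[b])
            marker_results[marker] = res
            for b, lm in res.landmarks.items():
                pre_rows += _landmark_rows(marker, b, lm)
            if redetect:
                for b in vals_by_batch:
                    _, lm_post = detect_landmarks(
                        norm[masks[b], j], config, res.grid,
                        (b, marker) in config.positive_peak_only,
                        config.peak_count_prior.get(marker))
                    post_rows += _landmark_rows(marker, b, lm_post)
        except Exception as exc:  # aggregate, report at end
            failures[marker] = str(exc)

    result = NormalizationResult(
        normalized=pd.DataFrame(norm, index=ds.cell_ids, columns=ds.marker_names),
        markers=marker_results,
        landmarks_pre=pd.DataFrame(pre_rows),
        landmarks_post=pd.DataFrame(post_rows),
        config=config,
        failures=failures,
    )
    if failures:
        raise NormalizationError(failures, result)
    return result


def _apply_override(res: MarkerResult, override: pd.DataFrame, marker: str,
                    config: RunConfig) -> MarkerResult:
    """Replace detected landmark locations with user-edited table rows and
    refit targets and warps."""
    sub = override[override["marker"] == marker]
    if sub.empty:
        return res
    batches = list(res.landmarks)
    locs = res.slot_locations.copy()
    for _, row in sub.iterrows():
        b = str(row["batch"])
        if b not in batches:
            continue
        bi = batches.index(b)
        ltype, idx = str(row["landmark_type"]), int(row["index"])
        if ltype == "neg_peak":
            slot = 0
        elif ltype == "valley":
            slot = 1 + 2 * idx
        else:
            slot = 2 + 2 * idx
        if slot < locs.shape[1]:
            locs[bi, slot] = float(row["location"])
    targets = compute_targets(locs, res.outlier_mask, res.slot_names)
    t_start, t_end = float(res.grid[0]), float(res.grid[-1])
    warps = {}
    for bi, b in enumerate(batches):
        ok = np.isfinite(locs[bi]) & ~res.outlier_mask[bi]
        warps[b] = fit_warp(locs[bi][ok], targets.locations[ok],
                            t_start, t_end, config.lambda_penalty)
    return MarkerResult(res.marker, res.grid, res.curves, res.landmarks,
                        locs, res.slot_names, res.outlier_mask, targets, warps)
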