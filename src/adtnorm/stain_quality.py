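"""Stain index and stain quality scoring from density landmarks.

The score family extends the classical flow-cytometry stain index to ADT
densities with one, two, or three-plus peaks.  All quantities are computed
from the kernel density curve and the cells backing it; peak membership is
delimited by the flanking valleys.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import ADTDataset, RunConfig, ValidationError
from .landmark_detection import (
    DensityCurve,
    LandmarkSet,
    arcsinh_transform,
    detect_landmarks,
    make_grid,
)


@dataclass
class PeakSummary:
    """Per-peak and per-valley quantities feeding the score formulas."""

    peak_modes: np.ndarray       # mode location per peak, ascending
    peak_heights: np.ndarray     # density height at each mode
    peak_sds: np.ndarray         # SD of cells within each peak interval
    peak_aucs: np.ndarray        # trapezoid AUC over each peak interval
    valley_locs: np.ndarray
    valley_heights: np.ndarray
    right_tail_auc: float        # AUC beyond the last valley
    sd_all: float                # SD of all cells (1-peak case)

    @property
    def n_peaks(self) -> int:
        return int(self.peak_modes.size)


def summarize_peaks(curve: DensityCurve, landmarks: LandmarkSet,
                    values) -> PeakSummary:
    """Compute peak/valley summary statistics for one (marker, batch).

    Peak intervals are delimited by the flanking valleys (or the grid
    endpoints); a cell belongs to peak i when its value lies in
    [valley_{i-1}, valley_i), with the peak-side boundary closed on the
    positive side.
    """
    landmarks.validate()
    values = np.asarray(values, dtype=float)
    g, d = curve.grid, curve.density
    vlocs = np.array([v.location for v in landmarks.valleys], dtype=float)
    vhts = np.array([v.height for v in landmarks.valleys], dtype=float)
    pmodes = np.array([p.location for p in landmarks.peaks], dtype=float)
    phts = np.array([p.height for p in landmarks.peaks], dtype=float)

    # cut points on the value axis: valleys between/through the peaks
    cuts = np.concatenate([[-np.inf], vlocs, [np.inf]])
    sds, aucs = [], []
    for i, mode in enumerate(pmodes):
        # a single peak with a right-flank slope valley owns [T_start, valley)
        relevant = cuts[(cuts < mode) | (cuts == -np.inf)]
        lb = relevant.max() if relevant.size else -np.inf
        rb_candidates = cuts[cuts > mode]
        rb = rb_candidates.min() if rb_candidates.size else np.inf
        if landmarks.positive_only and len(pmodes) == 1 and vlocs.size:
            lb, rb = vlocs[0], np.inf
        member = (values >= lb) & (values < rb)
        if not member.any():
            warnings.warn(f"empty peak interval around mode {mode:.3f}")
            sds.append(0.0)
            aucs.append(0.0)
            continue
        sds.append(float(np.std(values[member])))
        glb = max(lb, g[0])
        grb = min(rb, g[-1])
        sel = (g >= glb) & (g <= grb)
        aucs.append(float(np.trapezoid(d[sel], g[sel])) if sel.sum() >= 2 else 0.0)

    if vlocs.size and not (landmarks.positive_only and len(pmodes) == 1):
        sel = g >= vlocs[-1]
        right_tail = float(np.trapezoid(d[sel], g[sel])) if sel.sum() >= 2 else 0.0
    else:
        right_tail = 0.0

    return PeakSummary(
        peak_modes=pmodes, peak_heights=phts,
        peak_sds=np.array(sds), peak_aucs=np.array(aucs),
        valley_locs=vlocs, valley_heights=vhts,
        right_tail_auc=right_tail,
        sd_all=float(np.std(values)),
    )


def stain_index(summary: PeakSummary) -> float:
    """(PosPeakMode - NegPeakMode) / (2 * SD(NegPeak))."""
    if summary.n_peaks < 2:
        raise ValidationError("stain index needs at least 2 peaks")
    sd_neg = summary.peak_sds[0]
    if sd_neg == 0:
        raise ValidationError("degenerate negative peak (SD = 0)")
    return float((summary.peak_modes[-1] - summary.peak_modes[0]) / (2.0 * sd_neg))


def stain_quality_score(summary: PeakSummary, n_peaks: int | None = None) -> float:
    """Three-case separation-to-spread score.

    2 peaks:   [(PosMode - NegMode) / (SD(Neg) + SD(Pos))]
               * (PosHeight - ValleyHeight + 1) * (AUC(Pos) + 1)
    >=3 peaks: [(RightmostMode - NegMode) / sum SD(peak)]
               * (RightmostHeight - RightmostValleyHeight + 1)
               * (AUC(non-neg peaks) + 1)
    1 peak:    [(Valley - PeakMode) / SD(all cells)]
               * (0 - ValleyHeight + 1) * (AUC(RightTail) + 1)
    """
    if n_peaks is None:
        n_peaks = summary.n_peaks
    if n_peaks != summary.n_peaks:
        raise ValidationError("n_peaks inconsistent with summary")
    if n_peaks >= 3:
        denom = float(summary.peak_sds.sum())
        if denom == 0:
            raise ValidationError("zero total SD")
        sep = summary.peak_modes[-1] - summary.peak_modes[0]
        sharp = summary.peak_heights[-1] - summary.valley_heights[-1] + 1.0
        auc = float(summary.peak_aucs[1:].sum()) + 1.0
        return float(sep / denom * sharp * auc)
    if n_peaks == 2:
        denom = float(summary.peak_sds[0] + summary.peak_sds[1])
        if denom == 0:
            raise ValidationError("zero total SD")
        sep = summary.peak_modes[1] - summary.peak_modes[0]
        sharp = summary.peak_heights[1] - summary.valley_heights[-1] + 1.0
        auc = summary.peak_aucs[1] + 1.0
        return float(sep / denom * sharp * auc)
    # single peak: valley distance bounds the (missing) positive separation
    if summary.sd_all == 0:
        raise ValidationError("zero SD of data")
    if summary.valley_locs.size == 0:
        raise ValidationError("1-peak score needs a slope-derived valley")
    sep = summary.valley_locs[-1] - summary.peak_modes[0]
    sharp = 0.0 - summary.valley_heights[-1] + 1.0
    auc = summary.right_tail_auc + 1.0
    return float(sep / summary.sd_all * sharp * auc)


def quality_report(ds: ADTDataset, config: RunConfig | None = None,
                   threshold: float | None = None) -> pd.DataFrame:
    """Score every (marker, batch): long table with n_peaks, score,
    stain_index and a low-quality flag (score < threshold, default 5)."""
    if config is None:
        config = RunConfig()
    if threshold is None:
        threshold = config.quality_threshold
    if ds.batch_of_cell is None:
        raise ValidationError("attach batch labels first")
    rows = []
    for j, marker in enumerate(ds.marker_names):
        vmax = float(np.max(arcsinh_transform(ds.counts[:, j],
                                              config.arcsinh_cofactor)))
        grid = make_grid(0.0, vmax + 3.0 * config.bandwidth_ladder[0],
                         config.grid_size)
        for b in ds.batches:
            if not ds.marker_available(marker, b):
                continue
            vals = arcsinh_transform(ds.counts[ds.batch_mask(b), j],
                                     config.arcsinh_cofactor)
            curve, lm = detect_landmarks(
                vals, config, grid,
                (b, marker) in config.positive_peak_only,
                config.peak_count_prior.get(marker))
            summary = summarize_peaks(curve, lm, vals)
            try:
                score = stain_quality_score(summary)
            except ValidationError:
                score = np.nan
            try:
                si = stain_index(summary)
            except ValidationError:
                si = np.nan
            rows.append({"marker": marker, "batch": b,
                         "n_peaks": summary.n_peaks,
                         "score": score, "stain_index": si,
                         "flagged": bool(score < threshold)
                         if np.isfinite(score) else True})
    report = pd.DataFrame(rows)
    means = (report.groupby("marker", sort=False)["score"]
             .mean().rename("marker_mean_score"))
    return report.merge(means, on="marker")
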