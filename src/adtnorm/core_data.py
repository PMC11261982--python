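"""Data model, count-matrix I/O and run configuration.

Conventions
-----------
Cells are rows and markers are columns everywhere.  Matrix Market input in
the common features x barcodes orientation is transposed on read.  Missing
(marker, batch) combinations are encoded as NA in outputs, never 0, because
0 is a valid count.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.io import mmread


class ValidationError(ValueError):
    """Raised when input data violates the data-model contract."""


# --------------------------------------------------------------------------
# dataset
# --------------------------------------------------------------------------

@dataclass
class ADTDataset:
    """A cells x markers non-negative integer count matrix with batch labels.

    Parameters
    ----------
    counts
        ``(n_cells, n_markers)`` array of non-negative counts.
    cell_ids
        Unique cell identifiers, one per row.
    marker_names
        Unique marker names, one per column.
    batch_of_cell
        Batch label per cell, or ``None`` until :func:`attach_batches`.
    availability
        Optional boolean frame (index = markers, columns = batches).  A
        marker absent in a batch contributes no cells to that marker's
        normalization and receives no warp for that batch.  ``None`` means
        every marker is present in every batch.
    """

    counts: np.ndarray
    cell_ids: list[str]
    marker_names: list[str]
    batch_of_cell: np.ndarray | None = None
    availability: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        c = self.counts
        if c.ndim != 2:
            raise ValidationError(f"counts must be 2-D, got shape {c.shape}")
        if c.shape[0] != len(self.cell_ids):
            raise ValidationError("cell_ids length does not match counts rows")
        if c.shape[1] != len(self.marker_names):
            raise ValidationError("marker_names length does not match counts columns")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell ids")
        if len(set(self.marker_names)) != len(self.marker_names):
            raise ValidationError("duplicate marker names")
        if c.size:
            if not np.issubdtype(c.dtype, np.number):
                raise ValidationError("counts must be numeric")
            if np.isnan(np.asarray(c, dtype=float)).any():
                i, j = np.argwhere(np.isnan(np.asarray(c, dtype=float)))[0]
                raise ValidationError(
                    f"missing entry for cell {self.cell_ids[i]!r}, marker "
                    f"{self.marker_names[j]!r}"
                )
            if (c < 0).any():
                i, j = np.argwhere(c < 0)[0]
                raise ValidationError(
                    f"negative count for cell {self.cell_ids[i]!r}, marker "
                    f"{self.marker_names[j]!r}"
                )
        if self.batch_of_cell is not None:
            self.batch_of_cell = np.asarray(self.batch_of_cell, dtype=object)
            if len(self.batch_of_cell) != c.shape[0]:
                raise ValidationError("batch_of_cell length mismatch")

    # -- convenience --------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_markers(self) -> int:
        return self.counts.shape[1]

    @property
    def batches(self) -> list[str]:
        if self.batch_of_cell is None:
            raise ValidationError("no batch labels attached")
        seen: dict[str, None] = {}
        for b in self.batch_of_cell:
            seen.setdefault(b)
        return list(seen)

    def batch_mask(self, batch: str) -> np.ndarray:
        return np.asarray(self.batch_of_cell == batch)

    def marker_available(self, marker: str, batch: str) -> bool:
        if self.availability is None:
            return True
        try:
            return bool(self.availability.loc[marker, batch])
        except KeyError:
            return True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.cell_ids, columns=self.marker_names)


# --------------------------------------------------------------------------
# readers / writers
# --------------------------------------------------------------------------

def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def read_counts(path_or_paths, format: str | None = None) -> ADTDataset:
    """Read a counts matrix from a dense table or Matrix Market triplet.

    ``path_or_paths`` is a single path for a dense CSV/TSV (header = marker
    names, first column = cell id), or a ``(matrix.mtx, features, barcodes)``
    triple for sparse input.  The MTX matrix is features x barcodes and is
    transposed to cells x markers on read.
    """
    if isinstance(path_or_paths, (tuple, list)):
        mtx_path, feat_path, bc_path = (Path(p) for p in path_or_paths)
        mat = mmread(str(mtx_path)).toarray().T  # -> cells x markers
        markers = pd.read_csv(feat_path, sep="\t", header=None)[0].astype(str).tolist()
        cells = pd.read_csv(bc_path, sep="\t", header=None)[0].astype(str).tolist()
        return ADTDataset(mat, cells, markers)

    path = Path(path_or_paths)
    if format == "matrix-market-triplet" or path.suffix.lower() == ".mtx":
        base = path.parent
        return read_counts((path, base / "features.tsv", base / "barcodes.tsv"))

    df = _read_table(path)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValidationError(
                f"non-numeric entry in marker {col!r}"
                + (f" for cell {bad[0]!r}" if len(bad) else "")
            )
    return ADTDataset(
        df.to_numpy(),
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
    )


def attach_batches(ds: ADTDataset, meta, batch_key: str) -> ADTDataset:
    """Attach per-cell batch labels from a metadata table.

    ``meta`` is a DataFrame or path to a CSV/TSV with a ``cell_id`` column
    and one or more candidate batch columns.  Batches with zero cells are
    dropped implicitly (labels are per cell).
    """
    if not isinstance(meta, pd.DataFrame):
        p = Path(meta)
        sep = "\t" if p.suffix.lower() in {".tsv", ".txt"} else ","
        meta = pd.read_csv(p, sep=sep)
    if "cell_id" not in meta.columns:
        raise ValidationError("metadata must have a 'cell_id' column")
    if batch_key not in meta.columns:
        raise ValidationError(f"batch key {batch_key!r} not in metadata columns")
    lut = dict(zip(meta["cell_id"].astype(str), meta[batch_key].astype(str)))
    missing = [cid for cid in ds.cell_ids if cid not in lut]
    if missing:
        raise ValidationError(
            f"{len(missing)} cell ids missing from metadata, e.g. {missing[:5]}"
        )
    labels = np.array([lut[cid] for cid in ds.cell_ids], dtype=object)
    return ADTDataset(
        ds.counts, ds.cell_ids, ds.marker_names, labels, ds.availability
    )


def write_normalized(values: np.ndarray, ds: ADTDataset, out_path) -> Path:
    """Write a normalized matrix as a dense table mirroring the input layout.

    Entries for a (marker, batch) absent per availability are written as NA.
    Round-trips losslessly at ~1e-9 precision.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != ds.counts.shape:
        raise ValidationError(
            f"values shape {values.shape} does not match dataset {ds.counts.shape}"
        )
    out = np.array(values, dtype=float, copy=True)
    if ds.availability is not None and ds.batch_of_cell is not None:
        for j, marker in enumerate(ds.marker_names):
            for batch in ds.batches:
                if not ds.marker_available(marker, batch):
                    out[ds.batch_mask(batch), j] = np.nan
    df = pd.DataFrame(out, index=ds.cell_ids, columns=ds.marker_names)
    out_path = Path(out_path)
    sep = "\t" if out_path.suffix.lower() in {".tsv", ".txt"} else ","
    df.to_csv(out_path, sep=sep, float_format="%.12g", index_label="cell_id")
    return out_path


def read_normalized(path) -> pd.DataFrame:
    return _read_table(Path(path))


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

DEFAULT_BANDWIDTH_LADDER = (0.5, 0.25, 0.1)


@dataclass
class RunConfig:
    """All tunables of the normalization pipeline.

    Defaults follow common cytometry practice: cofactor-5 arcsinh, 512-point
    density grid, scaled-MAD multiplier 3, near-interpolating warps.
    ``neg_candidate_thres`` defaults to ``asinh(10 / cofactor)`` so counts of
    10 or fewer are treated as candidate background.
    """

    arcsinh_cofactor: float = 5.0
    grid_size: int = 512
    bandwidth_ladder: tuple[float, ...] = DEFAULT_BANDWIDTH_LADDER
    neg_candidate_thres: float | None = None
    mad_multiplier: float = 3.0
    lambda_penalty: float = 1e-6
    min_height_frac: float = 0.01
    slope_valley_frac: float = 0.1
    minor_peak_frac: float = 1.0 / 3.0
    k_neighbors: int = 2
    mad_min_deviation: float = 0.2
    quality_threshold: float = 5.0
    target_landmark_location: dict[str, tuple[float, ...]] = field(default_factory=dict)
    positive_peak_only: set[tuple[str, str]] = field(default_factory=set)  # (batch, marker)
    peak_count_prior: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # YAML 1.1 parses exponent-only literals like "1e-06" as strings
        for name in ("arcsinh_cofactor", "mad_multiplier", "lambda_penalty",
                     "min_height_frac", "slope_valley_frac", "minor_peak_frac",
                     "mad_min_deviation", "quality_threshold"):
            setattr(self, name, float(getattr(self, name)))
        if self.neg_candidate_thres is not None:
            self.neg_candidate_thres = float(self.neg_candidate_thres)
        self.grid_size = int(self.grid_size)
        self.k_neighbors = int(self.k_neighbors)
        if self.neg_candidate_thres is None:
            self.neg_candidate_thres = float(np.arcsinh(10.0 / self.arcsinh_cofactor))
        self.bandwidth_ladder = tuple(float(b) for b in self.bandwidth_ladder)
        self.positive_peak_only = {tuple(p) for p in self.positive_peak_only}
        self.validate()

    def validate(self) -> None:
        if self.arcsinh_cofactor <= 0:
            raise ValidationError("arcsinh_cofactor must be positive")
        if self.grid_size < 16:
            raise ValidationError("grid_size too small")
        bl = self.bandwidth_ladder
        if not bl or any(b <= 0 for b in bl):
            raise ValidationError("bandwidth ladder must be positive")
        if any(b2 >= b1 for b1, b2 in zip(bl, bl[1:])):
            raise ValidationError("bandwidth ladder must be strictly decreasing")
        for name in ("neg_candidate_thres", "mad_multiplier", "lambda_penalty",
                     "min_height_frac", "slope_valley_frac", "minor_peak_frac",
                     "mad_min_deviation"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValidationError(f"{name} must be finite")
        if self.mad_multiplier <= 0:
            raise ValidationError("mad_multiplier must be positive")
        if self.lambda_penalty < 0:
            raise ValidationError("lambda_penalty must be non-negative")
        for marker, tl in self.target_landmark_location.items():
            tl = tuple(float(t) for t in tl)
            if any(b <= a for a, b in zip(tl, tl[1:])):
                raise ValidationError(
                    f"target_landmark_location for {marker!r} must be strictly increasing"
                )
            self.target_landmark_location[marker] = tl

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load config from a YAML/JSON document mirroring the field names.

        Unknown keys are an error — this catches typos in per-marker
        overrides.
        """
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        if "positive_peak_only" in data:
            data["positive_peak_only"] = {
                (str(b), str(m)) for b, m in data["positive_peak_only"]
            }
        if "target_landmark_location" in data:
            data["target_landmark_location"] = {
                str(k): tuple(v) for k, v in data["target_landmark_location"].items()
            }
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["positive_peak_only"] = sorted(list(p) for p in self.positive_peak_only)
        d["bandwidth_ladder"] = list(self.bandwidth_ladder)
        d["target_landmark_location"] = {
            k: list(v) for k, v in self.target_landmark_location.items()
        }
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def to_anndata(ds: ADTDataset):
    """Optional adapter: export to an AnnData object (anndata not required)."""
    import anndata as ad

    adata = ad.AnnData(X=np.asarray(ds.counts, dtype=float))
    adata.obs_names = ds.cell_ids
    adata.var_names = ds.marker_names
    if ds.batch_of_cell is not None:
        adata.obs["batch"] = pd.Categorical(ds.batch_of_cell)
    return adata
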