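"""Synthetic ADT count generator with exact landmark ground truth.

Cells belong to shared populations (cell types); each marker maps every
population to one of its mixture components.  Values are drawn on the
arcsinh scale — Normal(mode + batch_shift, sd * batch_scale) — then inverted
to the count scale and rounded, so true peak modes and analytic mixture
valleys are known by construction while near-zero discreteness artifacts are
exercised naturally.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core_data import ADTDataset, RunConfig, ValidationError


@dataclass
class MarkerSpec:
    """Mixture description for one marker.

    ``modes``/``sds`` are per mixture component (arcsinh scale, strictly
    increasing modes); ``pop_component`` maps each shared population index
    to the component that population expresses.
    """

    name: str
    modes: tuple[float, ...]
    sds: tuple[float, ...]
    pop_component: tuple[int, ...]
    expected_peaks: int = 2

    def __post_init__(self) -> None:
        if len(self.modes) != len(self.sds):
            raise ValidationError(f"{self.name}: modes/sds length mismatch")
        if any(b <= a for a, b in zip(self.modes, self.modes[1:])):
            raise ValidationError(f"{self.name}: modes must be strictly increasing")
        if any(s <= 0 for s in self.sds):
            raise ValidationError(f"{self.name}: sds must be positive")
        if any(c < 0 or c >= len(self.modes) for c in self.pop_component):
            raise ValidationError(f"{self.name}: pop_component out of range")


@dataclass
class BatchSpec:
    """Cell-type composition and global location/scale shift of one batch."""

    name: str
    proportions: tuple[float, ...]   # over shared populations
    shift: float = 0.0               # arcsinh-scale location shift
    scale: float = 1.0               # SD multiplier
    n_cells: int = 2000

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"batch {self.name!r}: proportions must be non-negative and sum to 1")
        if self.scale <= 0:
            raise ValidationError(f"batch {self.name!r}: scale must be positive")


@dataclass
class SimTruth:
    """Ground truth backing a simulated dataset."""

    populations: list[str]
    pop_of_cell: np.ndarray                      # population name per cell
    modes: dict[tuple[str, str], np.ndarray]     # (marker, batch) -> active modes
    valleys: dict[tuple[str, str], np.ndarray]   # analytic mixture minima

    def labels_frame(self, cell_ids) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": cell_ids, "population": self.pop_of_cell})


def _mixture_valleys(modes, sds, weights, lo=None, hi=None, n_grid=4001):
    """Analytic density minima between adjacent active modes."""
    modes = np.asarray(modes, float)
    sds = np.asarray(sds, float)
    weights = np.asarray(weights, float)
    valleys = []
    for a, b in zip(modes[:-1], modes[1:]):
        x = np.linspace(a, b, n_grid)[1:-1]
        dens = np.zeros_like(x)
        for m, s, w in zip(modes, sds, weights):
            dens += w * np.exp(-0.5 * ((x - m) / s) ** 2) / (s * np.sqrt(2 * np.pi))
        valleys.append(float(x[np.argmin(dens)]))
    return np.asarray(valleys)


def simulate_dataset(markers: list[MarkerSpec], batches: list[BatchSpec],
                     seed: int, populations: list[str] | None = None,
                     cofactor: float = 5.0):
    """Draw a reproducible (ADTDataset, SimTruth) pair.

    Per cell: population ~ batch proportions; per marker: arcsinh value ~
    Normal(component mode + shift, component sd * scale); counts =
    round(cofactor * sinh(value)) clipped at 0.
    """
    rng = np.random.default_rng(seed)
    n_pops = len(markers[0].pop_component)
    if populations is None:
        populations = [f"pop{i}" for i in range(n_pops)]
    if len(populations) != n_pops:
        raise ValidationError("populations length mismatch")
    for m in markers:
        if len(m.pop_component) != n_pops:
            raise ValidationError(f"{m.name}: pop_component length mismatch")

    cell_ids: list[str] = []
    batch_labels: list[str] = []
    pop_labels: list[str] = []
    count_blocks: list[np.ndarray] = []
    modes_truth: dict[tuple[str, str], np.ndarray] = {}
    valleys_truth: dict[tuple[str, str], np.ndarray] = {}

    for bspec in batches:
        pops = rng.choice(n_pops, size=bspec.n_cells, p=bspec.proportions)
        block = np.zeros((bspec.n_cells, len(markers)), dtype=np.int64)
        for j, mspec in enumerate(markers):
            comp = np.asarray(mspec.pop_component)[pops]
            mu = np.asarray(mspec.modes)[comp] + bspec.shift
            sd = np.asarray(mspec.sds)[comp] * bspec.scale
            vals = rng.normal(mu, sd)
            block[:, j] = np.maximum(
                np.rint(cofactor * np.sinh(vals)), 0).astype(np.int64)
            # truth: active components of this batch
            props = np.zeros(len(mspec.modes))
            for pi, w in enumerate(bspec.proportions):
                props[mspec.pop_component[pi]] += w
            active = props > 0
            act_modes = (np.asarray(mspec.modes)[active] + bspec.shift)
            act_sds = np.asarray(mspec.sds)[active] * bspec.scale
            act_w = props[active] / props[active].sum()
            modes_truth[(mspec.name, bspec.name)] = act_modes
            valleys_truth[(mspec.name, bspec.name)] = _mixture_valleys(
                act_modes, act_sds, act_w)
        start = len(cell_ids)
        cell_ids += [f"{bspec.name}_cell{start + i}" for i in range(bspec.n_cells)]
        batch_labels += [bspec.name] * bspec.n_cells
        pop_labels += [populations[p] for p in pops]
        count_blocks.append(block)

    ds = ADTDataset(
        np.vstack(count_blocks), cell_ids, [m.name for m in markers],
        np.array(batch_labels, dtype=object))
    truth = SimTruth(populations, np.array(pop_labels, dtype=object),
                     modes_truth, valleys_truth)
    return ds, truth


# --------------------------------------------------------------------------
# scenario builders
# --------------------------------------------------------------------------

def _restrict(batch: BatchSpec, keep: list[int]) -> BatchSpec:
    p = np.zeros(len(batch.proportions))
    base = np.asarray(batch.proportions)
    for k in keep:
        p[k] = base[k]
    if p.sum() == 0:
        p[keep[0]] = 1.0
    return replace(batch, proportions=tuple(p / p.sum()))


def imbalance_batches(batches: list[BatchSpec], scenario: str,
                      t_pops: list[int] | None = None,
                      sub_pop: int | None = None) -> list[BatchSpec]:
    """Batch specs for a skewed-composition scenario.

    ``mild`` restricts the last batch to the T-like populations; ``moderate``
    restricts all but the first batch; ``severe`` additionally restricts the
    last batch to a single sub-population.
    """
    if scenario not in {"mild", "moderate", "severe"}:
        raise ValidationError(f"unknown scenario {scenario!r}")
    n_pops = len(batches[0].proportions)
    if n_pops < 2:
        raise ValidationError("need >= 2 populations for imbalance scenarios")
    if t_pops is None:
        t_pops = list(range(1, n_pops))  # convention: population 0 is the B-like one
    if sub_pop is None:
        sub_pop = t_pops[0]
    new = list(batches)
    if scenario == "mild":
        new[-1] = _restrict(new[-1], t_pops)
    elif scenario == "moderate":
        for i in range(1, len(new)):
            new[i] = _restrict(new[i], t_pops)
    else:
        for i in range(1, len(new) - 1):
            new[i] = _restrict(new[i], t_pops)
        new[-1] = _restrict(new[-1], [sub_pop])
    return new


def positive_only_pairs(markers: list[MarkerSpec],
                        batches: list[BatchSpec]) -> set[tuple[str, str]]:
    """(batch, marker) pairs whose composition leaves a single *expressing*
    component — the prior-knowledge override a user would supply."""
    pairs = set()
    for mspec in markers:
        for bspec in batches:
            comps = {mspec.pop_component[i]
                     for i, w in enumerate(bspec.proportions) if w > 0}
            if len(comps) == 1 and next(iter(comps)) > 0:
                pairs.add((bspec.name, mspec.name))
    return pairs


def simulate_imbalance(markers: list[MarkerSpec], batches: list[BatchSpec],
                       scenario: str, seed: int,
                       populations: list[str] | None = None,
                       t_pops: list[int] | None = None,
                       sub_pop: int | None = None,
                       cofactor: float = 5.0):
    """Skew cell-type composition across batches and simulate; see
    :func:`imbalance_batches` for the scenarios."""
    new = imbalance_batches(batches, scenario, t_pops, sub_pop)
    return simulate_dataset(markers, new, seed, populations, cofactor)


def simulate_titration(levels: dict[str, float] | None = None, seed: int = 0,
                       n_cells: int = 2000, cofactor: float = 5.0):
    """One bimodal marker titrated across antibody concentrations.

    Each concentration level becomes one batch.  Higher concentration means
    larger positive/negative separation, a sharper positive peak and a larger
    positive fraction; the lowest level drops the positive population
    entirely (stain failure).  Returns ``(ADTDataset, SimTruth, levels)``.
    """
    if levels is None:
        levels = {"1/25x": 0.04, "1/5x": 0.2, "1x": 1.0, "2x": 2.0}
    order = sorted(levels, key=levels.get)
    neg_mode = 0.9
    batches = []
    marker_variants: dict[str, MarkerSpec] = {}
    for name in order:
        conc = levels[name]
        if conc <= 0.05:
            pos_frac = 0.0
            sep, pos_sd = 0.8, 0.65
        else:
            # saturating dose-response: separation grows with log-concentration
            sep = 1.2 + 1.1 * np.log10(conc / 0.2 + 1.0) / np.log10(11.0) * 2.0
            pos_sd = max(0.25, 0.55 - 0.12 * np.log10(conc / 0.04))
            pos_frac = 0.45
        marker_variants[name] = MarkerSpec(
            "CD9", (neg_mode, neg_mode + sep), (0.22, pos_sd), (0, 1),
            expected_peaks=1 if pos_frac == 0 else 2)
        batches.append(BatchSpec(name, (1.0 - pos_frac, pos_frac),
                                 n_cells=n_cells))

    # one dataset, one batch per level, each with its own mixture geometry
    rng = np.random.default_rng(seed)
    cell_ids, batch_labels, pop_labels, blocks = [], [], [], []
    modes_truth, valleys_truth = {}, {}
    for bspec in batches:
        mspec = marker_variants[bspec.name]
        pops = rng.choice(2, size=bspec.n_cells, p=bspec.proportions)
        mu = np.asarray(mspec.modes)[pops]
        sd = np.asarray(mspec.sds)[pops]
        vals = rng.normal(mu, sd)
        counts = np.maximum(np.rint(cofactor * np.sinh(vals)), 0).astype(np.int64)
        blocks.append(counts[:, None])
        start = len(cell_ids)
        cell_ids += [f"{bspec.name}_cell{start + i}" for i in range(bspec.n_cells)]
        batch_labels += [bspec.name] * bspec.n_cells
        pop_labels += ["negative" if p == 0 else "positive" for p in pops]
        w = np.asarray(bspec.proportions)
        active = w > 0
        act_modes = np.asarray(mspec.modes)[active]
        modes_truth[("CD9", bspec.name)] = act_modes
        valleys_truth[("CD9", bspec.name)] = _mixture_valleys(
            act_modes, np.asarray(mspec.sds)[active], w[active] / w[active].sum())
    ds = ADTDataset(np.vstack(blocks), cell_ids, ["CD9"],
                    np.array(batch_labels, dtype=object))
    truth = SimTruth(["negative", "positive"], np.array(pop_labels, dtype=object),
                     modes_truth, valleys_truth)
    return ds, truth, {name: levels[name] for name in order}


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------

DEFAULT_POPULATIONS = ["B", "CD4T", "CD8T", "Mono"]

# CD3: neg on B/Mono, pos on T.  CD4: trimodal (neg / mid on Mono / high on
# CD4T).  CD19: pos on B only.  IgCtrl: unimodal background.
DEFAULT_MARKERS = [
    MarkerSpec("CD3", (1.0, 3.6), (0.22, 0.30), (0, 1, 1, 0), expected_peaks=2),
    MarkerSpec("CD4", (1.0, 2.7, 4.3), (0.20, 0.25, 0.26), (0, 2, 0, 1),
               expected_peaks=3),
    MarkerSpec("CD19", (1.0, 3.4), (0.22, 0.30), (1, 0, 0, 0), expected_peaks=2),
    MarkerSpec("IgCtrl", (1.0,), (0.25,), (0, 0, 0, 0), expected_peaks=1),
]

DEFAULT_BATCHES = [
    BatchSpec("batch1", (0.25, 0.30, 0.25, 0.20), shift=0.0, scale=1.00),
    BatchSpec("batch2", (0.20, 0.35, 0.25, 0.20), shift=0.8, scale=1.10),
    BatchSpec("batch3", (0.30, 0.25, 0.25, 0.20), shift=-0.5, scale=0.95),
]


def default_fixture(seed: int = 0, n_cells: int = 2000):
    """3 batches x 4 markers x ``n_cells`` cells with batch shifts up to
    +-1.0 arcsinh units.  Returns ``(ADTDataset, SimTruth, RunConfig)``."""
    batches = [replace(b, n_cells=n_cells) for b in DEFAULT_BATCHES]
    ds, truth = simulate_dataset(DEFAULT_MARKERS, batches, seed,
                                 DEFAULT_POPULATIONS)
    config = RunConfig(peak_count_prior={"CD4": 3, "IgCtrl": 1})
    return ds, truth, config


def gating_fixture(seed: int = 0, n_cells: int = 2000):
    """3 populations (B / CD4 T / CD8 T), 4 markers, >= 6 SD peak separation.

    Returns ``(ADTDataset, SimTruth, RunConfig)``; populations are the
    gating ground truth.
    """
    pops = ["B", "CD4T", "CD8T"]
    markers = [
        MarkerSpec("CD3", (0.8, 3.8), (0.20, 0.25), (0, 1, 1)),
        MarkerSpec("CD4", (0.8, 3.8), (0.20, 0.25), (0, 1, 0)),
        MarkerSpec("CD8", (0.8, 3.8), (0.20, 0.25), (0, 0, 1)),
        MarkerSpec("CD19", (0.8, 3.8), (0.20, 0.25), (1, 0, 0)),
    ]
    batches = [
        BatchSpec("s1", (0.34, 0.33, 0.33), shift=0.0, n_cells=n_cells),
        BatchSpec("s2", (0.30, 0.40, 0.30), shift=0.6, n_cells=n_cells),
    ]
    ds, truth = simulate_dataset(markers, batches, seed, pops)
    return ds, truth, RunConfig()


def write_simulation(out_dir, ds: ADTDataset, truth: SimTruth,
                     config: RunConfig | None = None) -> None:
    """Write counts (CSV + MTX triplet), metadata, truth labels and config."""
    from pathlib import Path

    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds.to_frame().to_csv(out / "counts.csv", index_label="cell_id")
    mmwrite(str(out / "counts.mtx"), csr_matrix(ds.counts.T))
    pd.Series(ds.marker_names).to_csv(out / "features.tsv", sep="\t",
                                      index=False, header=False)
    pd.Series(ds.cell_ids).to_csv(out / "barcodes.tsv", sep="\t",
                                  index=False, header=False)
    pd.DataFrame({"cell_id": ds.cell_ids, "batch": ds.batch_of_cell,
                  "population": truth.pop_of_cell}).to_csv(
        out / "metadata.csv", index=False)
    rows = []
    for (m, b), modes in truth.modes.items():
        for i, loc in enumerate(modes):
            rows.append({"marker": m, "batch": b, "kind": "peak",
                         "index": i, "location": loc})
        for i, loc in enumerate(truth.valleys[(m, b)]):
            rows.append({"marker": m, "batch": b, "kind": "valley",
                         "index": i, "location": loc})
    pd.DataFrame(rows).to_csv(out / "sim_truth.tsv", sep="\t", index=False)
    if config is not None:
        (out / "config.json").write_text(config.to_json())
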