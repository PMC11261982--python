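"""Valley-threshold auto-gating, accuracy scoring and percent positivity.

A cell is positive for a marker iff its normalized value is >= that marker's
aligned valley (ties at the threshold gate positive).  Because thresholds
come from the shared post-alignment valleys, a single rule set serves all
batches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import ValidationError

RELATIONS = {"above_valley", "below_valley", "between_valleys"}


@dataclass
class GatingRule:
    """One cell-type definition: conjunction of marker/valley conditions.

    ``conditions`` entries are ``(marker, relation, valley_index)`` with a
    1-based valley index; ``between_valleys`` with index i selects the band
    between valley i and valley i+1.
    """

    cell_type: str
    conditions: list[tuple[str, str, int]]
    parent: str | None = None

    def __post_init__(self) -> None:
        for marker, rel, idx in self.conditions:
            if rel not in RELATIONS:
                raise ValidationError(
                    f"rule {self.cell_type!r}: unknown relation {rel!r}")
            if idx < 1:
                raise ValidationError(
                    f"rule {self.cell_type!r}: valley index must be >= 1")


@dataclass
class GateResult:
    labels: pd.Series                      # per-cell terminal label or "ungated"
    thresholds: dict[tuple[str, int], float] = field(default_factory=dict)

    def counts(self) -> pd.Series:
        return self.labels.value_counts()


def read_rules(path) -> list[GatingRule]:
    """Load rules from TSV (cell_type, parent, marker, relation, valley_index;
    one row per condition) or JSON (list of rule objects)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        return [GatingRule(r["cell_type"],
                           [tuple(c) for c in r["conditions"]],
                           r.get("parent")) for r in data]
    df = pd.read_csv(path, sep="\t")
    rules: dict[str, GatingRule] = {}
    for _, row in df.iterrows():
        ct = str(row["cell_type"])
        parent = row.get("parent")
        parent = None if pd.isna(parent) or parent in ("", "None") else str(parent)
        cond = (str(row["marker"]), str(row["relation"]), int(row["valley_index"]))
        if ct in rules:
            rules[ct].conditions.append(cond)
        else:
            rules[ct] = GatingRule(ct, [cond], parent)
    return list(rules.values())


def _resolve_chain(rule: GatingRule, by_name: dict[str, GatingRule]):
    """Own conditions plus all ancestors'; detects hierarchy cycles."""
    conds = list(rule.conditions)
    seen = {rule.cell_type}
    cur = rule
    while cur.parent is not None:
        if cur.parent not in by_name:
            raise ValidationError(
                f"rule {cur.cell_type!r} references unknown parent {cur.parent!r}")
        cur = by_name[cur.parent]
        if cur.cell_type in seen:
            raise ValidationError(f"gating hierarchy cycle at {cur.cell_type!r}")
        seen.add(cur.cell_type)
        conds = list(cur.conditions) + conds
    return conds


def _valley_lookup(landmarks) -> dict[tuple[str, int], float]:
    """Accept a mapping {marker: [valleys...]}, a NormalizationResult, or a
    long-format landmark/target table and return {(marker, idx): location}."""
    out: dict[tuple[str, int], float] = {}
    if hasattr(landmarks, "markers"):  # NormalizationResult
        for m, res in landmarks.markers.items():
            for i, s in enumerate(res.slot_names):
                if s.startswith("valley_"):
                    out[(m, int(s.split("_")[1]))] = float(res.targets.locations[i])
        return out
    if isinstance(landmarks, pd.DataFrame):
        for _, row in landmarks.iterrows():
            if str(row.get("slot", row.get("landmark_type", ""))).startswith("valley"):
                slot = str(row.get("slot", ""))
                idx = int(slot.split("_")[1]) if slot else int(row["index"]) + 1
                out[(str(row["marker"]), idx)] = float(row["location"])
        return out
    for m, valleys in landmarks.items():
        if np.isscalar(valleys):
            valleys = [valleys]
        for i, v in enumerate(valleys, start=1):
            out[(m, i)] = float(v)
    return out


def auto_gate(values: pd.DataFrame, landmarks, rules: list[GatingRule]) -> GateResult:
    """Assign each cell the first matching terminal cell type.

    ``values`` is the normalized cells x markers frame; ``landmarks``
    supplies the aligned valley thresholds.  Rules are evaluated top-down
    through the hierarchy (a child inherits its ancestors' conditions);
    cells matching no terminal rule are "ungated".
    """
    thresholds = _valley_lookup(landmarks)
    by_name = {r.cell_type: r for r in rules}
    parents = {r.parent for r in rules if r.parent is not None}
    terminal = [r for r in rules if r.cell_type not in parents]

    labels = pd.Series("ungated", index=values.index, dtype=object)
    unassigned = np.ones(len(values), dtype=bool)
    for rule in terminal:
        conds = _resolve_chain(rule, by_name)
        mask = np.ones(len(values), dtype=bool)
        for marker, rel, idx in conds:
            if marker not in values.columns:
                raise ValidationError(
                    f"rule {rule.cell_type!r} references missing marker {marker!r}")
            if (marker, idx) not in thresholds:
                raise ValidationError(
                    f"rule {rule.cell_type!r} references missing valley "
                    f"{idx} of marker {marker!r}")
            v = values[marker].to_numpy(dtype=float)
            thr = thresholds[(marker, idx)]
            if rel == "above_valley":
                mask &= v >= thr
            elif rel == "below_valley":
                mask &= v < thr
            else:  # between_valleys(i): [valley_i, valley_{i+1})
                if (marker, idx + 1) not in thresholds:
                    raise ValidationError(
                        f"rule {rule.cell_type!r}: between_valleys({idx}) needs "
                        f"valley {idx + 1} of {marker!r}")
                upper = thresholds[(marker, idx + 1)]
                mask &= (v >= thr) & (v < upper)
        hit = mask & unassigned
        labels.iloc[np.nonzero(hit)[0]] = rule.cell_type
        unassigned &= ~hit
    return GateResult(labels, thresholds)


def gating_accuracy(result: GateResult, reference, label_map=None) -> pd.DataFrame:
    """Per-cell-type fraction of reference cells receiving the matching
    label, plus the macro average (empty classes reported NA, excluded)."""
    ref = pd.Series(reference)
    if len(ref) != len(result.labels):
        raise ValidationError("reference length mismatch")
    ref = ref.set_axis(result.labels.index)
    if label_map:
        unmapped = set(ref.unique()) - set(label_map)
        if unmapped:
            raise ValidationError(f"unmapped reference labels: {sorted(unmapped)}")
        ref = ref.map(label_map)
    rows = []
    for ct in sorted(ref.unique()):
        members = ref == ct
        n = int(members.sum())
        acc = float((result.labels[members] == ct).mean()) if n else np.nan
        rows.append({"cell_type": ct, "n": n, "accuracy": acc})
    table = pd.DataFrame(rows)
    macro = table.loc[table["n"] > 0, "accuracy"].mean()
    table.attrs["macro_accuracy"] = float(macro)
    return table


def percent_positive(values, threshold_or_landmarks, marker: str | None = None,
                     subset=None) -> float:
    """Fraction of subset cells at or above the marker's aligned valley."""
    if isinstance(values, pd.DataFrame):
        if marker is None:
            raise ValidationError("marker required for a DataFrame input")
        v = values[marker].to_numpy(dtype=float)
    else:
        v = np.asarray(values, dtype=float)
    if np.isscalar(threshold_or_landmarks):
        thr = float(threshold_or_landmarks)
    else:
        lut = _valley_lookup(threshold_or_landmarks)
        thr = lut[(marker, 1)]
    if subset is not None:
        v = v[np.asarray(subset)]
    if v.size == 0:
        raise ValidationError("empty cell subset")
    return float(np.mean(v >= thr))
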