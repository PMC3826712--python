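"""Patch-to-patch connectivity tables and summary statistics.

A connectivity table holds one record per unordered patch pair within a
Euclidean gate distance (default 25 km — the dispersal range beyond which
little or no gene flow is observed for the gazelle): edge-to-edge Euclidean
distance, least-cost path length and movement cost, and the cost of the
narrowest-point-1-km corridor.  Traversability is classified against a
reference pair with documented inter-patch movements: a pair is traversable
iff its movement cost does not exceed the reference pair's.

The package ships a transcription of the published 15-pair connectivity
summary for the Przewalski's gazelle populations around Qinghai Lake
(patches GZ, HG, TL, SG, KM, KT, SI, HD, YZ, WY, RQ and potential patches
P1, P2), including the landscape-genetics annotation columns (standardized
F'_ST and first-generation migrant counts) which are carried as inert
validation metadata, never computed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import corridor_surface, corridor_width_cost, cost_distance, least_cost_path
from .patches import Patch, euclidean_patch_distance
from .surfaces import Surface

__all__ = [
    "ConnectivityRecord",
    "ConnectivityTable",
    "build_network",
    "classify_traversable",
    "summarize",
    "load_reference_table",
    "REFERENCE_TABLE_RESOURCE",
]

#: Package-data path of the published gazelle connectivity transcription.
REFERENCE_TABLE_RESOURCE = "data/qinghai_gazelle_connectivity.csv"

_NUMERIC_COLUMNS = ("euclidean_km", "lcp_length_km", "movement_cost", "corridor_1km_cost")


@dataclass(frozen=True)
class ConnectivityRecord:
    """One unordered patch pair's connectivity measurements."""

    pair: tuple[str, str]
    euclidean_km: float
    lcp_length_km: float
    movement_cost: float
    corridor_1km_cost: float
    traversable: bool | None = None  # None = undetermined (no reference applied)
    reachable: bool = True
    annotations: dict = field(default_factory=dict)

    @property
    def key(self) -> frozenset:
        return frozenset(self.pair)


@dataclass
class ConnectivityTable:
    records: list[ConnectivityRecord]
    provenance: str = "computed"  # 'computed' | 'transcribed-fixture'

    def __post_init__(self) -> None:
        keys = [r.key for r in self.records]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate patch pairs in connectivity table")

    def __len__(self) -> int:
        return len(self.records)

    def record(self, a: str, b: str) -> ConnectivityRecord:
        want = frozenset((a, b))
        for r in self.records:
            if r.key == want:
                return r
        raise KeyError(f"pair {a}-{b} not in table")

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "pair_a": r.pair[0],
                "pair_b": r.pair[1],
                "euclidean_km": r.euclidean_km,
                "lcp_length_km": r.lcp_length_km,
                "movement_cost": r.movement_cost,
                "corridor_1km_cost": r.corridor_1km_cost,
                "traversable": "" if r.traversable is None else bool(r.traversable),
            }
            row.update(r.annotations)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, provenance: str = "computed") -> "ConnectivityTable":
        extra = [c for c in df.columns if c not in ("pair_a", "pair_b", "traversable", *_NUMERIC_COLUMNS)]
        records = []
        for _, row in df.iterrows():
            trav = row.get("traversable", None)
            if isinstance(trav, str):
                trav = {"true": True, "false": False}.get(trav.strip().lower(), None)
            elif trav is not None and not isinstance(trav, bool) and pd.isna(trav):
                trav = None
            records.append(
                ConnectivityRecord(
                    pair=(str(row["pair_a"]), str(row["pair_b"])),
                    euclidean_km=float(row["euclidean_km"]),
                    lcp_length_km=float(row["lcp_length_km"]),
                    movement_cost=float(row["movement_cost"]),
                    corridor_1km_cost=float(row["corridor_1km_cost"]),
                    traversable=trav,
                    annotations={c: row[c] for c in extra},
                )
            )
        return cls(records, provenance)

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str = "computed") -> "ConnectivityTable":
        return cls.from_dataframe(pd.read_csv(path), provenance)


def load_reference_table() -> ConnectivityTable:
    """The shipped transcription of the published gazelle connectivity summary."""
    res = importlib.resources.files("patchconnect").joinpath(REFERENCE_TABLE_RESOURCE)
    with importlib.resources.as_file(res) as p:
        return ConnectivityTable.from_csv(p, provenance="transcribed-fixture")


def build_network(
    patches: list[Patch],
    cost_surface: Surface,
    max_euclid_km: float = 25.0,
    width_km: float = 1.0,
) -> ConnectivityTable:
    """Compute connectivity records for all patch pairs within the gate.

    Pairs separated by more than ``max_euclid_km`` (edge-to-edge) are
    omitted; gated pairs that turn out mutually unreachable over the cost
    surface are kept with a no-path flag rather than silently dropped.
    One cost-distance field per patch is computed and shared across pairs.
    """
    if len(patches) < 2:
        raise ValueError("need at least two patches to build a network")
    s = cost_surface.cell_size_m
    fields: dict[str, object] = {}

    def field_for(p: Patch):
        if p.id not in fields:
            fields[p.id] = cost_distance(cost_surface, p)
        return fields[p.id]

    records = []
    for i in range(len(patches)):
        for j in range(i + 1, len(patches)):
            a, b = patches[i], patches[j]
            euclid = euclidean_patch_distance(a, b, s)
            if euclid > max_euclid_km:
                continue
            cd_a = field_for(a)
            path = least_cost_path(cost_surface, a, b, field_a=cd_a)
            if path is None:
                records.append(
                    ConnectivityRecord((a.id, b.id), euclid, np.nan, np.inf, np.inf, reachable=False)
                )
                continue
            cd_b = field_for(b)
            barrier = ~cost_surface.valid_mask
            C = corridor_surface(cd_a, cd_b, barrier_mask=barrier)
            wres = corridor_width_cost(C, width_km=width_km)
            corridor_cost = wres.threshold_cost if wres.achieved else np.nan
            records.append(
                ConnectivityRecord((a.id, b.id), euclid, path.length_km, path.total_cost, corridor_cost)
            )
    return ConnectivityTable(records, provenance="computed")


def classify_traversable(table: ConnectivityTable, reference_pair: tuple[str, str]) -> ConnectivityTable:
    """Flag pairs whose movement cost <= the reference pair's; sort by cost.

    The reference pair (one with documented inter-patch movements) is itself
    traversable by construction.  Records come back in ascending movement
    cost — descending permeability.
    """
    ref = table.record(*reference_pair)  # KeyError if missing
    threshold = ref.movement_cost
    flagged = [replace(r, traversable=bool(r.movement_cost <= threshold)) for r in table.records]
    flagged.sort(key=lambda r: (r.movement_cost, r.pair))
    return ConnectivityTable(flagged, provenance=table.provenance)


def summarize(table: ConnectivityTable) -> pd.DataFrame:
    """Per-column n/min/max/mean over the table's data rows."""
    if len(table) == 0:
        raise ValueError("cannot summarize an empty connectivity table")
    df = table.to_dataframe()
    stats = {}
    for col in _NUMERIC_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        vals = vals[np.isfinite(vals)]
        stats[col] = {"n": int(vals.size), "min": vals.min(), "max": vals.max(), "mean": vals.mean()}
    return pd.DataFrame(stats).T[["n", "min", "max", "mean"]]
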