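"""Rule-table reclassification of raw landscape layers into 1-10 scores.

Each landscape variable (elevation, slope, NDVI, human density, distances to
linear/areal features) carries an ordered set of half-open bins ``[a, b)``
mapping raw values to integer scores 1-10 or to BARRIER.  A BARRIER bin marks
cells the focal species never uses or crosses: such cells are excluded from
habitat statistics and removed from the movement graph downstream.  BARRIER is
distinct from nodata, which means "no information" and merely propagates.

The shipped default tables encode the expert-determined classification for
Przewalski's gazelle in the Qinghai Lake region: eight habitat-suitability
variables and seven movement-cost variables, with relative AHP weights.  Bin
boundary convention throughout: closed lower bound, open upper bound;
``< x`` means ``(-inf, x)`` and ``> x`` means ``[x, +inf)``, so printed
touching ranges tile the domain with no overlap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ahp import WeightSet
from .grid import RasterGrid

__all__ = [
    "BARRIER",
    "RuleTable",
    "ScoreGrid",
    "RuleTableError",
    "load_rule_tables",
    "reclassify_layer",
    "SUITABILITY_VARIABLES",
    "COST_VARIABLES",
    "default_suitability_weights",
    "default_cost_weights",
]

#: Sentinel score for cells the species never uses (the rule tables' N/A).
BARRIER = "BARRIER"

INF = float("inf")


class RuleTableError(ValueError):
    """Invalid rule table: overlapping or gapped bins, bad scores."""


@dataclass(frozen=True)
class RuleTable:
    """Ordered bins mapping a variable's raw values to scores 1-10 or BARRIER.

    ``bins`` is a list of ``(lower, upper, score)`` with half-open intervals
    ``[lower, upper)``.  ``domain`` is the variable's full range; validation
    checks the bins tile it exactly.
    """

    variable_name: str
    bins: tuple[tuple[float, float, int | str], ...]
    domain: tuple[float, float] = (-INF, INF)

    def __post_init__(self) -> None:
        object.__setattr__(self, "bins", tuple((float(a), float(b), s) for a, b, s in self.bins))
        self.validate()

    def validate(self) -> None:
        for a, b, s in self.bins:
            if not (s == BARRIER or (isinstance(s, (int, np.integer)) and 1 <= s <= 10)):
                raise RuleTableError(f"{self.variable_name}: score {s!r} not in 1-10 or BARRIER")
            if not a < b:
                raise RuleTableError(f"{self.variable_name}: empty bin [{a}, {b})")
        ordered = sorted(self.bins, key=lambda t: t[0])
        lo, hi = self.domain
        cursor = lo
        for a, b, s in ordered:
            if a < cursor:
                raise RuleTableError(
                    f"{self.variable_name}: bin [{a}, {b}) overlaps previous coverage ending at {cursor}"
                )
            if a > cursor:
                raise RuleTableError(f"{self.variable_name}: gap [{cursor}, {a}) not covered by any bin")
            cursor = b
        if cursor < hi:
            raise RuleTableError(f"{self.variable_name}: gap [{cursor}, {hi}) not covered by any bin")

    def score(self, value: float) -> int | str:
        """Score a single raw value (exact bin lookup)."""
        for a, b, s in self.bins:
            if a <= value < b:
                return s
        raise RuleTableError(f"{self.variable_name}: value {value} falls in no bin")

    def representative_value(self, target_score: int | str) -> float:
        """A raw value guaranteed to map to ``target_score`` (bin midpoint).

        For half-unbounded bins a point one bin-width (or 10% of the finite
        bound) inside the finite edge is used.  Used by the synthetic landscape
        generator to plant cells with known scores.
        """
        for a, b, s in self.bins:
            if s == target_score:
                if np.isfinite(a) and np.isfinite(b):
                    return (a + b) / 2.0
                if np.isfinite(a):  # [a, inf)
                    return a + (abs(a) * 0.1 if a != 0 else 1.0)
                return b - (abs(b) * 0.1 if b != 0 else 1.0)  # (-inf, b)
        raise RuleTableError(f"{self.variable_name}: no bin with score {target_score!r}")

    def achievable_scores(self) -> list[int]:
        return sorted({s for _, _, s in self.bins if s != BARRIER})

    def to_dict(self) -> dict:
        return {
            "variable": self.variable_name,
            "domain": [_json_num(self.domain[0]), _json_num(self.domain[1])],
            "bins": [[_json_num(a), _json_num(b), s] for a, b, s in self.bins],
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "RuleTable":
        dom = obj.get("domain", ["-inf", "inf"])
        bins = tuple((_parse_num(a), _parse_num(b), s if s == BARRIER else int(s)) for a, b, s in obj["bins"])
        return cls(obj["variable"], bins, (_parse_num(dom[0]), _parse_num(dom[1])))


def _json_num(x: float):
    if x == INF:
        return "inf"
    if x == -INF:
        return "-inf"
    return x


def _parse_num(x) -> float:
    return float(x)


@dataclass
class ScoreGrid:
    """A reclassified raster: integer scores 1-10 plus a barrier mask.

    Barrier cells carry no score; their ``values`` entries are set to NaN.
    """

    grid: RasterGrid
    barrier_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.barrier_mask is None:
            self.barrier_mask = np.zeros(self.grid.shape, dtype=bool)
        self.barrier_mask = np.asarray(self.barrier_mask, dtype=bool)
        if self.barrier_mask.shape != self.grid.shape:
            raise ValueError("barrier_mask shape does not match grid")
        ok = ~(self.barrier_mask | self.grid.nodata_mask)
        vals = self.grid.values[ok]
        if vals.size and (np.any(vals < 1) or np.any(vals > 10) or np.any(vals != np.round(vals))):
            raise ValueError("score grid values must be integers in 1-10 outside barrier/nodata")

    @property
    def values(self) -> np.ndarray:
        return self.grid.values

    @property
    def nodata_mask(self) -> np.ndarray:
        return self.grid.nodata_mask


def reclassify_layer(layer: RasterGrid, rules: RuleTable) -> ScoreGrid:
    """Map every non-nodata cell of ``layer`` through its rule-table bin.

    Pure pointwise map: BARRIER bins populate the barrier mask, nodata
    propagates unchanged.  Raises :class:`RuleTableError` naming the first
    offending cell if a value falls in no bin (impossible for validated
    tables whose domain covers the data).
    """
    vals = layer.values
    out = np.full(layer.shape, np.nan)
    barrier = np.zeros(layer.shape, dtype=bool)
    assigned = layer.nodata_mask.copy()
    for a, b, s in rules.bins:
        hit = (~assigned) & (vals >= a) & (vals < b)
        if s == BARRIER:
            barrier |= hit
        else:
            out[hit] = s
        assigned |= hit
    if not assigned.all():
        r, c = np.argwhere(~assigned)[0]
        raise RuleTableError(
            f"{rules.variable_name}: value {vals[r, c]} at cell ({r}, {c}) falls in no bin"
        )
    g = layer.copy_with(out)
    return ScoreGrid(g, barrier)


# ---------------------------------------------------------------------------
# Default rule tables: expert classification for Przewalski's gazelle.
# Suitability scores 1-10 = low to high habitat quality; cost scores 1-10 =
# low to high movement resistance; N/A (BARRIER) = never used / never crossed.
# ---------------------------------------------------------------------------

SUITABILITY_VARIABLES = (
    "elevation",
    "slope",
    "ndvi",
    "human_density",
    "dist_river",
    "dist_highway",
    "dist_railway",
    "dist_farmland",
)

COST_VARIABLES = (
    "elevation",
    "slope",
    "dist_highway",
    "dist_railway",
    "dist_farmland",
    "dist_settlement",
    "dist_house",
)

_DEFAULT_SUITABILITY: dict[str, tuple[tuple[float, float, int | str], ...]] = {
    "elevation": (
        (-INF, 3000, 1),
        (3000, 3200, 4),
        (3200, 3300, 10),
        (3300, 3400, 9),
        (3400, 3500, 8),
        (3500, 3600, 7),
        (3600, 3700, 6),
        (3700, 3800, 5),
        (3800, 3900, 3),
        (3900, 4000, 2),
        (4000, INF, BARRIER),
    ),
    "slope": (
        (0, 5, 10),
        (5, 10, 9),
        (10, 15, 8),
        (15, 20, 6),
        (20, 25, 4),
        (25, 60, 1),
        (60, INF, BARRIER),
    ),
    "ndvi": (
        (-INF, 0.1, 1),
        (0.1, 0.2, 2),
        (0.2, 0.3, 3),
        (0.3, 0.4, 4),
        (0.4, 0.5, 5),
        (0.5, 0.6, 6),
        (0.6, 0.7, 7),
        (0.7, 0.8, 8),
        (0.8, 0.9, 9),
        (0.9, INF, 10),
    ),
    "human_density": (
        (0, 5, 10),
        (5, 10, 9),
        (10, 15, 8),
        (15, 20, 7),
        (20, 25, 6),
        (25, 30, 5),
        (30, 35, 4),
        (35, 40, 3),
        (40, 45, 2),
        (45, INF, 1),
    ),
    "dist_river": (
        (0, 500, 10),
        (500, 1000, 9),
        (1000, 1500, 8),
        (1500, 2000, 6),
        (2000, 2500, 5),
        (2500, 3000, 3),
        (3000, 4000, 2),
        (4000, INF, 1),
    ),
    "dist_highway": (
        (0, 250, 1),
        (250, 500, 3),
        (500, 1000, 5),
        (1000, 1500, 7),
        (1500, 2000, 9),
        (2000, INF, 10),
    ),
    "dist_railway": (
        (0, 250, 2),
        (250, 500, 3),
        (500, 1000, 7),
        (1000, INF, 10),
    ),
    "dist_farmland": (
        (0, 250, 2),
        (250, 500, 4),
        (500, 750, 6),
        (750, 1000, 8),
        (1000, 1500, 9),
        (1500, INF, 10),
    ),
}

_DEFAULT_COST: dict[str, tuple[tuple[float, float, int | str], ...]] = {
    "elevation": (
        (-INF, 3400, 1),
        (3400, 3600, 3),
        (3600, 3800, 5),
        (3800, 3900, 7),
        (3900, 4000, 9),
        (4000, INF, BARRIER),
    ),
    "slope": (
        (0, 5, 1),
        (5, 10, 3),
        (10, 15, 6),
        (15, 20, 8),
        (20, 25, 9),
        (25, 60, 10),
        (60, INF, BARRIER),
    ),
    "dist_highway": (
        (0, 90, 10),
        (90, 150, 9),
        (150, 200, 7),
        (200, 300, 6),
        (300, 500, 4),
        (500, 1000, 3),
        (1000, 2000, 2),
        (2000, INF, 1),
    ),
    "dist_railway": (
        (0, 30, 10),
        (30, 90, 8),
        (90, 150, 6),
        (150, 200, 4),
        (200, INF, 1),
    ),
    "dist_farmland": (
        (0, 90, 10),
        (90, 150, 8),
        (150, 200, 6),
        (200, 300, 4),
        (300, 500, 2),
        (500, INF, 1),
    ),
    "dist_settlement": (
        (0, 200, BARRIER),
        (200, 300, 10),
        (300, 500, 8),
        (500, 1000, 6),
        (1000, 1500, 4),
        (1500, 2000, 3),
        (2000, 2500, 2),
        (2500, INF, 1),
    ),
    "dist_house": (
        (0, 30, BARRIER),
        (30, 90, 9),
        (90, 150, 7),
        (150, 300, 4),
        (300, 500, 2),
        (500, INF, 1),
    ),
}

# Bounded-below domains (distances, densities, slope start at 0).
_DOMAINS: dict[str, tuple[float, float]] = {
    "elevation": (-INF, INF),
    "slope": (0.0, INF),
    "ndvi": (-INF, INF),
    "human_density": (0.0, INF),
    "dist_river": (0.0, INF),
    "dist_highway": (0.0, INF),
    "dist_railway": (0.0, INF),
    "dist_farmland": (0.0, INF),
    "dist_settlement": (0.0, INF),
    "dist_house": (0.0, INF),
}

# Expert AHP weights (printed to 4 d.p.; the cost row sums to 1.0001 and is
# renormalized by WeightSet so weights always sum to exactly 1).
_SUITABILITY_WEIGHTS = {
    "elevation": 0.0548,
    "slope": 0.3891,
    "ndvi": 0.1375,
    "human_density": 0.1813,
    "dist_river": 0.0818,
    "dist_highway": 0.0964,
    "dist_railway": 0.0284,
    "dist_farmland": 0.0307,
}

_COST_WEIGHTS = {
    "elevation": 0.0322,
    "slope": 0.3875,
    "dist_highway": 0.1715,
    "dist_railway": 0.0477,
    "dist_farmland": 0.0495,
    "dist_settlement": 0.2095,
    "dist_house": 0.1022,
}


def default_suitability_weights() -> WeightSet:
    """The shipped expert weights for the eight habitat-suitability variables."""
    return WeightSet.from_weights(_SUITABILITY_WEIGHTS)


def default_cost_weights() -> WeightSet:
    """The shipped expert weights for the seven movement-cost variables."""
    return WeightSet.from_weights(_COST_WEIGHTS)


def load_rule_tables(config: str | Path | dict | None = None) -> dict[str, dict[str, RuleTable]]:
    """Load rule tables keyed ``variable -> {"suitability": ..., "cost": ...}``.

    With ``config=None`` the built-in default tables are returned.  A config
    may be a JSON/YAML file path or an already-parsed mapping of the same
    shape as :meth:`RuleTable.to_dict` entries under ``suitability`` / ``cost``
    keys.  All tables are validated on load; overlapping or gapped bins raise
    :class:`RuleTableError` naming the variable and interval.
    """
    if config is None:
        tables: dict[str, dict[str, RuleTable]] = {}
        for name, bins in _DEFAULT_SUITABILITY.items():
            tables.setdefault(name, {})["suitability"] = RuleTable(name, bins, _DOMAINS[name])
        for name, bins in _DEFAULT_COST.items():
            tables.setdefault(name, {})["cost"] = RuleTable(name, bins, _DOMAINS[name])
        return tables
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        try:
            obj = json.loads(text)
        except json.JSONDecodeError:
            import yaml

            obj = yaml.safe_load(text)
    else:
        obj = config
    tables = {}
    for kind in ("suitability", "cost"):
        for entry in obj.get(kind, []):
            t = RuleTable.from_dict(entry)
            tables.setdefault(t.variable_name, {})[kind] = t
    return tables
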