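"""Time strata, distance-scaled dispersal multipliers, land connectivity.

Dispersal probability between areas is down-weighted with distance: all
pairwise great-circle distances between per-stratum area midpoints are
divided by the single shortest recorded distance across all strata, and
the dispersal multiplier is the reciprocal of that relative distance, so
the nearest recorded pair of areas gets multiplier 1 and everything else
less.  Land connectivity (direct links and their transitive closure) is a
separate, purely configurational layer used to classify dispersal events
as terrestrial, ambiguous, or transoceanic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import GeoPoint, great_circle_km
from .regionalization import AreaSet


@dataclass(frozen=True)
class TimeStratum:
    """A geological time bin [end_ma, start_ma] with its temporal midpoint."""

    start_ma: float  # older bound
    end_ma: float    # younger bound

    def __post_init__(self) -> None:
        if self.end_ma < 0 or self.start_ma <= self.end_ma:
            raise ValueError(f"invalid stratum ({self.start_ma}, {self.end_ma})")

    @property
    def midpoint_ma(self) -> float:
        return 0.5 * (self.start_ma + self.end_ma)

    @property
    def label(self) -> str:
        return f"{self.end_ma:g}-{self.start_ma:g}Ma"

    def contains(self, age_ma: float) -> bool:
        return self.end_ma <= age_ma <= self.start_ma


def default_strata() -> list[TimeStratum]:
    """Seven 30-Myr bins back to 180 Ma plus a terminal 180–230 Ma bin."""
    bounds = [0.0, 30.0, 60.0, 90.0, 120.0, 150.0, 180.0, 230.0]
    return [TimeStratum(start_ma=b1, end_ma=b0) for b0, b1 in zip(bounds, bounds[1:])]


def stratum_for_age(strata, age_ma: float) -> TimeStratum:
    for s in strata:
        if s.contains(age_ma):
            return s
    raise ValueError(f"age {age_ma} Ma outside all strata")


@dataclass
class DispersalMultiplierMatrix:
    """Per-stratum relative distances and the derived dispersal multipliers.

    `relative_distance` has zero diagonal and a global off-diagonal minimum
    of exactly 1 (after scaling by the shortest recorded distance);
    `multiplier` is its elementwise reciprocal with unit diagonal, so every
    multiplier lies in (0, 1].
    """

    stratum: TimeStratum
    areas: tuple
    distance_km: np.ndarray
    relative_distance: np.ndarray

    @property
    def multiplier(self) -> np.ndarray:
        m = np.ones_like(self.relative_distance)
        off = ~np.eye(len(self.areas), dtype=bool)
        m[off] = 1.0 / self.relative_distance[off]
        return m


def build_distance_matrices(
    areas: AreaSet, strata, midpoints: dict | None = None
) -> list[DispersalMultiplierMatrix]:
    """Distance and multiplier matrices for each stratum.

    `midpoints` maps stratum label -> {area: GeoPoint}; by default the
    AreaSet's own per-stratum midpoints are used.  Scaling divides every
    matrix by the single global minimum off-diagonal distance, so the
    minimum relative distance across all strata is 1 exactly.
    """
    labels = list(areas.labels)
    n = len(labels)
    raw = []
    for st in strata:
        mids = midpoints[st.label] if midpoints is not None else areas.midpoints_for(st.label)
        missing = [a for a in labels if a not in mids]
        if missing:
            raise ValueError(f"stratum {st.label}: missing midpoints for {missing}")
        D = np.zeros((n, n))
        for i in range(n):
            for k in range(i + 1, n):
                d = great_circle_km(mids[labels[i]], mids[labels[k]])
                if d <= 0.0:
                    raise ValueError(
                        f"areas {labels[i]} and {labels[k]} share a midpoint in "
                        f"stratum {st.label}; zero distance breaks the scaling"
                    )
                D[i, k] = D[k, i] = d
        raw.append(D)
    off = ~np.eye(n, dtype=bool)
    global_min = min(float(D[off].min()) for D in raw)
    out = []
    for st, D in zip(strata, raw):
        out.append(
            DispersalMultiplierMatrix(
                stratum=st, areas=tuple(labels), distance_km=D,
                relative_distance=D / global_min,
            )
        )
    return out


def uniform_multipliers(areas: AreaSet, strata) -> list[DispersalMultiplierMatrix]:
    """All-ones multipliers (the unconstrained analysis)."""
    n = areas.n_areas
    out = []
    for st in strata:
        rel = np.ones((n, n))
        np.fill_diagonal(rel, 0.0)
        out.append(
            DispersalMultiplierMatrix(
                stratum=st, areas=tuple(areas.labels),
                distance_km=np.full((n, n), np.nan), relative_distance=rel,
            )
        )
    return out


@dataclass
class ConnectivityMatrix:
    """Boolean land connectivity between areas within one stratum."""

    stratum: TimeStratum
    areas: tuple
    connected: np.ndarray                     # direct land routes
    reachable: np.ndarray | None = None       # closure, filled by `reachability`

    def __post_init__(self) -> None:
        c = np.asarray(self.connected, dtype=bool)
        if not np.array_equal(c, c.T):
            raise ValueError("connectivity must be symmetric")
        np.fill_diagonal(c, True)
        self.connected = c

    def index(self, label: str) -> int:
        try:
            return self.areas.index(label)
        except ValueError:
            raise KeyError(f"unknown area label {label!r}") from None


def reachability(conn: ConnectivityMatrix) -> ConnectivityMatrix:
    """Fill in the transitive closure of the direct-connection graph.

    Floyd–Warshall on booleans: reachable[i, j] is true iff a land route
    exists via any chain of intermediate areas.
    """
    n = len(conn.areas)
    reach = conn.connected.copy()
    for k in range(n):
        reach |= np.outer(reach[:, k], reach[k, :])
    return ConnectivityMatrix(
        stratum=conn.stratum, areas=conn.areas, connected=conn.connected,
        reachable=reach,
    )


def connectivity_from_yaml_dict(data: dict, strata) -> dict:
    """Build {stratum label: ConnectivityMatrix} from a YAML-style mapping.

    Expected layout: {"areas": [...], "strata": {label: [[area, area], ...]}}
    listing the directly connected pairs per stratum.
    """
    areas = tuple(data["areas"])
    idx = {a: i for i, a in enumerate(areas)}
    out = {}
    for st in strata:
        pairs = data["strata"].get(st.label, [])
        mat = np.eye(len(areas), dtype=bool)
        for a, b in pairs:
            mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = True
        out[st.label] = reachability(
            ConnectivityMatrix(stratum=st, areas=areas, connected=mat)
        )
    return out


def write_multiplier_file(matrices, path) -> None:
    """Dispersal-multiplier file: one whitespace matrix block per stratum,
    each block terminated by a line "END", oldest stratum last."""
    with open(path, "w") as fh:
        for m in matrices:
            mult = m.multiplier
            for row in mult:
                fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")
            fh.write("END\n")


def write_time_periods_file(strata, path) -> None:
    """Time-periods file: one stratum upper (older) bound per line."""
    with open(path, "w") as fh:
        for st in strata:
            fh.write(f"{st.start_ma:g}\n")


def read_multiplier_file(path, strata, areas: AreaSet) -> list[DispersalMultiplierMatrix]:
    blocks, current = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line == "END":
                blocks.append(np.array(current, dtype=float))
                current = []
            else:
                current.append([float(x) for x in line.split()])
    if len(blocks) != len(strata):
        raise ValueError(f"expected {len(strata)} matrix blocks, found {len(blocks)}")
    out = []
    for st, mult in zip(strata, blocks):
        rel = np.zeros_like(mult)
        off = ~np.eye(mult.shape[0], dtype=bool)
        rel[off] = 1.0 / mult[off]
        out.append(
            DispersalMultiplierMatrix(
                stratum=st, areas=tuple(areas.labels),
                distance_km=np.full_like(mult, np.nan), relative_distance=rel,
            )
        )
    return out
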