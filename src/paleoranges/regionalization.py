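"""Bioregion delineation by k-means on the unit sphere, with PVE selection.

Occurrence palaeocoordinates are clustered per epoch with k-means; the
number of clusters is chosen as the smallest k whose proportion of variance
explained, PVE = BCSS/TSS, reaches a cutoff (default 98%).  Clustering is
done on 3D unit-sphere Cartesian coordinates so the result is free of
date-line artifacts.  Clusters are then linked across epochs into a named
AreaSet, and each taxon is coded into the set of areas its occurrences
fall nearest to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .geometry import GeoPoint, cartesian_to_sphere, points_to_matrix, sphere_to_cartesian
from .occurrences import OccurrenceTable, assign_epoch

#: area labels of a classic 10-area global scheme for Mesozoic–Cenozoic tetrapods
DEFAULT_AREA_LABELS = ("AUS", "EAS", "ENA", "EUR", "MNA", "MSA", "NAF", "NSA", "SSA", "WAS")


@dataclass
class ClusteringResult:
    """One k-means solution with its variance decomposition."""

    k: int
    assignments: np.ndarray          # record -> cluster index
    centroids: np.ndarray            # (k, 3) cluster means (not re-normalized)
    bcss: float
    tss: float

    @property
    def pve(self) -> float:
        """Proportion of variance explained, BCSS / TSS (0 for a single point set)."""
        return 0.0 if self.tss == 0 else self.bcss / self.tss

    def centroid_points(self) -> list:
        return [cartesian_to_sphere(c) for c in self.centroids]


def kmeans_pve(points, k: int, restarts: int = 100, seed: int | None = 0) -> ClusteringResult:
    """Best-of-`restarts` k-means on unit-sphere coordinates.

    Lloyd iterations run to convergence from k-means++ starts; the solution
    with maximal BCSS (equivalently minimal within-cluster SS) is kept.
    """
    X = points_to_matrix(points)
    n_distinct = len(np.unique(X.round(12), axis=0))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds number of distinct points ({n_distinct})")
    if k < 1:
        raise ValueError("k must be >= 1")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed, tol=1e-12)
    labels = km.fit_predict(X)
    tss = float(((X - X.mean(axis=0)) ** 2).sum())
    wcss = float(km.inertia_)
    bcss = max(tss - wcss, 0.0)
    # k-means relocates empty clusters, so exactly k non-empty clusters result
    assert len(np.unique(labels)) == k
    return ClusteringResult(k=k, assignments=labels, centroids=km.cluster_centers_,
                            bcss=bcss, tss=tss)


@dataclass
class KSelection:
    """PVE-vs-k table and the selected cluster count."""

    k: int
    pve_by_k: dict
    cutoff: float
    reached_cutoff: bool

    def as_series(self) -> pd.Series:
        return pd.Series(self.pve_by_k, name="pve")


def select_k(points, kmin: int = 5, kmax: int = 15, cutoff: float = 0.98,
             restarts: int = 100, seed: int | None = 0) -> KSelection:
    """Smallest k in [kmin, kmax] whose best-of-restarts PVE reaches `cutoff`.

    The full PVE table is returned so that judgement calls (several viable
    k, consistency across epochs) remain possible; when no k reaches the
    cutoff the largest k is returned with `reached_cutoff=False`.
    """
    if kmin > kmax:
        raise ValueError("kmin must be <= kmax")
    X = points_to_matrix(points)
    n_distinct = len(np.unique(X.round(12), axis=0))
    table: dict[int, float] = {}
    chosen = None
    for k in range(kmin, kmax + 1):
        if k > n_distinct:
            break
        table[k] = kmeans_pve(points, k, restarts=restarts, seed=seed).pve
        if chosen is None and table[k] >= cutoff:
            chosen = k
    if not table:
        raise ValueError("no feasible k: fewer distinct points than kmin")
    if chosen is None:
        return KSelection(k=max(table), pve_by_k=table, cutoff=cutoff, reached_cutoff=False)
    return KSelection(k=chosen, pve_by_k=table, cutoff=cutoff, reached_cutoff=True)


def write_pve_table(selections: dict, path) -> None:
    """PVE-by-k table, one row per epoch, as TSV (percentages)."""
    rows = {}
    for epoch, sel in selections.items():
        rows[epoch] = {k: 100.0 * v for k, v in sel.pve_by_k.items()}
    pd.DataFrame(rows).T.to_csv(path, sep="\t", float_format="%.2f")


@dataclass
class AreaSet:
    """Named geographic areas with per-stratum midpoints.

    `midpoints` maps a stratum key (epoch label or time-stratum label) to a
    dict of area label -> GeoPoint.  Taxa/nodes are assigned to areas by
    the nearest-midpoint rule (great-circle, ties to the lowest area index).
    """

    labels: tuple
    midpoints: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("area labels must be unique")

    @property
    def n_areas(self) -> int:
        return len(self.labels)

    def midpoints_for(self, stratum_key) -> dict:
        if stratum_key in self.midpoints:
            return self.midpoints[stratum_key]
        if len(self.midpoints) == 1:
            return next(iter(self.midpoints.values()))
        raise KeyError(f"no midpoints defined for stratum {stratum_key!r}")

    def nearest_area(self, point: GeoPoint, stratum_key) -> tuple[str, float, bool]:
        """(label, central angle to midpoint, tie flag) of the nearest area."""
        mids = self.midpoints_for(stratum_key)
        v = sphere_to_cartesian(point)
        best_label, best_cos, tie = None, -2.0, False
        for label in self.labels:
            if label not in mids:
                continue
            c = float(np.dot(v, sphere_to_cartesian(mids[label])))
            if c > best_cos + 1e-12:
                best_label, best_cos, tie = label, c, False
            elif abs(c - best_cos) <= 1e-12:
                tie = True
        if best_label is None:
            raise KeyError(f"stratum {stratum_key!r} has no area midpoints")
        ang = float(np.degrees(np.arccos(np.clip(best_cos, -1.0, 1.0))))
        return best_label, ang, tie

    def to_yaml_dict(self) -> dict:
        return {
            "areas": list(self.labels),
            "midpoints": {
                str(k): {a: [p.lat, p.lon] for a, p in mids.items()}
                for k, mids in self.midpoints.items()
            },
        }

    @classmethod
    def from_yaml_dict(cls, data: dict) -> "AreaSet":
        mids = {
            k: {a: GeoPoint(lat, lon) for a, (lat, lon) in d.items()}
            for k, d in data["midpoints"].items()
        }
        return cls(labels=tuple(data["areas"]), midpoints=mids)


def assemble_areas(per_epoch: dict, override: dict | None = None,
                   labels=None) -> AreaSet:
    """Link clusters across epochs into named areas by greedy centroid linkage.

    The first epoch's clusters seed the area list; each later epoch's
    clusters are matched greedily to the nearest existing area centroid
    (closest pair first), and unmatched clusters open new areas.  An
    `override` mapping {epoch: {cluster_index: label}} wins where given.
    """
    override = override or {}
    epochs = list(per_epoch)
    for ep, mapping in override.items():
        if ep not in per_epoch:
            raise ValueError(f"override references unknown epoch {ep!r}")
        for ci in mapping:
            if not 0 <= ci < per_epoch[ep].k:
                raise ValueError(f"override references unknown cluster {ci} in {ep!r}")

    def new_label(i: int) -> str:
        if labels is not None:
            return labels[i]
        return f"A{i + 1:02d}"

    area_centroids: list[np.ndarray] = []
    area_labels: list[str] = []
    midpoints: dict = {ep: {} for ep in epochs}
    for ep in epochs:
        res = per_epoch[ep]
        cents = np.asarray(res.centroids, dtype=float)
        cents = cents / np.linalg.norm(cents, axis=1, keepdims=True)
        assigned: dict[int, str] = {}
        for ci, label in override.get(ep, {}).items():
            assigned[ci] = label
            if label not in area_labels:
                area_labels.append(label)
                area_centroids.append(cents[ci])
        free_clusters = [c for c in range(res.k) if c not in assigned]
        if area_centroids and free_clusters:
            taken_areas: set[str] = set()
            pairs = []
            for ci in free_clusters:
                for ai, ac in enumerate(area_centroids):
                    pairs.append((-float(np.dot(cents[ci], ac)), ci, ai))
            for _, ci, ai in sorted(pairs):
                if ci in assigned or area_labels[ai] in taken_areas:
                    continue
                assigned[ci] = area_labels[ai]
                taken_areas.add(area_labels[ai])
        for ci in range(res.k):
            if ci not in assigned:
                lb = new_label(len(area_labels))
                area_labels.append(lb)
                area_centroids.append(cents[ci])
                assigned[ci] = lb
        for ci, lb in assigned.items():
            midpoints[ep][lb] = cartesian_to_sphere(cents[ci])
    return AreaSet(labels=tuple(area_labels), midpoints=midpoints)


def code_taxon_ranges(occs: OccurrenceTable, areas: AreaSet) -> pd.DataFrame:
    """Binary taxon x area presence matrix from nearest-midpoint coding.

    Each occurrence is placed in its epoch stratum and assigned to the
    nearest area midpoint; a taxon's range is the union over its usable
    occurrences.  A taxon with no usable occurrence raises.
    """
    presence = pd.DataFrame(
        0, index=occs.taxa, columns=list(areas.labels), dtype=int
    )
    usable = {t: 0 for t in occs.taxa}
    single_key = next(iter(areas.midpoints)) if len(areas.midpoints) == 1 else None
    for row in occs.df.itertuples():
        if single_key is not None:
            key = single_key
        else:
            bin_ = assign_epoch(row.min_ma, row.max_ma)
            key = (bin_.label if bin_ is not None
                   and bin_.label in areas.midpoints else None)
        if key is None:
            continue
        label, _, _ = areas.nearest_area(GeoPoint(row.paleolat, row.paleolng), key)
        presence.loc[row.taxon, label] = 1
        usable[row.taxon] += 1
    empty = [t for t, n in usable.items() if n == 0]
    if empty:
        raise ValueError(f"taxa with zero usable occurrences: {empty}")
    return presence


def write_geography_file(presence: pd.DataFrame, path) -> None:
    """Write ranges in the classic biogeography geography-file layout.

    Header: "n_taxa n_areas (A B C ...)"; then one line per taxon with its
    binary presence string.
    """
    with open(path, "w") as fh:
        areas = " ".join(presence.columns)
        fh.write(f"{len(presence)}\t{presence.shape[1]}\t({areas})\n")
        for taxon, row in presence.iterrows():
            bits = "".join(str(int(v)) for v in row.values)
            fh.write(f"{taxon}\t{bits}\n")


def read_geography_file(path) -> pd.DataFrame:
    """Read the geography-file layout written by `write_geography_file`."""
    with open(path) as fh:
        header = fh.readline().split("\t")
        n_taxa, n_areas = int(header[0]), int(header[1])
        labels = header[2].strip().strip("()").split()
        if len(labels) != n_areas:
            labels = [f"A{i+1:02d}" for i in range(n_areas)]
        rows = {}
        for line in fh:
            if not line.strip():
                continue
            taxon, bits = line.rsplit(None, 1)
            rows[taxon.strip()] = [int(ch) for ch in bits.strip()]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=labels)
    if len(df) != n_taxa:
        raise ValueError("geography file row count does not match header")
    return df
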