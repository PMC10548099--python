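"""Synthetic datasets with the statistical structure the pipeline assumes.

Three generators, all pure functions of (config, seed):

* a constant-rate birth–death tree conditioned on its extant tip count,
  with optional fossil tips sampled at rate psi along extinct lineages;
* a forward range-evolution history on that tree (Gillespie anagenesis
  along branches, cladogenetic daughter draws at nodes) under known
  (d, e, j), optionally suppressing non-land-connected dispersal inside a
  designated saltwater-intolerant clade;
* occurrence clouds: von Mises–Fisher scatter on the sphere around the
  centroid(s) of each tip's true areas, with ages drawn in the tip's
  stratum.

The truth (node ranges, event list with terrestrial/transoceanic labels)
is retained so downstream estimates can be scored against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .geometry import GeoPoint, sample_vmf, sphere_to_cartesian
from .occurrences import COLUMNS, OccurrenceTable
from .paleogeography import TimeStratum, stratum_for_age
from .regionalization import AreaSet
from .statespace import RangeModelParams, RangeStateSpace, clado_table
from .trees import IndexedTree, enforce_min_branch_length

#: default synthetic area scheme: four well-separated continental centroids
DEFAULT_CENTROIDS = {
    "A": (40.0, -100.0),   # mid-northern landmass, west
    "B": (45.0, 15.0),     # mid-northern landmass, east
    "C": (-15.0, -60.0),   # southern landmass, west
    "D": (-25.0, 135.0),   # southern landmass, east
}

#: richer six-area scheme used for study-scale estimation experiments,
#: where per-lineage loss events must be numerous enough to inform e
SIX_AREA_CENTROIDS = {
    **DEFAULT_CENTROIDS,
    "E": (10.0, 70.0),     # equatorial landmass, east
    "F": (-55.0, -20.0),   # high-southern landmass
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition defaults for the synthetic generator.

    Tip counts, time span, rates and occurrence density mirror a
    continental-scale amniote fossil dataset: of order a hundred taxa over
    ~200 Myr, a handful of occurrences per taxon, and moderate coordinate
    scatter around area centroids.
    """

    n_tips: int = 100
    birth_rate: float = 0.1       # speciations / lineage / Myr
    death_rate: float = 0.05      # extinctions / lineage / Myr
    root_age: float = 200.0       # Ma
    psi: float = 0.05             # fossil-tip sampling rate / lineage / Myr
    true_params: RangeModelParams = field(
        default_factory=lambda: RangeModelParams(d=0.02, e=0.01, j=0.0))
    area_centroids: dict = field(default_factory=lambda: dict(DEFAULT_CENTROIDS))
    occ_per_taxon_mean: float = 2.5   # Poisson mean; +1 guarantees an occurrence
    coord_noise_concentration: float = 50.0  # von Mises–Fisher kappa
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 3:
            raise ValueError("n_tips must be >= 3")
        if not self.birth_rate > self.death_rate >= 0:
            raise ValueError("need birth_rate > death_rate >= 0")
        if self.coord_noise_concentration <= 0:
            raise ValueError("vMF concentration must be > 0")
        if self.root_age <= 0 or self.psi < 0 or self.occ_per_taxon_mean < 0:
            raise ValueError("root_age must be > 0; psi, occ mean >= 0")

    @property
    def areas(self) -> tuple:
        return tuple(self.area_centroids)

    def area_set(self) -> AreaSet:
        mids = {a: GeoPoint(*ll) for a, ll in self.area_centroids.items()}
        return AreaSet(labels=self.areas, midpoints={"all": mids})


# ---------------------------------------------------------------------------
# birth–death tree
# ---------------------------------------------------------------------------

class _SimNode:
    __slots__ = ("start", "end", "children", "extant", "label")

    def __init__(self, start: float):
        self.start = start            # forward time of origin
        self.end: float | None = None
        self.children: list["_SimNode"] = []
        self.extant = False
        self.label: str | None = None


def simulate_tree(config: SimulationConfig, seed: int | None = None,
                  max_tries: int = 1000) -> IndexedTree:
    """Birth–death tree conditioned on exactly `n_tips` extant terminals.

    Forward Gillespie from the root bifurcation; the simulation stops at a
    uniform point of the first holding interval during which the extant
    lineage count equals `n_tips`, and times are rescaled so the root sits
    at `root_age` Ma.  With psi > 0, fossil samples are drawn along
    branches at rate psi and otherwise-unsampled extinct subtrees are
    truncated at their youngest sample, yielding non-contemporaneous tips.
    Replicates going extinct (or exceeding 4x n_tips lineages without
    hitting the target) are rejected and redrawn, up to `max_tries`.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    for _ in range(max_tries):
        root = _SimNode(0.0)
        left, right = _SimNode(0.0), _SimNode(0.0)
        root.children = [left, right]
        root.end = 0.0
        active = [left, right]
        t = 0.0
        ok = False
        while active:
            n_act = len(active)
            if n_act == config.n_tips:
                rate = n_act * (config.birth_rate + config.death_rate)
                dt_hold = rng.exponential(1.0 / rate)
                t += rng.uniform(0.0, dt_hold)
                ok = True
                break
            if n_act > 4 * config.n_tips:
                break
            rate = n_act * (config.birth_rate + config.death_rate)
            t += rng.exponential(1.0 / rate)
            node = active[rng.integers(n_act)]
            if rng.uniform() < config.birth_rate / (config.birth_rate + config.death_rate):
                node.end = t
                node.children = [_SimNode(t), _SimNode(t)]
                active.remove(node)
                active.extend(node.children)
            else:
                node.end = t
                active.remove(node)
        if not ok:
            continue
        for node in active:
            node.end = t
            node.extant = True
        scale = config.root_age / t
        _rescale(root, scale)
        if config.psi > 0:
            _truncate_to_fossils(root, config.psi, rng)
        if not _prune_unsampled(root):
            continue
        _label_tips(root)
        newick = _to_newick(root) + ";"
        # pruning extinct sides can leave the surviving MRCA younger than the
        # original root; normalize so the returned tree's root sits at root_age
        dtree = dendropy.Tree.get(data=newick, schema="newick")
        dtree.suppress_unifurcations()
        dtree.seed_node.edge.length = None  # drop the stem above the MRCA
        max_depth = max(lf.distance_from_root() for lf in dtree.leaf_node_iter())
        if max_depth <= 0:
            continue
        factor = config.root_age / max_depth
        for edge in dtree.preorder_edge_iter():
            if edge.length:
                edge.length *= factor
        newick = dtree.as_string(schema="newick", suppress_rooting=True)
        newick = enforce_min_branch_length(newick, 0.1)
        tree = IndexedTree.from_newick(newick)
        if tree.n_tips >= config.n_tips:
            return tree
    raise RuntimeError(f"tree simulation failed after {max_tries} tries")


def _rescale(node: _SimNode, scale: float) -> None:
    node.start *= scale
    if node.end is not None:
        node.end *= scale
    for c in node.children:
        _rescale(c, scale)


def _truncate_to_fossils(node: _SimNode, psi: float, rng) -> None:
    """Truncate unsampled extinct terminal branches at their youngest fossil."""
    for c in node.children:
        _truncate_to_fossils(c, psi, rng)
    if not node.children and not node.extant:
        span = node.end - node.start
        k = rng.poisson(psi * span)
        if k > 0:
            node.end = node.start + float(np.max(rng.uniform(0.0, span, size=k)))
            node.extant = False
            node.label = "sampled"
        else:
            node.label = "unsampled"


def _prune_unsampled(node: _SimNode) -> bool:
    """Drop extinct-and-unsampled subtrees; returns False if nothing survives."""
    if not node.children:
        return node.extant or node.label == "sampled"
    kept = [c for c in node.children if _prune_unsampled(c)]
    if not kept:
        return False
    # a single surviving child leaves a unifurcation; dendropy merges the
    # two edge lengths when the Newick is re-read, preserving path lengths
    node.children = kept
    return True


def _label_tips(root: _SimNode) -> None:
    counter = {"t": 0, "f": 0}

    def walk(node: _SimNode) -> None:
        if not node.children:
            key = "t" if node.extant else "f"
            counter[key] += 1
            node.label = f"{key}{counter[key]}"
        for c in node.children:
            walk(c)

    walk(root)


def _to_newick(node: _SimNode) -> str:
    length = (node.end - node.start) if node.end is not None else 0.0
    if not node.children:
        return f"{node.label}:{length:.6f}"
    inner = ",".join(_to_newick(c) for c in node.children)
    return f"({inner}):{length:.6f}"


# ---------------------------------------------------------------------------
# forward range history
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrueDispersalEvent:
    branch: int
    from_mask: int
    to_area: str
    time_ma: float
    founder: bool
    transoceanic: bool | None = None   # truth label when connectivity is given


@dataclass
class TrueHistory:
    """A forward-simulated range history with full event bookkeeping."""

    tree: IndexedTree
    space: RangeStateSpace
    node_states: np.ndarray            # state index at each node (pre-cladogenesis)
    events: list
    root_state: int

    def tip_ranges(self) -> dict:
        return {
            label: self.space.labels_of_mask(int(self.space.state_masks[self.node_states[i]]))
            for i, label in enumerate(self.tree.tip_labels)
        }

    def presence_matrix(self) -> pd.DataFrame:
        ranges = self.tip_ranges()
        return pd.DataFrame(
            [[1 if a in ranges[t] else 0 for a in self.space.areas]
             for t in self.tree.tip_labels],
            index=self.tree.tip_labels, columns=list(self.space.areas), dtype=int,
        )

    def n_founder_events(self) -> int:
        return sum(1 for ev in self.events if ev.founder)

    def truth_dict(self) -> dict:
        return {
            "root_state": self.space.bitstring(self.root_state),
            "node_states": {int(n): self.space.bitstring(int(s))
                            for n, s in enumerate(self.node_states)},
            "events": [
                {"branch": ev.branch, "from": self.space.labels_of_mask(ev.from_mask),
                 "to": ev.to_area, "time_ma": ev.time_ma, "founder": ev.founder,
                 "transoceanic": ev.transoceanic}
                for ev in self.events
            ],
        }

    def write_truth_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.truth_dict(), fh, indent=1)


class RangeHistorySimulator:
    """Reusable forward simulator of the range-evolution process.

    Building the simulator once and calling `simulate(seed)` repeatedly
    amortizes the per-tree setup, which matters for the large replicate
    counts used in forward/likelihood consistency checks.

    Parameters mirror the likelihood side: `multipliers` scales dispersal
    rates per stratum; `connectivity` (dict stratum label -> matrix with
    closure) provides truth labels for events; `intolerant_node` marks the
    crown of a clade whose non-land-connected gains and jumps are
    multiplied by `ocean_suppression`.
    """

    def __init__(self, tree: IndexedTree, space: RangeStateSpace,
                 params: RangeModelParams, model: str = "DEC",
                 multipliers=None, connectivity=None,
                 intolerant_node: int | None = None,
                 ocean_suppression: float = 1.0,
                 condition_branches: bool = False):
        self.tree = tree
        self.space = space
        self.params = params
        self.model = model
        self.clado = clado_table(model, params.j, space)
        self.connectivity = connectivity
        self.intolerant = set()
        if intolerant_node is not None:
            self.intolerant = set(tree.subtree_nodes(intolerant_node))
        self.ocean_suppression = ocean_suppression
        # With condition_branches=False (the exact forward model) a replicate
        # with any null-range branch endpoint is rejected wholesale: correct,
        # but hopeless on long many-tip trees where the expected number of
        # global-extirpation events is >> 1.  With True, each branch is
        # redrawn until its endpoint is non-null (a per-branch conditioning
        # that slightly reweights loss-heavy paths but scales to large trees).
        self.condition_branches = condition_branches
        if multipliers is None:
            self.strata = [TimeStratum(start_ma=max(tree.age) * 2 + 1, end_ma=0.0)]
            n = space.n_areas
            self.mults = [np.ones((n, n))]
        else:
            mats = sorted(multipliers, key=lambda m: m.stratum.end_ma)
            self.strata = [m.stratum for m in mats]
            self.mults = [m.multiplier for m in mats]
        self._clado_by_anc = {}
        for si in range(1, space.n_states):
            sel = self.clado.anc == si
            self._clado_by_anc[si] = (self.clado.left[sel], self.clado.right[sel],
                                      self.clado.prob[sel], self.clado.is_jump[sel])

    def _conn_for_age(self, age: float):
        """Connectivity matrix whose stratum contains `age` (oldest as fallback)."""
        oldest = None
        for cm in self.connectivity.values():
            if cm.stratum.contains(age):
                return cm
            if oldest is None or cm.stratum.start_ma > oldest.stratum.start_ma:
                oldest = cm
        return oldest

    def _suppressed(self, node: int, src_area: int, dst_area: int, age: float) -> float:
        if node not in self.intolerant or self.connectivity is None:
            return 1.0
        conn = self._conn_for_age(age)
        return 1.0 if conn.connected[src_area, dst_area] else self.ocean_suppression

    def _stratum_at(self, age: float):
        for k, st in enumerate(self.strata):
            if st.contains(age):
                return k
        # ages beyond the oldest stratum use the oldest matrix
        return len(self.strata) - 1

    def _evolve_branch(self, node: int, mask: int, t_top: float, t_bot: float,
                       rng, events: list) -> int:
        d, e = self.params.d, self.params.e
        n = self.space.n_areas
        t = t_top
        while t > t_bot + 1e-12:
            k = self._stratum_at(t - 1e-12)
            st = self.strata[k]
            seg_end = max(t_bot, st.end_ma)
            if mask == 0:
                return 0
            members = [a for a in range(n) if mask >> a & 1]
            gains = {}
            if len(members) < self.space.max_range_size:
                for a in range(n):
                    if mask >> a & 1:
                        continue
                    rate = d * sum(self.mults[k][i, a]
                                   * self._suppressed(node, i, a, t)
                                   for i in members)
                    if rate > 0:
                        gains[a] = rate
            loss_rate = e * len(members)
            total = sum(gains.values()) + loss_rate
            if total <= 0:
                t = seg_end
                continue
            dt = rng.exponential(1.0 / total)
            if t - dt < seg_end:
                t = seg_end
                continue
            t -= dt
            u = rng.uniform() * total
            acc = 0.0
            chosen = None
            for a, rate in gains.items():
                acc += rate
                if u < acc:
                    chosen = ("gain", a)
                    break
            if chosen is None:
                lost = members[rng.integers(len(members))]
                chosen = ("loss", lost)
            kind, area = chosen
            if kind == "gain":
                events.append(self._make_event(node, mask, area, t, False, rng))
                mask |= 1 << area
            else:
                mask &= ~(1 << area)
        return mask

    def _make_event(self, branch: int, from_mask: int, area: int, time_ma: float,
                    founder: bool, rng) -> TrueDispersalEvent:
        trans = None
        if self.connectivity is not None:
            conn = self._conn_for_age(time_ma)
            srcs = [i for i in range(self.space.n_areas) if from_mask >> i & 1]
            if any(conn.connected[i, area] for i in srcs):
                trans = False
            elif any(conn.reachable[i, area] for i in srcs):
                # a long terrestrial detour existed; the lineage took either
                trans = bool(rng.uniform() < 0.5)
            else:
                trans = True
        return TrueDispersalEvent(
            branch=branch, from_mask=from_mask, to_area=self.space.areas[area],
            time_ma=time_ma, founder=founder, transoceanic=trans,
        )

    def simulate(self, seed: int, max_tries: int = 200) -> TrueHistory:
        """One forward replicate; replicates with a null-range tip are redrawn."""
        tree = self.tree
        for attempt in range(max_tries):
            rng = np.random.default_rng((seed, attempt))
            events: list[TrueDispersalEvent] = []
            node_states = np.zeros(tree.n_nodes, dtype=int)
            root_state = int(rng.integers(1, self.space.n_states))
            node_states[tree.root] = root_state
            ok = True
            for node in reversed(tree.postorder):  # preorder
                if not tree.children[node]:
                    continue
                si = int(node_states[node])
                if si == 0:
                    ok = False
                    break
                left, right, prob, is_jump = self._clado_by_anc[si]
                prob = self._reweight_jumps(node, si, left, right, prob, is_jump)
                ev = rng.choice(len(prob), p=prob)
                l_state, r_state = int(left[ev]), int(right[ev])
                if is_jump[ev]:
                    anc_mask = int(self.space.state_masks[si])
                    for child_state, child in ((l_state, tree.children[node][0]),
                                               (r_state, tree.children[node][1])):
                        child_mask = int(self.space.state_masks[child_state])
                        new_bit = child_mask & ~anc_mask
                        if new_bit:
                            area = int(new_bit).bit_length() - 1
                            events.append(self._make_event(
                                child, anc_mask, area, float(tree.age[node]),
                                True, rng))
                for child, child_state in zip(tree.children[node], (l_state, r_state)):
                    mask = int(self.space.state_masks[child_state])
                    end_mask = 0
                    branch_tries = 50 if self.condition_branches else 1
                    for _ in range(branch_tries):
                        branch_events: list[TrueDispersalEvent] = []
                        end_mask = self._evolve_branch(
                            child, mask, float(tree.age[node]),
                            float(tree.age[child]), rng, branch_events)
                        if end_mask != 0:
                            events.extend(branch_events)
                            break
                    if end_mask == 0:
                        ok = False
                        break
                    node_states[child] = self.space.index_of[end_mask]
                if not ok:
                    break
            if ok and np.all(node_states[: tree.n_tips] > 0):
                return TrueHistory(tree=tree, space=self.space,
                                   node_states=node_states, events=events,
                                   root_state=root_state)
        raise RuntimeError(f"range history rejected {max_tries} times "
                           "(null-range tips); lower e or shorten the tree")

    def _reweight_jumps(self, node, si, left, right, prob, is_jump) -> np.ndarray:
        if (node not in self.intolerant or self.connectivity is None
                or not is_jump.any() or self.ocean_suppression == 1.0):
            return prob
        conn = self._conn_for_age(float(self.tree.age[node]))
        anc_mask = int(self.space.state_masks[si])
        srcs = [i for i in range(self.space.n_areas) if anc_mask >> i & 1]
        w = prob.copy()
        for kk in np.where(is_jump)[0]:
            lm = int(self.space.state_masks[left[kk]])
            rm = int(self.space.state_masks[right[kk]])
            new_bit = (lm | rm) & ~anc_mask
            area = int(new_bit).bit_length() - 1
            if not any(conn.connected[i, area] for i in srcs):
                w[kk] *= self.ocean_suppression
        total = w.sum()
        if total <= 0:
            return prob
        return w / total


def simulate_range_history(tree: IndexedTree, space: RangeStateSpace,
                           params: RangeModelParams, model: str = "DEC",
                           multipliers=None, seed: int = 0, **kwargs) -> TrueHistory:
    """One-shot wrapper around RangeHistorySimulator."""
    sim = RangeHistorySimulator(tree, space, params, model=model,
                                multipliers=multipliers, **kwargs)
    return sim.simulate(seed)


# ---------------------------------------------------------------------------
# occurrence clouds
# ---------------------------------------------------------------------------

def simulate_occurrences(history: TrueHistory, config: SimulationConfig,
                         strata=None, seed: int | None = None) -> OccurrenceTable:
    """Occurrence points scattered around each tip's true area centroids.

    Per tip, 1 + Poisson(occ_per_taxon_mean) points: each picks one of the
    tip's areas uniformly and draws a von Mises–Fisher deviate around that
    area's centroid; ages are uniform in the stratum containing the tip's
    age.  Palaeo- and modern coordinates coincide (no plate motion).
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    tree = history.tree
    centroids = {a: sphere_to_cartesian(GeoPoint(*ll))
                 for a, ll in config.area_centroids.items()}
    rows = []
    ranges = history.tip_ranges()
    for i, label in enumerate(tree.tip_labels):
        tip_age = float(tree.age[i])
        if strata is not None:
            st = stratum_for_age(strata, tip_age)
            age_lo, age_hi = st.end_ma, st.start_ma
        else:
            age_lo, age_hi = max(tip_age - 2.0, 0.0), tip_age + 2.0
        areas = list(ranges[label])
        n_occ = 1 + int(rng.poisson(config.occ_per_taxon_mean))
        for _ in range(n_occ):
            area = areas[int(rng.integers(len(areas)))]
            vec = sample_vmf(centroids[area], config.coord_noise_concentration,
                             1, rng)[0]
            from .geometry import cartesian_to_sphere
            p = cartesian_to_sphere(vec)
            age = float(rng.uniform(age_lo, age_hi))
            rows.append({
                "taxon": label, "lat": p.lat, "lng": p.lon,
                "paleolat": p.lat, "paleolng": p.lon,
                "min_ma": round(age, 4), "max_ma": round(age, 4),
                "habitat": "nonmarine",
            })
    df = pd.DataFrame(rows, columns=COLUMNS)
    return OccurrenceTable(df, provenance=f"synthetic seed={config.seed}")


def simulate_dataset(config: SimulationConfig, model: str = "DEC",
                     multipliers=None, strata=None, **sim_kwargs):
    """Tree + range history + occurrences in one call.

    Returns (tree, history, occurrences).  Sub-seeds are derived from
    config.seed so the whole bundle is reproducible from one integer.
    """
    space = RangeStateSpace(config.areas)
    tree = simulate_tree(config, seed=config.seed)
    sim_kwargs.setdefault("condition_branches", True)
    history = simulate_range_history(tree, space, config.true_params,
                                     model=model, multipliers=multipliers,
                                     seed=config.seed + 10_000, **sim_kwargs)
    occs = simulate_occurrences(history, config, strata=strata,
                                seed=config.seed + 20_000)
    return tree, history, occs
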