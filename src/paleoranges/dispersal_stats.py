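"""Dispersal-event extraction, classification, and the skew test.

From fitted ancestral range estimates, every area gained along a branch
(beyond the cladogenetic inheritance at the parent node) is a dispersal
event; founder (jump) events are read off the most probable cladogenetic
outcome.  Events are classified against per-stratum land connectivity as
terrestrial (direct land link), ambiguous (land route only via
intermediate areas — a longer hypothetical terrestrial path), or
transoceanic (no land route).  A Pearson χ² test with expected counts
apportioned by clade node counts then asks whether transoceanic dispersal
is skewed between a saltwater-tolerant and a saltwater-intolerant clade.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .paleogeography import ConnectivityMatrix, stratum_for_age
from .range_models import NodeRangeEstimate, RangeFitResults
from .statespace import clado_table
from .trees import IndexedTree

CLASSIFICATIONS = ("terrestrial", "ambiguous", "transoceanic")


@dataclass(frozen=True)
class DispersalEvent:
    """A single area gain on a branch of the tree."""

    branch: int                 # child-node index identifying the branch
    from_areas: tuple           # source range (labels) at the moment of the gain
    to_area: str
    time_ma: float              # branch midpoint (anagenetic) or node age (founder)
    founder: bool = False
    classification: str | None = None

    def __post_init__(self) -> None:
        if self.to_area in self.from_areas:
            raise ValueError("to_area must lie outside from_areas")


def extract_dispersals(tree: IndexedTree, fit: RangeFitResults,
                       estimates: NodeRangeEstimate | None = None) -> list:
    """Dispersal events implied by MAP ancestral ranges.

    For each branch, the cladogenetic outcome at the parent is resolved to
    its most probable daughter pair consistent with the branch-top process
    (MAP over the clado distribution times the branch transition towards
    the child's MAP/tip state).  Areas in the child state absent from the
    inherited daughter range each yield one anagenetic event timed at the
    branch midpoint; a jump outcome yields one founder event at the parent
    node's age.
    """
    mdl = fit.model_obj
    space = mdl.space
    if estimates is None:
        estimates = fit.ancestral_marginals()
    j = fit.params.j if mdl.with_jump else 0.0
    clado = clado_table(mdl.base_model, j, space)
    from .range_models import _StratifiedKernels
    kernels = _StratifiedKernels(space, fit.params, mdl.multipliers,
                                 conditioned=mdl.conditioning == "branch")

    node_state = np.zeros(tree.n_nodes, dtype=int)
    node_state[: tree.n_tips] = mdl.tip_states
    pos_of = {node: pos for pos, node in enumerate(estimates.node_ids)}
    for node, pos in pos_of.items():
        node_state[node] = estimates.map_state[pos]

    events: list[DispersalEvent] = []
    for node in tree.postorder:
        if not tree.children[node]:
            continue
        s_anc = int(node_state[node])
        c1, c2 = tree.children[node]
        M1 = kernels.branch_matrix(tree.age[node], tree.age[c1])
        M2 = kernels.branch_matrix(tree.age[node], tree.age[c2])
        sel = clado.anc == s_anc
        score = (clado.prob[sel]
                 * M1[clado.left[sel], node_state[c1]]
                 * M2[clado.right[sel], node_state[c2]])
        if score.sum() <= 0:
            score = clado.prob[sel]
        kbest = int(np.argmax(score))
        l_state = int(clado.left[sel][kbest])
        r_state = int(clado.right[sel][kbest])
        is_jump = bool(clado.is_jump[sel][kbest])
        anc_mask = int(space.state_masks[s_anc])
        for child, inherited in ((c1, l_state), (c2, r_state)):
            inh_mask = int(space.state_masks[inherited])
            if is_jump and inh_mask & ~anc_mask:
                # founder daughter: its single area is a jump event at the node
                jump_area_bit = inh_mask & ~anc_mask
                events.append(DispersalEvent(
                    branch=child,
                    from_areas=space.labels_of_mask(anc_mask),
                    to_area=space.labels_of_mask(jump_area_bit)[0],
                    time_ma=float(tree.age[node]),
                    founder=True,
                ))
            child_mask = int(space.state_masks[node_state[child]])
            gained = child_mask & ~inh_mask  # anagenetic gains along the branch
            mid = 0.5 * (tree.age[node] + tree.age[child])
            for a in range(space.n_areas):
                if gained >> a & 1:
                    events.append(DispersalEvent(
                        branch=child,
                        from_areas=space.labels_of_mask(inh_mask),
                        to_area=space.areas[a],
                        time_ma=float(mid),
                    ))
    return events


def classify_event(ev: DispersalEvent, conn: ConnectivityMatrix) -> str:
    """terrestrial (direct link), ambiguous (indirect link only), transoceanic."""
    if conn.reachable is None:
        raise ValueError("connectivity matrix lacks its transitive closure; "
                         "run paleogeography.reachability first")
    to_i = conn.index(ev.to_area)
    from_i = [conn.index(a) for a in ev.from_areas]
    if not from_i:
        raise ValueError("event with empty source range")
    if any(conn.connected[i, to_i] for i in from_i):
        return "terrestrial"
    if any(conn.reachable[i, to_i] for i in from_i):
        return "ambiguous"
    return "transoceanic"


def classify_events(events, connectivity: dict, strata) -> list:
    """Classify every event using the connectivity of its time stratum."""
    out = []
    for ev in events:
        st = stratum_for_age(strata, ev.time_ma)
        out.append(replace(ev, classification=classify_event(ev, connectivity[st.label])))
    return out


@dataclass(frozen=True)
class SkewTestInput:
    """Observed transoceanic counts and node counts for the two clades."""

    scenario: str          # "min" or "max"
    O_t: int               # observed transoceanic events, tolerant clade
    O_i: int               # observed transoceanic events, intolerant clade
    N_ct: int              # internal node count, tolerant clade
    N_ci: int              # internal node count, intolerant clade

    @property
    def N_to(self) -> int:
        return self.O_t + self.O_i

    @property
    def N_T(self) -> int:
        return self.N_ct + self.N_ci


def count_scenarios(classified_events, tree: IndexedTree,
                    tolerant_node: int, intolerant_node: int) -> tuple:
    """Min/max transoceanic counts for the two clades.

    `tolerant_node` / `intolerant_node` are the crown nodes (e.g. from
    `tree.mrca`) of the saltwater-tolerant and -intolerant clades; the two
    subtrees must not overlap.  The minimum scenario treats ambiguous
    events as terrestrial, the maximum as transoceanic.  Node counts are
    the internal nodes of each clade's subtree.
    """
    sub_t = set(tree.subtree_nodes(tolerant_node))
    sub_i = set(tree.subtree_nodes(intolerant_node))
    if sub_t & sub_i:
        raise ValueError("tolerant and intolerant clades overlap")
    n_ct = sum(1 for n in sub_t if tree.children[n])
    n_ci = sum(1 for n in sub_i if tree.children[n])

    def counts(treat_ambiguous_as: str) -> tuple[int, int]:
        o_t = o_i = 0
        for ev in classified_events:
            cls = ev.classification
            if cls == "ambiguous":
                cls = treat_ambiguous_as
            if cls != "transoceanic":
                continue
            if ev.branch in sub_t:
                o_t += 1
            elif ev.branch in sub_i:
                o_i += 1
        return o_t, o_i

    o_t_min, o_i_min = counts("terrestrial")
    o_t_max, o_i_max = counts("transoceanic")
    return (
        SkewTestInput("min", O_t=o_t_min, O_i=o_i_min, N_ct=n_ct, N_ci=n_ci),
        SkewTestInput("max", O_t=o_t_max, O_i=o_i_max, N_ct=n_ct, N_ci=n_ci),
    )


def expected_counts(N_to: float, N_ct: float, N_ci: float) -> tuple[float, float]:
    """Expected transoceanic counts apportioned by clade node counts.

    E_t = N_to * N_ct / N_T and E_i = N_to * N_ci / N_T, the no-skew
    expectation when clades differ in size.
    """
    N_T = N_ct + N_ci
    if N_T <= 0:
        raise ValueError("total node count must be positive")
    return N_to * N_ct / N_T, N_to * N_ci / N_T


@dataclass(frozen=True)
class SkewTestResult:
    """Pearson χ² (df=1, no continuity correction) for transoceanic skew."""

    scenario: str
    O_t: int
    O_i: int
    E_t: float
    E_i: float
    chi2: float
    p: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p < self.alpha

    def as_dict(self) -> dict:
        return {
            "scenario": self.scenario, "O_tolerant": self.O_t,
            "O_intolerant": self.O_i, "E_tolerant": round(self.E_t, 4),
            "E_intolerant": round(self.E_i, 4), "chi2": round(self.chi2, 4),
            "p": round(self.p, 6), "significant": self.significant,
        }


def chisq_from_statistic(chi2_value: float) -> float:
    """Upper-tail χ²(df=1) probability of a given statistic."""
    if chi2_value < 0:
        raise ValueError("chi-square statistic must be non-negative")
    return float(chi2_dist.sf(chi2_value, df=1))


def chisq_skew(inp: SkewTestInput, alpha: float = 0.05) -> SkewTestResult:
    """Pearson χ² test of observed vs expected transoceanic counts.

    chi2 = (O_t - E_t)^2 / E_t + (O_i - E_i)^2 / E_i with df = 1 and no
    continuity correction; zero expected counts are rejected (an exact
    binomial test would be needed there).
    """
    E_t, E_i = expected_counts(inp.N_to, inp.N_ct, inp.N_ci)
    if E_t <= 0 or E_i <= 0:
        raise ValueError("zero expected count: the chi-square approximation "
                         "is invalid; use an exact (binomial) test instead")
    stat = (inp.O_t - E_t) ** 2 / E_t + (inp.O_i - E_i) ** 2 / E_i
    return SkewTestResult(
        scenario=inp.scenario, O_t=inp.O_t, O_i=inp.O_i, E_t=E_t, E_i=E_i,
        chi2=float(stat), p=chisq_from_statistic(float(stat)), alpha=alpha,
    )


def events_frame(events) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "branch": ev.branch, "from": "+".join(ev.from_areas),
            "to": ev.to_area, "time_ma": ev.time_ma,
            "founder": ev.founder, "classification": ev.classification,
        }
        for ev in events
    ])


def write_events_tsv(events, path) -> None:
    events_frame(events).to_csv(path, sep="\t", index=False)
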