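import numpy as np
import pytest

import paleoranges as pr


@pytest.fixture(scope="session")
def tree3():
    """Three-tip tree with unequal branch lengths (ages: n1=1.5, root=2.5)."""
    return pr.IndexedTree.from_newick("((A:1.0,B:1.5):1.0,C:2.0);")


@pytest.fixture(scope="session")
def space2():
    return pr.RangeStateSpace(("X", "Y"))


@pytest.fixture(scope="session")
def small_bundle():
    """A 10-tip synthetic dataset (tree, history, occurrences), reused widely."""
    cfg = pr.SimulationConfig(n_tips=10, seed=3, root_age=50, psi=0.0)
    tree = pr.simulate_tree(cfg)
    space = pr.RangeStateSpace(cfg.areas)
    history = pr.simulate_range_history(tree, space, cfg.true_params, seed=4,
                                        condition_branches=True)
    occs = pr.simulate_occurrences(history, cfg, seed=5)
    return cfg, tree, space, history, occs


def oracle_clado_2areas(model: str, j: float) -> dict:
    """Independent hand enumeration of cladogenesis events for 2 areas.

    States are labelled 'A' (first area), 'B' (second), 'AB'.  Returns
    {ancestor: [(left, right, prob), ...]} with probabilities normalized.
    """
    w = (3.0 - j) / 3.0
    table = {}
    for anc, other in (("A", "B"), ("B", "A")):
        events = [(anc, anc, w)]
        if j > 0:
            events += [(anc, other, j), (other, anc, j)]
        table[anc] = events
    if model == "DEC":
        table["AB"] = [("AB", "A", w), ("A", "AB", w), ("AB", "B", w),
                       ("B", "AB", w), ("A", "B", w), ("B", "A", w)]
    elif model == "DIVALIKE":
        table["AB"] = [("A", "B", w), ("B", "A", w)]
    elif model == "BAYAREALIKE":
        table["AB"] = [("AB", "AB", w)]
    else:
        raise ValueError(model)
    out = {}
    for anc, events in table.items():
        total = sum(e[2] for e in events)
        out[anc] = [(l, r, p / total) for l, r, p in events]
    return out


def oracle_q_2areas(d: float, e: float, m_ab: float = 1.0, m_ba: float = 1.0):
    """Hand-written 4x4 anagenetic rate matrix over (null, A, B, AB)."""
    Q = np.array([
        [0.0, 0.0, 0.0, 0.0],
        [e, 0.0, 0.0, d * m_ab],
        [e, 0.0, 0.0, d * m_ba],
        [0.0, e, e, 0.0],
    ])
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def brute_force_3tip(tree3, space2, model, params, conditioning="none"):
    """Exhaustive 3-tip/2-area likelihood: sum over internal states and
    cladogenetic outcomes weighted by matrix exponentials.

    Returns a dict {(sA, sB, sC) state-label triple: probability}, plus the
    per-node posterior given one fixed configuration is recoverable from
    the summands.  Completely independent of the package's pruning code.
    """
    from scipy.linalg import expm
    label_of = {1: "A", 2: "B", 3: "AB"}
    mask_of = {"A": 1, "B": 2, "AB": 3}
    ct = oracle_clado_2areas(model.replace("+J", ""),
                             params.j if model.endswith("+J") else 0.0)
    Q = oracle_q_2areas(params.d, params.e)

    def P(t):
        M = expm(Q * t)
        if conditioning == "branch":
            M = M.copy()
            surv = 1.0 - M[:, 0]
            M[:, 0] = 0.0
            M[surv > 0] /= surv[surv > 0, None]
        return M

    # branches: tips A (1.0), B (1.5), C (2.0); internal n1 (1.0)
    PA, PB, PC, PN = P(1.0), P(1.5), P(2.0), P(1.0)
    probs = {}
    for sA in (1, 2, 3):
        for sB in (1, 2, 3):
            for sC in (1, 2, 3):
                tot = 0.0
                for sroot in ("A", "B", "AB"):
                    for l0, r0, p0 in ct[sroot]:
                        for sn1 in ("A", "B", "AB"):
                            for l1, r1, p1 in ct[sn1]:
                                tot += (1.0 / 3.0) * p0 \
                                    * PN[mask_of[l0], mask_of[sn1]] * p1 \
                                    * PA[mask_of[l1], sA] \
                                    * PB[mask_of[r1], sB] \
                                    * PC[mask_of[r0], sC]
                probs[(label_of[sA], label_of[sB], label_of[sC])] = tot
    return probs


@pytest.fixture(scope="session")
def chain_connectivity():
    """Connectivity on 4 areas: A-B linked, B-C linked, D isolated."""
    strata = [pr.TimeStratum(start_ma=300.0, end_ma=0.0)]
    conn = np.eye(4, dtype=bool)
    conn[0, 1] = conn[1, 0] = True
    conn[1, 2] = conn[2, 1] = True
    cm = pr.reachability(pr.ConnectivityMatrix(
        stratum=strata[0], areas=("A", "B", "C", "D"), connected=conn))
    return strata, {strata[0].label: cm}


def tip_labels_of(space, mask_int):
    return space.labels_of_mask(int(space.state_masks[mask_int]))
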