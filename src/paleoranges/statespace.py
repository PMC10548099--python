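"""Geographic range state space, anagenetic rates and cladogenesis tables.

A geographic range is a non-empty subset of discrete areas, bit-encoded.
Anagenesis (along branches) is a continuous-time Markov chain: single-area
gains at rate d (summed over source areas and scaled by the dispersal
multiplier between source and target) and single-area losses at rate e;
the empty (null) range is an absorbing state representing global
extirpation of the lineage.  Cladogenesis (at nodes) follows one of three
range-inheritance models:

DEC          narrow sympatry, subset sympatry, and narrow vicariance
             (one daughter restricted to a single area);
DIVALIKE     narrow sympatry and vicariance with splits of any size;
BAYAREALIKE  both daughters copy the full ancestral range.

Each model optionally adds founder-event ("jump") speciation: one daughter
jumps into a single area outside the ancestral range.  Per-event weights
follow the usual convention y = s = v = (3 - j)/3 for the non-jump event
classes and j for jumps, normalized per ancestral state, with j in [0, 3).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

MODELS = ("DEC", "DIVALIKE", "BAYAREALIKE")


@dataclass(frozen=True)
class RangeModelParams:
    """Anagenetic rates (per Myr) and the founder-event weight."""

    d: float  # per source-area dispersal (range-gain) rate
    e: float  # per-area extirpation (range-loss) rate
    j: float = 0.0  # founder-event weight, dimensionless

    def __post_init__(self) -> None:
        if self.d < 0 or self.e < 0:
            raise ValueError("rates d, e must be non-negative")
        if not 0.0 <= self.j < 3.0:
            raise ValueError("founder weight j must lie in [0, 3)")


class RangeStateSpace:
    """All bit-encoded ranges over `areas` up to `max_range_size`.

    State 0 is the null (empty) range, present only for anagenesis; states
    1..S are the non-empty subsets ordered by (size, bitmask).
    """

    def __init__(self, areas, max_range_size: int | None = None):
        self.areas = tuple(areas)
        n = len(self.areas)
        if n < 1:
            raise ValueError("need at least one area")
        self.n_areas = n
        self.max_range_size = n if max_range_size is None else min(max_range_size, n)
        if self.max_range_size < 1:
            raise ValueError("max_range_size must be >= 1")
        masks = [0]
        for size in range(1, self.max_range_size + 1):
            for combo in combinations(range(n), size):
                masks.append(sum(1 << a for a in combo))
        self.state_masks = np.array(masks, dtype=np.int64)
        self.index_of = {int(m): i for i, m in enumerate(masks)}
        self.n_states = len(masks)

    def mask_of_labels(self, labels) -> int:
        mask = 0
        for lb in labels:
            mask |= 1 << self.areas.index(lb)
        return mask

    def labels_of_mask(self, mask: int) -> tuple:
        return tuple(a for i, a in enumerate(self.areas) if mask >> i & 1)

    def state_index(self, labels_or_mask) -> int:
        mask = (labels_or_mask if isinstance(labels_or_mask, (int, np.integer))
                else self.mask_of_labels(labels_or_mask))
        try:
            return self.index_of[int(mask)]
        except KeyError:
            raise ValueError(f"range {labels_or_mask!r} not in state space") from None

    def size_of_state(self, idx: int) -> int:
        return int(bin(int(self.state_masks[idx])).count("1"))

    def bitstring(self, idx: int) -> str:
        mask = int(self.state_masks[idx])
        return "".join("1" if mask >> i & 1 else "0" for i in range(self.n_areas))


def build_q_matrix(space: RangeStateSpace, params: RangeModelParams,
                   multiplier: np.ndarray | None = None) -> np.ndarray:
    """Anagenetic rate matrix over the state space.

    rate(R -> R ∪ {a}) = d * Σ_{i∈R} m[i, a]   (a outside R, respecting max size)
    rate(R -> R \\ {i}) = e                     (including loss to the null range)
    The null range is absorbing; rows sum to zero.
    """
    n = space.n_areas
    if multiplier is None:
        multiplier = np.ones((n, n))
    multiplier = np.asarray(multiplier, dtype=float)
    if multiplier.shape != (n, n):
        raise ValueError(f"multiplier shape {multiplier.shape} != ({n}, {n})")
    S = space.n_states
    Q = np.zeros((S, S))
    for si in range(1, S):
        mask = int(space.state_masks[si])
        members = [a for a in range(n) if mask >> a & 1]
        if len(members) < space.max_range_size:
            for a in range(n):
                if mask >> a & 1:
                    continue
                target = space.index_of.get(mask | (1 << a))
                if target is None:
                    continue
                Q[si, target] = params.d * sum(multiplier[i, a] for i in members)
        for i in members:
            target = space.index_of[mask & ~(1 << i)]
            Q[si, target] = params.e
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


@dataclass
class CladoTable:
    """Sparse per-ancestor cladogenesis distribution.

    Events are stored as parallel arrays over all (ancestor, left, right)
    triples with non-zero probability; `prob` is normalized within each
    ancestral state.  `is_jump` marks founder events.
    """

    model: str
    j: float
    anc: np.ndarray
    left: np.ndarray
    right: np.ndarray
    prob: np.ndarray
    is_jump: np.ndarray

    def events_for(self, anc_idx: int):
        sel = self.anc == anc_idx
        return list(zip(self.left[sel], self.right[sel], self.prob[sel], self.is_jump[sel]))


def clado_table(model: str, j: float, space: RangeStateSpace) -> CladoTable:
    """Enumerate allowed ordered daughter pairs per ancestral state.

    Ordered pairs each carry their event-class weight: (3-j)/3 for
    sympatry/subset/vicariance, j for jumps; weights are normalized per
    ancestral state.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    if not 0.0 <= j < 3.0:
        raise ValueError("founder weight j must lie in [0, 3)")
    w = (3.0 - j) / 3.0
    anc, left, right, prob, jump = [], [], [], [], []
    idx = space.index_of
    for si in range(1, space.n_states):
        mask = int(space.state_masks[si])
        size = bin(mask).count("1")
        events: list[tuple[int, int, float, bool]] = []

        def add(lmask: int, rmask: int, weight: float, is_jump: bool = False) -> None:
            li, ri = idx.get(lmask), idx.get(rmask)
            if li is None or ri is None:
                return
            events.append((li, ri, weight, is_jump))

        if model == "DEC":
            if size == 1:
                add(mask, mask, w)
            else:
                for a in range(space.n_areas):           # subset sympatry
                    if mask >> a & 1:
                        single = 1 << a
                        add(mask, single, w)
                        add(single, mask, w)
                sub = (mask - 1) & mask                   # narrow vicariance
                while sub:
                    rest = mask & ~sub
                    if min(bin(sub).count("1"), bin(rest).count("1")) == 1:
                        add(sub, rest, w)
                    sub = (sub - 1) & mask
        elif model == "DIVALIKE":
            if size == 1:
                add(mask, mask, w)
            else:
                sub = (mask - 1) & mask                   # vicariance, any split
                while sub:
                    add(sub, mask & ~sub, w)
                    sub = (sub - 1) & mask
        else:  # BAYAREALIKE: exact copy only
            add(mask, mask, w)

        if j > 0:
            for a in range(space.n_areas):                # founder events
                if mask >> a & 1:
                    continue
                single = 1 << a
                add(mask, single, j, True)
                add(single, mask, j, True)

        total = sum(ev[2] for ev in events)
        if total <= 0:
            # degenerate corner (e.g. w == 0 with no jump targets): fall back
            # to an even distribution over the enumerated non-jump events
            events = [(li, ri, 1.0, jp) for li, ri, _, jp in events]
            total = len(events)
        for li, ri, weight, jp in events:
            anc.append(si); left.append(li); right.append(ri)
            prob.append(weight / total); jump.append(jp)

    return CladoTable(
        model=model, j=j,
        anc=np.array(anc, dtype=int), left=np.array(left, dtype=int),
        right=np.array(right, dtype=int), prob=np.array(prob, dtype=float),
        is_jump=np.array(jump, dtype=bool),
    )
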