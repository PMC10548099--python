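"""Likelihood-based ancestral range estimation on dated trees.

`GeographicRangeModel` fits one of six range-evolution models (DEC,
DIVALIKE, BAYAREALIKE, each with or without founder-event "+J") to tip
ranges on a time-scaled phylogeny by maximum likelihood, optionally with
time-stratified distance-based dispersal multipliers.  The likelihood is
computed by Felsenstein pruning over the bit-encoded range state space;
branches crossing stratum boundaries are split at the boundaries and each
segment uses its stratum's rate matrix.  `RangeFitResults` carries the
estimates, information criteria and marginal ancestral-range estimates.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize
from scipy.stats import chi2

from .statespace import (CladoTable, RangeModelParams, RangeStateSpace,
                         build_q_matrix, clado_table)
from .trees import IndexedTree

MODEL_NAMES = ("DEC", "DEC+J", "DIVALIKE", "DIVALIKE+J",
               "BAYAREALIKE", "BAYAREALIKE+J")


def parse_model_name(name: str) -> tuple[str, bool]:
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown model {name!r}; expected one of {MODEL_NAMES}")
    base, _, suffix = name.partition("+")
    return base, suffix == "J"


class _Kernel:
    """Transition probabilities P(t) = expm(Qt) for one rate matrix.

    Uses an eigendecomposition when it reproduces a reference expm to high
    accuracy, falling back to scaling-and-squaring per call otherwise.
    """

    def __init__(self, Q: np.ndarray):
        self.Q = Q
        self._use_eig = False
        try:
            w, V = np.linalg.eig(Q)
            Vinv = np.linalg.inv(V)
            self._w, self._V, self._Vinv = w, V, Vinv
            ref = expm(Q)  # t = 1 reference
            test = np.real(V @ (np.exp(w)[:, None] * Vinv))
            if np.max(np.abs(test - ref)) < 1e-10:
                self._use_eig = True
        except np.linalg.LinAlgError:
            pass

    def P(self, t: float) -> np.ndarray:
        if t == 0.0:
            return np.eye(self.Q.shape[0])
        if self._use_eig:
            M = np.real(self._V @ (np.exp(self._w * t)[:, None] * self._Vinv))
        else:
            M = expm(self.Q * t)
        np.clip(M, 0.0, None, out=M)
        return M


class _StratifiedKernels:
    """Per-stratum kernels and stratified branch transition matrices."""

    def __init__(self, space: RangeStateSpace, params: RangeModelParams,
                 multipliers=None, conditioned: bool = False):
        self.conditioned = conditioned
        if multipliers is None:
            self.strata = None
            self.kernels = [_Kernel(build_q_matrix(space, params))]
        else:
            # oldest stratum last; sort by end bound ascending (young -> old)
            mats = sorted(multipliers, key=lambda m: m.stratum.end_ma)
            self.strata = [m.stratum for m in mats]
            self.kernels = [
                _Kernel(build_q_matrix(space, params, m.multiplier)) for m in mats
            ]

    def branch_matrix(self, parent_age: float, child_age: float) -> np.ndarray:
        """Transition matrix from the branch top (older) to its bottom."""
        if parent_age < child_age - 1e-9:
            raise ValueError("parent must be older than child")
        if self.strata is None:
            M = self.kernels[0].P(parent_age - child_age)
            return self._condition(M) if self.conditioned else M
        M = None
        # iterate strata old -> young so M = P_old @ ... @ P_young
        for st, kern in zip(reversed(self.strata), reversed(self.kernels)):
            lo = max(child_age, st.end_ma)
            hi = min(parent_age, st.start_ma)
            if hi - lo <= 1e-12:
                continue
            P = kern.P(hi - lo)
            M = P if M is None else M @ P
        if M is None:  # zero-length branch (after rescaling cannot happen)
            M = np.eye(self.kernels[0].Q.shape[0])
        return self._condition(M) if self.conditioned else M

    @staticmethod
    def _condition(M: np.ndarray) -> np.ndarray:
        """Condition a branch on a non-null endpoint: the exact law of the
        per-branch-redraw simulator (each lineage observed to survive)."""
        surv = 1.0 - M[:, 0]
        M = M.copy()
        M[:, 0] = 0.0
        good = surv > 1e-300
        M[good] /= surv[good, None]
        return M


def _as_state_indices(space: RangeStateSpace, tree: IndexedTree, tip_ranges) -> np.ndarray:
    """Map tip ranges (DataFrame presence matrix or dict) to state indices."""
    states = np.zeros(tree.n_tips, dtype=int)
    if isinstance(tip_ranges, pd.DataFrame):
        cols = list(tip_ranges.columns)
        if tuple(cols) != tuple(space.areas):
            tip_ranges = tip_ranges[list(space.areas)]
        for i, label in enumerate(tree.tip_labels):
            row = tip_ranges.loc[label]
            mask = sum(1 << a for a, v in enumerate(row.values) if v)
            states[i] = space.state_index(mask)
    else:
        for i, label in enumerate(tree.tip_labels):
            states[i] = space.state_index(tuple(tip_ranges[label]))
    if np.any(states == 0):
        bad = [tree.tip_labels[i] for i in np.where(states == 0)[0]]
        raise ValueError(f"tips with empty range: {bad}")
    return states


def _pruning_pass(tree: IndexedTree, tip_states: np.ndarray, clado: CladoTable,
                  kernels: _StratifiedKernels):
    """Post-order partial likelihoods with per-node rescaling.

    Returns (L, up_messages, log_scale) where L[node] is the (scaled)
    conditional likelihood at the instant before cladogenesis and
    up_messages[child] is the (scaled) message at the top of the child's
    branch.
    """
    S = kernels.kernels[0].Q.shape[0]
    L = np.zeros((tree.n_nodes, S))
    up = [None] * tree.n_nodes
    branch_mats = [None] * tree.n_nodes
    log_scale = 0.0
    for node in tree.postorder:
        if not tree.children[node]:
            L[node, tip_states[node]] = 1.0
            continue
        c1, c2 = tree.children[node]
        msgs = []
        for c in (c1, c2):
            M = kernels.branch_matrix(tree.age[node], tree.age[c])
            branch_mats[c] = M
            msgs.append(M @ L[c])
        up[c1], up[c2] = msgs
        contrib = clado.prob * msgs[0][clado.left] * msgs[1][clado.right]
        vec = np.zeros(S)
        np.add.at(vec, clado.anc, contrib)
        peak = vec.max()
        if not np.isfinite(peak) or peak <= 0.0:
            raise FloatingPointError(
                f"non-finite/zero partial likelihood at node {node}"
            )
        L[node] = vec / peak
        log_scale += np.log(peak)
    return L, up, branch_mats, log_scale


def tree_loglik(tree: IndexedTree, tip_ranges, model: str,
                params: RangeModelParams, space: RangeStateSpace,
                multipliers=None, conditioning: str = "none") -> float:
    """Log-likelihood of tip ranges under a range-evolution model.

    The root likelihood is the mean of the root conditional likelihoods
    over all non-null states (a flat root prior).
    """
    base, with_jump = parse_model_name(model)
    j = params.j if with_jump else 0.0
    clado = clado_table(base, j, space)
    kernels = _StratifiedKernels(space, params, multipliers,
                                 conditioned=conditioning == "branch")
    tip_states = _as_state_indices(space, tree, tip_ranges)
    L, _, _, log_scale = _pruning_pass(tree, tip_states, clado, kernels)
    root_mean = L[tree.root, 1:].mean()
    if root_mean <= 0:
        return -np.inf
    return float(np.log(root_mean) + log_scale)


@dataclass
class NodeRangeEstimate:
    """Marginal range probabilities for each internal node."""

    space: RangeStateSpace
    node_ids: list
    ages: np.ndarray
    probs: np.ndarray  # (n_internal, n_states); null probability is 0

    @property
    def map_state(self) -> np.ndarray:
        return self.probs.argmax(axis=1)

    def map_labels(self, node_pos: int) -> tuple:
        return self.space.labels_of_mask(
            int(self.space.state_masks[self.map_state[node_pos]])
        )

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for pos, node in enumerate(self.node_ids):
            mi = int(self.map_state[pos])
            rows.append({
                "node": node,
                "age_ma": float(self.ages[pos]),
                "map_range": self.space.bitstring(mi),
                "map_labels": "+".join(self.space.labels_of_mask(
                    int(self.space.state_masks[mi]))),
                "map_prob": float(self.probs[pos, mi]),
            })
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.as_frame().to_csv(path, sep="\t", index=False)


class GeographicRangeModel:
    """Maximum-likelihood model of geographic range evolution on a tree.

    Parameters
    ----------
    tree : IndexedTree
        Dated binary tree, branch lengths in Myr.
    tip_ranges : DataFrame or mapping
        Binary taxon x area presence matrix (or taxon -> area labels).
    model : str
        One of DEC, DEC+J, DIVALIKE, DIVALIKE+J, BAYAREALIKE, BAYAREALIKE+J.
    space : RangeStateSpace, optional
        Defaults to all non-empty subsets of the presence-matrix areas.
    multipliers : list of DispersalMultiplierMatrix, optional
        Time-stratified dispersal multipliers; None means unconstrained.
    """

    def __init__(self, tree: IndexedTree, tip_ranges, model: str = "DEC",
                 space: RangeStateSpace | None = None, multipliers=None,
                 max_range_size: int | None = None,
                 conditioning: str = "none"):
        if conditioning not in ("none", "branch"):
            raise ValueError("conditioning must be 'none' or 'branch'")
        self.conditioning = conditioning
        self.tree = tree
        self.model = model
        self.base_model, self.with_jump = parse_model_name(model)
        if space is None:
            if isinstance(tip_ranges, pd.DataFrame):
                areas = tuple(tip_ranges.columns)
            else:
                areas = tuple(sorted({a for v in tip_ranges.values() for a in v}))
            space = RangeStateSpace(areas, max_range_size=max_range_size)
        self.space = space
        self.multipliers = multipliers
        self.tip_states = _as_state_indices(space, tree, tip_ranges)
        self.n_free_params = 3 if self.with_jump else 2

    @classmethod
    def from_files(cls, tree_path, geography_path, model: str = "DEC",
                   multipliers=None, **kwargs) -> "GeographicRangeModel":
        from .regionalization import read_geography_file
        tree = IndexedTree.from_file(tree_path)
        presence = read_geography_file(geography_path)
        return cls(tree, presence, model=model, multipliers=multipliers, **kwargs)

    # -- likelihood ----------------------------------------------------

    def loglike(self, params: RangeModelParams) -> float:
        j = params.j if self.with_jump else 0.0
        clado = clado_table(self.base_model, j, self.space)
        kernels = _StratifiedKernels(self.space, params, self.multipliers,
                                     conditioned=self.conditioning == "branch")
        try:
            L, _, _, log_scale = _pruning_pass(self.tree, self.tip_states,
                                               clado, kernels)
        except FloatingPointError:
            return -np.inf
        root_mean = L[self.tree.root, 1:].mean()
        if root_mean <= 0:
            return -np.inf
        return float(np.log(root_mean) + log_scale)

    def data_hash(self) -> str:
        h = hashlib.md5()
        h.update(self.tree.as_newick().encode())
        for label, st in zip(self.tree.tip_labels, self.tip_states):
            h.update(f"{label}:{int(st)};".encode())
        return h.hexdigest()

    # -- fitting -------------------------------------------------------

    def fit(self, starts: int = 5, seed: int = 0,
            d_bounds=(1e-12, 5.0), e_bounds=(1e-12, 5.0),
            j_max: float = 2.99999) -> "RangeFitResults":
        """Bounded quasi-Newton ML over (log10 d, log10 e[, j])."""
        rng = np.random.default_rng(seed)
        lb = [np.log10(d_bounds[0]), np.log10(e_bounds[0])]
        ub = [np.log10(d_bounds[1]), np.log10(e_bounds[1])]
        if self.with_jump:
            lb.append(0.0)
            ub.append(j_max)
        bounds = list(zip(lb, ub))

        def unpack(x) -> RangeModelParams:
            d, e = 10.0 ** x[0], 10.0 ** x[1]
            j = float(x[2]) if self.with_jump else 0.0
            return RangeModelParams(d=d, e=e, j=j)

        def neg(x) -> float:
            ll = self.loglike(unpack(x))
            return 1e10 if not np.isfinite(ll) else -ll

        x0s = [np.array([-2.0, -2.0] + ([0.1] if self.with_jump else []))]
        for _ in range(max(starts - 1, 0)):
            x = [rng.uniform(-4.0, 0.0), rng.uniform(-4.0, 0.0)]
            if self.with_jump:
                x.append(rng.uniform(0.0, 2.0))
            x0s.append(np.array(x))

        best, best_ll = None, -np.inf
        converged = False
        for x0 in x0s:
            res = minimize(neg, x0, method="L-BFGS-B", bounds=bounds)
            if np.isfinite(res.fun) and -res.fun > best_ll:
                best, best_ll = res, -res.fun
                converged = bool(res.success)
        if best is None:
            raise RuntimeError("all optimizer starts failed")
        params = unpack(best.x)
        return RangeFitResults(model_obj=self, params=params, llf=best_ll,
                               converged=converged)


@dataclass
class RangeFitResults:
    """ML fit of a range-evolution model: estimates, fit scores, marginals."""

    model_obj: GeographicRangeModel
    params: RangeModelParams
    llf: float
    converged: bool
    _marginals: NodeRangeEstimate | None = field(default=None, repr=False)

    @property
    def model(self) -> str:
        return self.model_obj.model

    @property
    def n_free_params(self) -> int:
        return self.model_obj.n_free_params

    @property
    def nobs(self) -> int:
        return self.model_obj.tree.n_tips

    @property
    def aic(self) -> float:
        return 2.0 * self.n_free_params - 2.0 * self.llf

    @property
    def aicc(self) -> float:
        k, n = self.n_free_params, self.nobs
        if n - k - 1 <= 0:
            return np.inf
        return self.aic + 2.0 * k * (k + 1) / (n - k - 1)

    def data_hash(self) -> str:
        return self.model_obj.data_hash()

    def summary(self) -> str:
        p = self.params
        lines = [
            "Geographic range evolution model fit",
            "=" * 44,
            f"model:        {self.model}",
            f"tips:         {self.nobs}",
            f"areas:        {self.model_obj.space.n_areas}",
            f"states:       {self.model_obj.space.n_states}",
            f"stratified:   {self.model_obj.multipliers is not None}",
            f"lnL:          {self.llf:.4f}",
            f"AIC:          {self.aic:.4f}",
            f"AICc:         {self.aicc:.4f}",
            f"converged:    {self.converged}",
            "-" * 44,
            f"d (dispersal)    {p.d:.6g} /Myr",
            f"e (extirpation)  {p.e:.6g} /Myr",
        ]
        if self.model_obj.with_jump:
            lines.append(f"j (founder)      {p.j:.6g}")
        return "\n".join(lines)

    def ancestral_marginals(self) -> NodeRangeEstimate:
        """Marginal range probabilities at each internal node.

        Standard two-pass (inside/outside) conditional marginals at the
        instant before cladogenesis, incorporating the cladogenetic event
        distribution; vectors are normalized and the null range carries
        probability zero.
        """
        if self._marginals is not None:
            return self._marginals
        mdl = self.model_obj
        tree = mdl.tree
        j = self.params.j if mdl.with_jump else 0.0
        clado = clado_table(mdl.base_model, j, mdl.space)
        kernels = _StratifiedKernels(mdl.space, self.params, mdl.multipliers,
                                     conditioned=mdl.conditioning == "branch")
        L, up, branch_mats, _ = _pruning_pass(tree, mdl.tip_states, clado, kernels)
        S = mdl.space.n_states
        above = np.zeros((tree.n_nodes, S))
        prior = np.zeros(S)
        prior[1:] = 1.0 / (S - 1)
        above[tree.root] = prior
        for node in reversed(tree.postorder):  # preorder: root first
            if not tree.children[node]:
                continue
            c1, c2 = tree.children[node]
            for child, sib in ((c1, c2), (c2, c1)):
                w = above[node][clado.anc] * clado.prob * up[sib][
                    clado.right if child == c1 else clado.left]
                H = np.zeros(S)
                np.add.at(H, clado.left if child == c1 else clado.right, w)
                vec = H @ branch_mats[child]
                peak = vec.max()
                above[child] = vec / peak if peak > 0 else vec
        internals = [n for n in tree.postorder if tree.children[n]]
        probs = np.zeros((len(internals), S))
        for pos, node in enumerate(internals):
            vec = above[node] * L[node]
            vec[0] = 0.0
            total = vec.sum()
            if total <= 0:
                raise FloatingPointError(f"zero marginal at node {node}")
            probs[pos] = vec / total
        self._marginals = NodeRangeEstimate(
            space=mdl.space, node_ids=internals,
            ages=tree.age[internals], probs=probs,
        )
        return self._marginals


def fit_model(tree: IndexedTree, tip_ranges, model: str, multipliers=None,
              starts: int = 5, seed: int = 0, **kwargs) -> RangeFitResults:
    """Convenience wrapper: build a GeographicRangeModel and fit it."""
    mdl = GeographicRangeModel(tree, tip_ranges, model=model,
                               multipliers=multipliers, **kwargs)
    return mdl.fit(starts=starts, seed=seed)


def compare_models(fits) -> pd.DataFrame:
    """Model-comparison table: ΔAIC, Akaike weights, AICc weights, LRT.

    All fits must be on identical data (checked by hash).  Likelihood-ratio
    tests are computed only for nested (M, M+J) pairs, with one degree of
    freedom.
    """
    fits = list(fits)
    hashes = {f.data_hash() for f in fits}
    if len(hashes) != 1:
        raise ValueError("fits compare different data (hash mismatch)")
    aic = np.array([f.aic for f in fits])
    aicc = np.array([f.aicc for f in fits])

    def weights(scores: np.ndarray) -> np.ndarray:
        finite = np.isfinite(scores)
        if not finite.any():  # e.g. AICc undefined for tiny tip counts
            return np.full(len(scores), np.nan)
        w = np.zeros(len(scores))
        delta = scores[finite] - scores[finite].min()
        w[finite] = np.exp(-0.5 * delta)
        return w / w.sum()

    aic_w, aicc_w = weights(aic), weights(aicc)
    by_name = {f.model: f for f in fits}
    rows = []
    for i, f in enumerate(fits):
        lrt_p = np.nan
        if f.model.endswith("+J") and f.model[:-2] in by_name:
            base = by_name[f.model[:-2]]
            stat = max(2.0 * (f.llf - base.llf), 0.0)
            lrt_p = float(chi2.sf(stat, df=1))
        rows.append({
            "model": f.model, "n_params": f.n_free_params, "lnL": f.llf,
            "d": f.params.d, "e": f.params.e,
            "j": f.params.j if f.model.endswith("+J") else 0.0,
            "AIC": f.aic, "dAIC": f.aic - aic.min(), "AIC_weight": aic_w[i],
            "AICc": f.aicc, "AICc_weight": aicc_w[i],
            "LRT_p_vs_base": lrt_p,
        })
    return pd.DataFrame(rows).sort_values("AIC").reset_index(drop=True)


def ancestral_marginals(fit: RangeFitResults) -> NodeRangeEstimate:
    """Functional alias for RangeFitResults.ancestral_marginals()."""
    if not fit.converged:
        raise ValueError("fit did not converge; refusing to compute marginals")
    return fit.ancestral_marginals()
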