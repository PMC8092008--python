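"""Hidden-Markov likelihood over ordered pillars of triple-conserved synteny.

Each pillar is one ancestral post-triplication locus, carrying up to three
syntenic track slots per genome.  The hidden state assigns, per genome, a
permutation of the three track slots to the three parental subgenomes; with
``G`` genomes the combined state space has ``6**G`` members.  Emissions are
phylogenetic likelihoods of the observed presence/absence patterns, computed
by Felsenstein pruning of the seven-state loss chain over the species tree.
Adjacent pillars share their hidden permutations with per-genome persistence
``1 - theta``, which is what lets synteny inform subgenome assignments.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

from . import _forward
from .loss_model import (
    N_STATES, RATE_PARAMS, STATES, STATE_INDEX, STATE_NAMES, SUBGENOMES,
    SUBGENOME_NAMES, LossModelSpec, Variant, build_generator,
    free_parameter_names, root_branch_row, root_chain,
    transition_probabilities,
)
from .trees import SpeciesTree, enumerate_topologies  # noqa: F401 (re-export)

#: The six track->subgenome permutations; ``PERMS[p][k]`` is the subgenome of
#: slot ``k`` (0-based) under permutation ``p``.
PERMS: tuple[tuple[int, int, int], ...] = tuple(itertools.permutations(SUBGENOMES))
N_PERMS = len(PERMS)

#: Observed slot-presence patterns reuse the subset coding of the state space
#: (subsets of {1,2,3}, here read as slot numbers).
SLOT_SUBSETS = STATES

#: ``PERM_STATE[p, o]`` = copy-number state index obtained by pushing observed
#: slot subset ``o`` through permutation ``p``.
PERM_STATE = np.empty((N_PERMS, N_STATES), dtype=np.int64)
for _p, _perm in enumerate(PERMS):
    for _o, _subset in enumerate(SLOT_SUBSETS):
        PERM_STATE[_p, _o] = STATE_INDEX[frozenset(_perm[i - 1] for i in _subset)]

#: presence indicator: ``STATE_HAS[k-1, s]`` is 1 if subgenome ``k`` survives
#: in state ``s``.
STATE_HAS = np.array([[1.0 if k in s else 0.0 for s in STATES] for k in SUBGENOMES])


def tip_state(present_slots, perm) -> int:
    """Copy-number state of one genome's tracks under a slot permutation.

    ``present_slots`` is an iterable of slot numbers (1..3) with a surviving
    gene; ``perm`` is either a permutation index (0..5) or a 3-tuple mapping
    slot k (1-based position) to a subgenome.
    """
    slots = frozenset(int(s) for s in present_slots)
    if not slots:
        raise ValueError("a pillar genome must retain at least one slot")
    if not isinstance(perm, (int, np.integer)):
        perm = PERMS.index(tuple(perm))
    return int(PERM_STATE[perm, STATE_INDEX[slots]])


@dataclass(frozen=True)
class HmmSpec:
    """Synteny persistence of the hidden permutations along the pillar chain."""

    theta: float | tuple = 0.05
    break_policy: str = "uniform"

    def theta_vector(self, G: int) -> np.ndarray:
        th = np.asarray(self.theta, dtype=float)
        th = np.broadcast_to(th, (G,)).copy()
        if np.any(th < 0) or np.any(th > 1):
            raise ValueError("theta must lie in [0, 1]")
        return th


class PillarSet:
    """Compact ordered pillar table.

    ``patterns[i, g]`` encodes which track slots of genome ``g`` hold a
    surviving gene at pillar ``i`` (subset coding shared with the state
    space); ``breaks[i, g]`` marks loss of track contiguity to the previous
    pillar.
    """

    def __init__(self, patterns, breaks, genomes, ids=None, anchors=None,
                 genes=None):
        self.patterns = np.asarray(patterns, dtype=np.int64)
        self.breaks = np.asarray(breaks, dtype=bool)
        self.genomes = tuple(genomes)
        n = self.patterns.shape[0]
        if self.patterns.shape != (n, len(self.genomes)) or self.breaks.shape != self.patterns.shape:
            raise ValueError("inconsistent pillar arrays")
        if n == 0:
            raise ValueError("empty pillar set")
        self.ids = list(ids) if ids is not None else [f"p{i}" for i in range(n)]
        self.anchors = list(anchors) if anchors is not None else ["" for _ in range(n)]
        self.genes = genes  # optional {(genome, slot): list of gene ids}

    def __len__(self):
        return self.patterns.shape[0]

    def reorder(self, order) -> "PillarSet":
        order = np.asarray(order, dtype=int)
        if sorted(order.tolist()) != list(range(len(self))):
            raise ValueError("ordering must be a permutation of pillar indices")
        genes = None
        if self.genes is not None:
            genes = {k: [v[i] for i in order] for k, v in self.genes.items()}
        return PillarSet(self.patterns[order], self.breaks[order], self.genomes,
                         [self.ids[i] for i in order], [self.anchors[i] for i in order],
                         genes)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PillarSet":
        df = df.sort_values("order_index")
        genomes = []
        for col in df.columns:
            if col.endswith(".slot1_gene"):
                genomes.append(col[: -len(".slot1_gene")])
        if not genomes:
            raise ValueError("no genome slot columns found")
        n = len(df)
        patterns = np.zeros((n, len(genomes)), dtype=np.int64)
        breaks = np.zeros((n, len(genomes)), dtype=bool)
        genes = {}
        for g_i, g in enumerate(genomes):
            present = np.stack(
                [df[f"{g}.slot{k}_present"].to_numpy().astype(bool) for k in (1, 2, 3)],
                axis=1)
            for k in (1, 2, 3):
                genes[(g, k)] = df[f"{g}.slot{k}_gene"].fillna("").tolist()
            subsets = [frozenset(k + 1 for k in range(3) if row[k]) for row in present]
            if any(not s for s in subsets):
                raise ValueError(f"genome {g} has a pillar with no surviving slot")
            patterns[:, g_i] = [STATE_INDEX[s] for s in subsets]
            breaks[:, g_i] = df[f"{g}.break"].to_numpy().astype(bool)
        return cls(patterns, breaks, genomes,
                   ids=df["pillar_id"].tolist(), anchors=df["anchor"].tolist(),
                   genes=genes)

    def to_dataframe(self) -> pd.DataFrame:
        cols: dict = {
            "pillar_id": self.ids,
            "order_index": np.arange(len(self)),
            "anchor": self.anchors,
        }
        for g_i, g in enumerate(self.genomes):
            for k in (1, 2, 3):
                present = np.array(
                    [k in SLOT_SUBSETS[p] for p in self.patterns[:, g_i]], dtype=int)
                if self.genes is not None and (g, k) in self.genes:
                    gene_col = self.genes[(g, k)]
                else:
                    gene_col = [f"{g}_g{i}_t{k}" if present[i] else ""
                                for i in range(len(self))]
                cols[f"{g}.slot{k}_gene"] = gene_col
                cols[f"{g}.slot{k}_present"] = present
            cols[f"{g}.break"] = self.breaks[:, g_i].astype(int)
        return pd.DataFrame(cols)


def read_pillars(path) -> PillarSet:
    return PillarSet.from_dataframe(pd.read_csv(path, sep="\t"))


def write_pillars(pillars: PillarSet, path) -> None:
    pillars.to_dataframe().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------------
# likelihood engine
# ---------------------------------------------------------------------------------


class PillarLikelihood:
    """Shared machinery for likelihood evaluation, fitting and posteriors."""

    def __init__(self, pillars: PillarSet, tree: SpeciesTree, *,
                 use_breaks: bool = True):
        if set(pillars.genomes) != set(tree.genomes):
            raise ValueError("pillar genomes do not match tree tips")
        self.tree = tree
        self.G = tree.n_tips
        self.S = N_PERMS ** self.G
        # reorder pillar columns to the tree's tip order
        col = [pillars.genomes.index(g) for g in tree.genomes]
        self.patterns = pillars.patterns[:, col]
        self.breaks = pillars.breaks[:, col]
        self.pillars = pillars
        self.use_breaks = use_breaks
        self.n = len(pillars)
        # distinct observation patterns
        upat, pat_idx = np.unique(self.patterns, axis=0, return_inverse=True)
        self.upat = upat
        self.pat_idx = pat_idx.astype(np.int64)
        # digits of each combined state, genome 0 most significant
        digits = np.empty((self.S, self.G), dtype=np.int64)
        idx = np.arange(self.S)
        for g in range(self.G - 1, -1, -1):
            digits[:, g] = idx % N_PERMS
            idx //= N_PERMS
        self.state_digits = digits
        # flat index into the pruning tensor L (shape (7,)*G) for every
        # (distinct pattern, combined state) pair
        F = np.zeros((upat.shape[0], self.S), dtype=np.int64)
        for g in range(self.G):
            F += PERM_STATE[digits[:, g][None, :], upat[:, g][:, None]] * (
                N_STATES ** (self.G - 1 - g))
        self.F = F
        self._tip_axis = {tid: tree.genomes.index(tree.labels[tid]) for tid in tree.tips}

    # -- transition matrices ------------------------------------------------------
    def _pmats(self, spec: LossModelSpec, nu: np.ndarray) -> list[np.ndarray]:
        Q_non = build_generator(spec, "non_root")
        mats = [None] * self.tree.n_nodes
        for node in range(1, self.tree.n_nodes):
            mats[node] = transition_probabilities(Q_non, float(nu[node]))
        # root edge: only the start-state row is ever used; for the two-step
        # model it comes from the augmented (single-arrival) chain
        row7, _, _ = root_branch_row(spec, float(nu[0]))
        P0 = np.zeros((N_STATES, N_STATES))
        P0[spec.root_state] = row7
        mats[0] = P0
        return mats

    # -- pruning ------------------------------------------------------------------
    def _inside(self, Pmats) -> dict[int, np.ndarray]:
        """Inside (Felsenstein) arrays per node over the full tip-state grid.

        ``ins[n][s, t1..tG]`` is the probability of the tip states below node
        ``n`` given state ``s`` at ``n``; axes for tips outside the subtree
        are singletons and broadcast.
        """
        tree = self.tree
        ins: dict[int, np.ndarray] = {}
        for node in tree.postorder:
            if not tree.children[node]:
                axis = self._tip_axis[node]
                shape = [N_STATES] + [1] * self.G
                shape[1 + axis] = N_STATES
                ins[node] = np.eye(N_STATES).reshape(shape)
            else:
                arr = None
                for c in tree.children[node]:
                    contrib = np.tensordot(Pmats[c], ins[c], axes=(1, 0))
                    arr = contrib if arr is None else arr * contrib
                ins[node] = arr
        return ins

    def _tensorL(self, spec: LossModelSpec, nu: np.ndarray,
                 ins: dict | None = None, Pmats=None) -> np.ndarray:
        if Pmats is None:
            Pmats = self._pmats(spec, nu)
        if ins is None:
            ins = self._inside(Pmats)
        L = np.tensordot(Pmats[0], ins[0], axes=(1, 0))[spec.root_state]
        return L

    def _outside(self, Pmats, ins, spec) -> dict[int, np.ndarray]:
        """Outside arrays: evidence from tips outside each node's subtree."""
        tree = self.tree
        out: dict[int, np.ndarray] = {}
        shape = [N_STATES] + [1] * self.G
        out[0] = Pmats[0][spec.root_state].reshape(shape)
        order = [n for n in reversed(tree.postorder) if tree.children[n]]
        for node in order:
            kids = tree.children[node]
            for c in kids:
                sib_arr = out[node]
                for d in kids:
                    if d != c:
                        sib_arr = sib_arr * np.tensordot(Pmats[d], ins[d], axes=(1, 0))
                out[c] = np.tensordot(Pmats[c], sib_arr, axes=(0, 0))
        return out

    # -- emission + forward -------------------------------------------------------
    def _emissions(self, spec: LossModelSpec, nu: np.ndarray) -> np.ndarray:
        L = self._tensorL(spec, nu)
        E = L.ravel()[self.F]
        np.clip(E, 0.0, None, out=E)
        return E

    def _theta_eff(self, theta: np.ndarray) -> np.ndarray:
        eff = np.broadcast_to(theta, (self.n, self.G)).copy()
        if self.use_breaks:
            eff[self.breaks] = 1.0
        eff[0] = 0.0
        return eff

    def loglik(self, spec: LossModelSpec, nu, theta) -> float:
        nu = np.asarray(nu, dtype=float)
        theta = np.broadcast_to(np.asarray(theta, dtype=float), (self.G,))
        E = self._emissions(spec, nu)
        return float(_forward.forward_lnl(E, self.pat_idx, self._theta_eff(theta), self.G))

    def posteriors(self, spec: LossModelSpec, nu, theta) -> tuple[np.ndarray, float]:
        nu = np.asarray(nu, dtype=float)
        theta = np.broadcast_to(np.asarray(theta, dtype=float), (self.G,))
        E = self._emissions(spec, nu)
        gamma, lnl = _forward.forward_backward(E, self.pat_idx, self._theta_eff(theta), self.G)
        return gamma, float(lnl)


def emission_loglik(pillar_pattern, state, tree: SpeciesTree, spec: LossModelSpec,
                    nu=None) -> float:
    """Log-probability of one pillar's presence pattern under one combined
    orthology state.

    ``pillar_pattern`` maps genome label to the iterable of present slot
    numbers; ``state`` maps genome label to a permutation (index or 3-tuple).
    Branch lengths default to those stored on the tree.
    """
    if set(pillar_pattern) != set(tree.genomes):
        raise ValueError("pillar genomes do not match tree tips")
    nu = tree.lengths if nu is None else np.asarray(nu, dtype=float)
    tips = {}
    for g in tree.genomes:
        tips[g] = tip_state(pillar_pattern[g], state[g])
    Q_non = build_generator(spec, "non_root")
    Pmats = [None] + [transition_probabilities(Q_non, float(nu[i]))
                      for i in range(1, tree.n_nodes)]

    def inside(node) -> np.ndarray:
        if not tree.children[node]:
            v = np.zeros(N_STATES)
            v[tips[tree.labels[node]]] = 1.0
            return v
        arr = np.ones(N_STATES)
        for c in tree.children[node]:
            arr = arr * (Pmats[c] @ inside(c))
        return arr

    row7, _, _ = root_branch_row(spec, float(nu[0]))
    lik = float(row7 @ inside(0))
    return np.log(lik) if lik > 0 else -np.inf


def sequence_loglik(pillars, tree: SpeciesTree, spec: LossModelSpec,
                    hmm: HmmSpec, nu=None, use_breaks: bool = True) -> float:
    """Forward-algorithm log-likelihood of an ordered pillar sequence."""
    if isinstance(pillars, pd.DataFrame):
        pillars = PillarSet.from_dataframe(pillars)
    eng = PillarLikelihood(pillars, tree, use_breaks=use_breaks)
    nu = tree.lengths if nu is None else nu
    return eng.loglik(spec, nu, hmm.theta_vector(eng.G))


# ---------------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------------

_BOUNDS = {
    "rate": (np.log(1e-4), np.log(100.0)),
    "unit": (1e-6, 1.0),
    "nu": (np.log(1e-6), np.log(20.0)),
    "theta": (1e-4, 1.0),
}


@dataclass
class FitResult:
    """Maximum-likelihood fit of a loss model to an ordered pillar set."""

    variant: Variant
    spec: LossModelSpec
    nu: np.ndarray
    theta: np.ndarray
    lnL: float
    converged: bool
    n_restarts: int
    seed: int
    n_free: int
    engine: PillarLikelihood = field(repr=False)
    _gamma: np.ndarray | None = field(default=None, repr=False)

    @property
    def branch_lengths(self) -> dict[str, float]:
        names = self.engine.tree.edge_names()
        return {names[i]: float(self.nu[i]) for i in range(len(self.nu))}

    def posteriors(self) -> np.ndarray:
        if self._gamma is None:
            self._gamma, _ = self.engine.posteriors(self.spec, self.nu, self.theta)
        return self._gamma

    def to_dict(self) -> dict:
        from .loss_model import spec_to_dict
        return {
            "variant": self.variant.value,
            "lnL": self.lnL,
            "params": spec_to_dict(self.spec),
            "branch_lengths": self.branch_lengths,
            "theta": [float(t) for t in self.theta],
            "converged": bool(self.converged),
            "n_free_loss_params": self.n_free,
            "seed": self.seed,
            "n_restarts": self.n_restarts,
        }


class _Packer:
    """Maps between the optimizer vector and (spec, nu, theta)."""

    def __init__(self, engine, variant, template: LossModelSpec,
                 frozen: dict[str, float], theta_mode, theta_fixed):
        self.engine = engine
        self.variant = variant
        self.template = template
        self.frozen = dict(frozen)
        self.loss_names = [n for n in free_parameter_names(variant)
                           if n not in self.frozen]
        self.theta_mode = theta_mode  # "shared" | "per_genome" | None (fixed)
        self.theta_fixed = theta_fixed
        self.n_edges = engine.tree.n_nodes
        self.n_theta = 0 if theta_mode is None else (1 if theta_mode == "shared" else engine.G)

    @property
    def bounds(self):
        b = []
        for name in self.loss_names:
            b.append(_BOUNDS["rate"] if name in RATE_PARAMS else _BOUNDS["unit"])
        b.extend([_BOUNDS["nu"]] * self.n_edges)
        b.extend([_BOUNDS["theta"]] * self.n_theta)
        return b

    def pack(self, spec: LossModelSpec, nu, theta) -> np.ndarray:
        x = []
        for name in self.loss_names:
            v = spec.get_param(name)
            x.append(np.log(np.clip(v, 1e-4, 100.0)) if name in RATE_PARAMS
                     else np.clip(v, 1e-6, 1.0))
        x.extend(np.log(np.clip(np.asarray(nu, dtype=float), 1e-6, 20.0)))
        if self.n_theta:
            th = np.broadcast_to(np.asarray(theta, dtype=float), (self.engine.G,))
            if self.theta_mode == "shared":
                x.append(float(np.clip(th.mean(), 1e-4, 1.0)))
            else:
                x.extend(np.clip(th, 1e-4, 1.0))
        return np.array(x)

    def unpack(self, x: np.ndarray):
        vals = dict(self.frozen)
        i = 0
        for name in self.loss_names:
            vals[name] = float(np.exp(x[i])) if name in RATE_PARAMS else float(x[i])
            i += 1
        spec = self.template.with_params(vals)
        nu = np.exp(x[i: i + self.n_edges])
        i += self.n_edges
        if self.theta_mode is None:
            theta = np.broadcast_to(np.asarray(self.theta_fixed, dtype=float),
                                    (self.engine.G,)).copy()
        elif self.theta_mode == "shared":
            theta = np.full(self.engine.G, float(x[i]))
        else:
            theta = np.asarray(x[i: i + self.n_theta], dtype=float)
        return spec, nu, theta


def _template_spec(variant: Variant, last_subgenome: int,
                   init: dict[str, float]) -> LossModelSpec:
    base = LossModelSpec.null()
    kw: dict = {"variant": variant, "last_subgenome": last_subgenome}
    if variant is Variant.G3_ROOTSPEC:
        kw.update(root_sigma=1.0, root_fT=(1.0, 1.0, 1.0), root_fD=(1.0, 1.0, 1.0))
    if variant is Variant.G3_ROOT:
        kw.update(tau=1.0, beta12=0.3, beta13=0.3)
    from dataclasses import replace
    spec = replace(base, **kw)
    return spec.with_params({n: init.get(n, spec.get_param(n))
                             for n in free_parameter_names(variant)})


def _canonicalize_labels(spec: LossModelSpec) -> LossModelSpec:
    """Resolve the exact subgenome-1 <-> subgenome-2 label symmetry.

    Relabeling subgenomes 1 and 2 (swapping their fractionation factors and
    mirroring the hidden permutations) leaves the likelihood unchanged, so
    the G3-family fit surface has two equivalent modes.  The convention here
    is that subgenome 1 is the least fractionated (LF), so the mode with the
    smaller combined factors on subgenome 1 is reported.
    """
    if spec.variant not in (Variant.G3, Variant.G3_ROOTSPEC):
        return spec
    if spec.fT[0] + spec.fD[0] <= spec.fT[1] + spec.fD[1]:
        return spec
    vals = {"fT1": spec.fT[1], "fT2": spec.fT[0],
            "fD1": spec.fD[1], "fD2": spec.fD[0]}
    if spec.variant is Variant.G3_ROOTSPEC:
        vals.update({"root_fT1": spec.root_fT[1], "root_fT2": spec.root_fT[0],
                     "root_fD1": spec.root_fD[1], "root_fD2": spec.root_fD[0]})
    return spec.with_params(vals)


def fit(pillars, tree: SpeciesTree, variant: Variant = Variant.G3, *,
        last_subgenome: int = 1, theta: str | float = "per_genome",
        n_restarts: int = 5, seed: int = 0, use_breaks: bool = True,
        frozen: dict[str, float] | None = None,
        init: dict[str, float] | None = None,
        init_nu=None, init_theta: float = 0.1,
        maxiter: int = 400, tol: float = 1e-6) -> FitResult:
    """Maximize the pillar-sequence likelihood over loss parameters, branch
    lengths and synteny persistence.

    ``theta`` selects the persistence parameterization: ``"per_genome"``
    (default), ``"shared"``, or a fixed numeric value excluded from the
    optimization.  ``frozen`` pins named loss parameters (e.g. ``tau``) at
    fixed values.  Multi-start: the first start uses the supplied/default
    initial values, the rest are seeded random perturbations.
    """
    if isinstance(pillars, pd.DataFrame):
        pillars = PillarSet.from_dataframe(pillars)
    variant = Variant(variant)
    engine = PillarLikelihood(pillars, tree, use_breaks=use_breaks)
    init = dict(init or {})
    defaults = {"sigma": 1.0, "tau": 1.0, "beta12": 0.3, "beta13": 0.3,
                "root_sigma": 1.0}
    for name in free_parameter_names(variant):
        init.setdefault(name, defaults.get(name, 0.9))
    template = _template_spec(variant, last_subgenome, init)
    if isinstance(theta, str):
        theta_mode, theta_fixed = theta, None
        if theta not in ("shared", "per_genome"):
            raise ValueError("theta must be 'shared', 'per_genome' or a number")
    else:
        theta_mode, theta_fixed = None, float(theta)
    packer = _Packer(engine, variant, template, frozen or {}, theta_mode, theta_fixed)
    nu0 = np.asarray(init_nu, dtype=float) if init_nu is not None else \
        np.full(engine.tree.n_nodes, 0.2)
    x0 = packer.pack(template, nu0, init_theta)
    rng = np.random.default_rng(seed)
    bounds = packer.bounds

    def objective(x):
        spec, nu, th = packer.unpack(x)
        return -engine.loglik(spec, nu, th)

    best = None
    best_success = False
    for r in range(max(1, n_restarts)):
        if r == 0:
            xs = x0.copy()
        else:
            xs = x0 + rng.normal(0.0, 0.4, size=x0.shape)
            xs = np.clip(xs, [b[0] for b in bounds], [b[1] for b in bounds])
        res = scipy.optimize.minimize(
            objective, xs, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": tol, "eps": 1e-6})
        if best is None or res.fun < best.fun:
            best = res
            best_success = bool(res.success)
    if not best_success:
        warnings.warn(
            f"fit of {variant.value} did not report convergence after "
            f"{n_restarts} restarts (best lnL {-best.fun:.4f})", RuntimeWarning)
    spec, nu, th = packer.unpack(best.x)
    spec = _canonicalize_labels(spec)
    return FitResult(variant=variant, spec=spec, nu=nu, theta=th,
                     lnL=float(-best.fun), converged=best_success,
                     n_restarts=n_restarts, seed=seed,
                     n_free=len(free_parameter_names(variant)), engine=engine)


# ---------------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------------

#: ``PERM_ONEHOT[p, k, m-1]`` = 1 if permutation p maps slot k to subgenome m.
PERM_ONEHOT = np.zeros((N_PERMS, 3, 3))
for _p, _perm in enumerate(PERMS):
    for _k in range(3):
        PERM_ONEHOT[_p, _k, _perm[_k] - 1] = 1.0


def posterior_subgenome_assignments(fit_result: FitResult) -> np.ndarray:
    """Marginal track->subgenome probabilities.

    Returns an array of shape ``(n_pillars, G, 3, 3)``: for each pillar,
    genome and track slot, the posterior probability that the slot belongs to
    each subgenome (LF, MF1, MF2).  Each slot row sums to one.
    """
    eng = fit_result.engine
    gamma = fit_result.posteriors()
    gshape = gamma.reshape((len(eng.pillars),) + (N_PERMS,) * eng.G)
    out = np.empty((len(eng.pillars), eng.G, 3, 3))
    for g in range(eng.G):
        axes = tuple(1 + a for a in range(eng.G) if a != g)
        marg = gshape.sum(axis=axes)  # (n, 6)
        out[:, g] = np.einsum("np,pkm->nkm", marg, PERM_ONEHOT)
    return out


def assignments_to_frame(fit_result: FitResult) -> pd.DataFrame:
    arr = posterior_subgenome_assignments(fit_result)
    eng = fit_result.engine
    rows = []
    for i, pid in enumerate(eng.pillars.ids):
        for g_i, g in enumerate(eng.tree.genomes):
            for k in range(3):
                rows.append({
                    "pillar_id": pid, "genome": g, "slot": k + 1,
                    "p_LF": arr[i, g_i, k, 0], "p_MF1": arr[i, g_i, k, 1],
                    "p_MF2": arr[i, g_i, k, 2],
                })
    return pd.DataFrame(rows)


def _pattern_weight_tensor(fit_result: FitResult) -> np.ndarray:
    """Posterior weight of every tip-state tuple, summed over pillars."""
    eng = fit_result.engine
    gamma = fit_result.posteriors()
    gpat = np.zeros((eng.upat.shape[0], eng.S))
    np.add.at(gpat, eng.pat_idx, gamma)
    W = np.bincount(eng.F.ravel(), weights=gpat.ravel(),
                    minlength=N_STATES ** eng.G)
    return W.reshape((N_STATES,) * eng.G)


def _node_marginals(fit_result: FitResult):
    """Per-node state marginals over the tip-tuple grid, plus W and L."""
    eng = fit_result.engine
    spec, nu = fit_result.spec, fit_result.nu
    Pmats = eng._pmats(spec, nu)
    ins = eng._inside(Pmats)
    out = eng._outside(Pmats, ins, spec)
    L = eng._tensorL(spec, nu, ins=ins, Pmats=Pmats)
    W = _pattern_weight_tensor(fit_result)
    safe_L = np.where(L > 0, L, 1.0)
    marg = {}
    for node in range(eng.tree.n_nodes):
        m = ins[node] * out[node] / safe_L[None]
        marg[node] = m
    return marg, W, L, ins, Pmats


def expected_losses_per_branch(fit_result: FitResult) -> pd.DataFrame:
    """Posterior expected surviving-copy and loss counts per branch and
    subgenome.

    Because losses are irreversible each copy is lost at most once, so the
    expected loss count on a branch equals the drop in expected survivor
    counts between its endpoints.  On the root branch of the two-step model
    arrivals are counted explicitly from expected jump counts.
    """
    eng = fit_result.engine
    tree = eng.tree
    marg, W, L, ins, Pmats = _node_marginals(fit_result)
    n_pillars = len(eng.pillars)
    surv = np.zeros((tree.n_nodes, 3))
    for node in range(tree.n_nodes):
        node_state_p = np.tensordot(W, marg[node],
                                    axes=(tuple(range(eng.G)),
                                          tuple(range(1, eng.G + 1))))
        surv[node] = STATE_HAS @ node_state_p
    names = tree.edge_names()
    root_state = fit_result.spec.root_state
    rows = []
    is_two_step = fit_result.spec.variant is Variant.G3_ROOT
    if is_two_step:
        counts, chain = _root_edge_jump_counts(fit_result, W, L, ins, Pmats)
        sets = chain.state_sets
    for node in range(tree.n_nodes):
        if node == 0:
            top = np.array([n_pillars * STATE_HAS[k - 1, root_state]
                            for k in SUBGENOMES])
        else:
            top = surv[tree.parent[node]]
        for k in SUBGENOMES:
            if node == 0 and is_two_step:
                losses = sum(c for (u, v), c in counts.items()
                             if k in sets[u] and k not in sets[v])
                arrivals = sum(c for (u, v), c in counts.items()
                               if k not in sets[u] and k in sets[v])
            else:
                losses = top[k - 1] - surv[node, k - 1]
                arrivals = 0.0
            rows.append({
                "branch": names[node], "subgenome": SUBGENOME_NAMES[k],
                "survivors_parent": top[k - 1], "losses": losses,
                "arrivals": arrivals, "survivors_child": surv[node, k - 1],
            })
    return pd.DataFrame(rows)


def _root_edge_jump_counts(fit_result: FitResult, W=None, L=None, ins=None,
                           Pmats=None):
    """Posterior expected number of each jump type on the root branch.

    Works on the (possibly augmented) root chain and uses the Van Loan
    block-matrix integral for expected Markov jump counts conditioned on the
    branch endpoints.  Returns ``(counts, chain)`` with counts keyed by
    root-chain state index pairs.
    """
    eng = fit_result.engine
    spec, nu = fit_result.spec, fit_result.nu
    if W is None:
        Pmats = eng._pmats(spec, nu)
        ins = eng._inside(Pmats)
        L = eng._tensorL(spec, nu, ins=ins, Pmats=Pmats)
        W = _pattern_weight_tensor(fit_result)
    chain = root_chain(spec)
    Q = chain.Q
    n_ext = Q.shape[0]
    nu0 = float(nu[0])
    safe_L = np.where(L > 0, L, 1.0)
    # inside values of the first-divergence node, lifted to the root chain
    ins_ext = ins[0][chain.projection]  # (n_ext, tip axes)
    counts: dict[tuple[int, int], float] = {}
    for u in range(n_ext):
        for v in range(n_ext):
            if u == v or Q[u, v] <= 0:
                continue
            A = np.zeros((2 * n_ext, 2 * n_ext))
            A[:n_ext, :n_ext] = Q
            A[n_ext:, n_ext:] = Q
            A[u, n_ext + v] = Q[u, v]
            J = scipy.linalg.expm(A * nu0)[:n_ext, n_ext:]
            # E[N_{u->v}] summed over pillars:
            #   sum_t W(t) * sum_j J[start, j] * inside_ext(j, t) / L(t)
            contrib = np.tensordot(J[chain.start], ins_ext, axes=(0, 0)) / safe_L
            counts[(u, v)] = float((W * contrib).sum())
    return counts, chain


@dataclass(frozen=True)
class PreArrivalFractions:
    """Root-branch loss timing summary for the two-step hexaploidy model."""

    fractions: dict  # subgenome index -> fraction of its root losses pre-arrival
    never_arrived: float  # fraction of pillars never receiving the last subgenome
    pre_counts: dict
    post_counts: dict


def prearrival_loss_fractions(fit_result: FitResult) -> PreArrivalFractions:
    """Fraction of each early subgenome's root-branch losses that predate the
    arrival of the last subgenome, plus the never-arrived pillar fraction.

    Pre-arrival losses of subgenome ``m`` are jumps out of states lacking the
    last subgenome that drop ``m`` (both plain losses and combined
    loss-plus-arrival jumps); post-arrival losses drop ``m`` from a state
    already containing the last subgenome.
    """
    if fit_result.spec.variant is not Variant.G3_ROOT:
        raise ValueError("pre-arrival fractions require the two-step (G3_ROOT) model")
    eng = fit_result.engine
    spec, nu = fit_result.spec, fit_result.nu
    last = spec.last_subgenome
    marg, W, L, ins, Pmats = _node_marginals(fit_result)
    counts, chain = _root_edge_jump_counts(fit_result, W, L, ins, Pmats)
    others = [k for k in SUBGENOMES if k != last]
    pre: dict[int, float] = {m: 0.0 for m in others}
    post: dict[int, float] = {m: 0.0 for m in others}
    for (u, v), c in counts.items():
        su, sv = chain.state_sets[u], chain.state_sets[v]
        for m in others:
            if m in su and m not in sv:
                if chain.pre_arrival[u]:
                    pre[m] += c
                else:
                    post[m] += c
    fractions = {m: (pre[m] / (pre[m] + post[m]) if pre[m] + post[m] > 0 else 0.0)
                 for m in others}
    # posterior mass still in the pre-arrival block at the end of the root edge
    _, row_ext, chain2 = root_branch_row(spec, float(nu[0]))
    ins_ext = ins[0][chain2.projection]
    safe_L = np.where(L > 0, L, 1.0)
    pre_idx = np.flatnonzero(chain2.pre_arrival)
    end_pre = np.tensordot(row_ext[pre_idx], ins_ext[pre_idx], axes=(0, 0))
    never = float((W * (end_pre / safe_L)).sum())
    return PreArrivalFractions(fractions=fractions,
                               never_arrived=never / len(eng.pillars),
                               pre_counts=pre, post_counts=post)


# ---------------------------------------------------------------------------------
# ordering comparison
# ---------------------------------------------------------------------------------

def compare_orderings(pillars, tree: SpeciesTree, spec: LossModelSpec,
                      hmm: HmmSpec, orderings, nu=None, refit: bool = False,
                      **fit_kwargs) -> pd.DataFrame:
    """Log-likelihood of the pillar data under alternative pillar orderings.

    Break flags refer to the original ordering, so they are ignored here and
    synteny coupling acts only through ``theta``.  With ``refit`` each
    ordering is refitted; otherwise parameters are held fixed.
    """
    if isinstance(pillars, pd.DataFrame):
        pillars = PillarSet.from_dataframe(pillars)
    rows = []
    for j, order in enumerate(orderings):
        sub = pillars.reorder(order)
        if refit:
            fr = fit(sub, tree, spec.variant, use_breaks=False, **fit_kwargs)
            lnl = fr.lnL
        else:
            lnl = sequence_loglik(sub, tree, spec, hmm, nu=nu, use_breaks=False)
        rows.append({"ordering": j, "lnL": lnl})
    df = pd.DataFrame(rows).sort_values("lnL", ascending=False).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
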