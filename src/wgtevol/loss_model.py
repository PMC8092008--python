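"""Seven-state copy-number model of homoeolog loss after a whole-genome triplication.

A hexaploidy leaves every ancestral locus with up to three surviving copies,
one from each parental subgenome.  Losses are irreversible, so the copy-number
process is a continuous-time Markov chain over the seven nonempty subsets of
the subgenomes ``{1, 2, 3}``:

* ``T``  -- all three copies present (the triplicated state);
* ``D12, D13, D23`` -- one copy lost (the "duplicated" states);
* ``S1, S2, S3`` -- single-copy, absorbing.

Subgenome 1 is the least-fractionated subgenome (LF), 2 is MF1 and 3 is MF2.
The base T->D loss rate is folded into branch lengths (``nu = alpha * t``);
losses out of duplicated states are scaled by ``sigma``.  Biased fractionation
enters through per-subgenome factors ``fT[g]`` (losses out of ``T``) and
``fD[g]`` (losses out of ``D`` states), with MF2 as the fixed baseline
(``fT[3] = fD[3] = 1``).  The two-step hexaploidy model adds arrival
transitions on the root branch: every locus starts in the two-subgenome state
left by the first hybridization and the last subgenome arrives at rate ``tau``
(no prior loss) or ``beta`` (one MF copy already lost).
"""
from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg
import yaml

SUBGENOMES = (1, 2, 3)
SUBGENOME_NAMES = {1: "LF", 2: "MF1", 3: "MF2"}

#: Copy-number states as subsets of surviving subgenomes, in canonical order.
STATES: tuple[frozenset, ...] = (
    frozenset({1, 2, 3}),
    frozenset({1, 2}),
    frozenset({1, 3}),
    frozenset({2, 3}),
    frozenset({1}),
    frozenset({2}),
    frozenset({3}),
)
STATE_NAMES = ("T", "D12", "D13", "D23", "S1", "S2", "S3")
STATE_INDEX = {s: i for i, s in enumerate(STATES)}
N_STATES = len(STATES)


class Variant(str, enum.Enum):
    """Nested family of loss models, from no bias to the two-step root model."""

    NULL = "null"          # no fractionation bias
    ONE_DOM = "1dom"       # one dominant (LF) subgenome
    G3 = "g3"              # all three subgenomes distinct
    G3_ROOTSPEC = "g3rootspec"  # G3 with separate parameters on the root branch
    G3_ROOT = "g3root"     # G3 plus two-step arrival of the last subgenome


_FREE_PARAMS = {
    Variant.NULL: ("sigma",),
    Variant.ONE_DOM: ("sigma", "fT1", "fD1"),
    Variant.G3: ("sigma", "fT1", "fT2", "fD1", "fD2"),
    Variant.G3_ROOTSPEC: (
        "sigma", "fT1", "fT2", "fD1", "fD2",
        "root_sigma", "root_fT1", "root_fT2", "root_fD1", "root_fD2",
    ),
    Variant.G3_ROOT: (
        "sigma", "fT1", "fT2", "fD1", "fD2", "tau", "beta12", "beta13",
    ),
}

#: Parameters optimized on a log scale (positive rates); the rest are
#: fractionation factors constrained to [0, 1].
RATE_PARAMS = frozenset(
    {"sigma", "root_sigma", "tau", "beta12", "beta13"})


@dataclass(frozen=True)
class LossModelSpec:
    """Variant plus parameter values of the seven-state loss chain.

    ``fT`` and ``fD`` are 3-tuples indexed by subgenome (1-based in the
    notation, 0-based in the tuple); the third entry is the fixed baseline 1.
    """

    variant: Variant = Variant.NULL
    sigma: float = 1.0
    fT: tuple[float, float, float] = (1.0, 1.0, 1.0)
    fD: tuple[float, float, float] = (1.0, 1.0, 1.0)
    root_sigma: float | None = None
    root_fT: tuple[float, float, float] | None = None
    root_fD: tuple[float, float, float] | None = None
    tau: float | None = None
    beta12: float | None = None
    beta13: float | None = None
    last_subgenome: int = 1

    def __post_init__(self):
        v = Variant(self.variant)
        object.__setattr__(self, "variant", v)
        object.__setattr__(self, "fT", tuple(float(x) for x in self.fT))
        object.__setattr__(self, "fD", tuple(float(x) for x in self.fD))
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        for name, f in (("fT", self.fT), ("fD", self.fD)):
            if len(f) != 3:
                raise ValueError(f"{name} must have one entry per subgenome")
            if not all(0.0 <= x <= 1.0 for x in f):
                raise ValueError(f"{name} entries must lie in [0, 1]")
            if f[2] != 1.0:
                raise ValueError(f"{name}[3] is the fixed baseline and must be 1")
        if v is Variant.NULL and (any(x != 1 for x in self.fT) or any(x != 1 for x in self.fD)):
            raise ValueError("NULL forces all fractionation factors to 1")
        if v is Variant.ONE_DOM and (self.fT[1] != 1 or self.fD[1] != 1):
            raise ValueError("ONE_DOM forces fT[2] = fD[2] = 1")
        if v is Variant.G3_ROOTSPEC:
            if self.root_sigma is None or self.root_fT is None or self.root_fD is None:
                raise ValueError("G3_ROOTSPEC requires root_sigma, root_fT, root_fD")
            object.__setattr__(self, "root_fT", tuple(float(x) for x in self.root_fT))
            object.__setattr__(self, "root_fD", tuple(float(x) for x in self.root_fD))
            if self.root_sigma <= 0:
                raise ValueError("root_sigma must be > 0")
            for name, f in (("root_fT", self.root_fT), ("root_fD", self.root_fD)):
                if not all(0.0 <= x <= 1.0 for x in f) or f[2] != 1.0:
                    raise ValueError(f"invalid {name}")
        elif self.root_sigma is not None or self.root_fT is not None or self.root_fD is not None:
            raise ValueError("root-specific parameters are only valid for G3_ROOTSPEC")
        if v is Variant.G3_ROOT:
            if self.tau is None or self.beta12 is None or self.beta13 is None:
                raise ValueError("G3_ROOT requires tau, beta12 and beta13")
            if self.tau < 0 or self.beta12 < 0 or self.beta13 < 0:
                raise ValueError("arrival rates must be >= 0")
        elif self.tau is not None or self.beta12 is not None or self.beta13 is not None:
            raise ValueError("arrival parameters are only valid for the G3_ROOT variant")
        if self.last_subgenome not in SUBGENOMES:
            raise ValueError("last_subgenome must be 1, 2 or 3")

    # -- convenience constructors -------------------------------------------------
    @classmethod
    def null(cls, sigma: float = 1.0) -> "LossModelSpec":
        return cls(Variant.NULL, sigma=sigma)

    @classmethod
    def one_dom(cls, sigma: float, fT1: float, fD1: float) -> "LossModelSpec":
        return cls(Variant.ONE_DOM, sigma=sigma, fT=(fT1, 1.0, 1.0), fD=(fD1, 1.0, 1.0))

    @classmethod
    def g3(cls, sigma: float, fT, fD) -> "LossModelSpec":
        return cls(Variant.G3, sigma=sigma, fT=tuple(fT), fD=tuple(fD))

    @classmethod
    def g3_rootspec(cls, sigma, fT, fD, root_sigma, root_fT, root_fD) -> "LossModelSpec":
        return cls(Variant.G3_ROOTSPEC, sigma=sigma, fT=tuple(fT), fD=tuple(fD),
                   root_sigma=root_sigma, root_fT=tuple(root_fT), root_fD=tuple(root_fD))

    @classmethod
    def g3_root(cls, sigma, fT, fD, tau, beta12, beta13, last_subgenome: int = 1) -> "LossModelSpec":
        return cls(Variant.G3_ROOT, sigma=sigma, fT=tuple(fT), fD=tuple(fD),
                   tau=tau, beta12=beta12, beta13=beta13, last_subgenome=last_subgenome)

    # -- root start state ---------------------------------------------------------
    @property
    def root_state(self) -> int:
        """Index of the state at the polyploidy event itself.

        ``T`` for single-step models; the two-subgenome state left by the first
        hybridization for the two-step (G3_ROOT) model.
        """
        if self.variant is Variant.G3_ROOT:
            return STATE_INDEX[frozenset(SUBGENOMES) - {self.last_subgenome}]
        return STATE_INDEX[frozenset(SUBGENOMES)]

    # -- flat parameter access (used by the optimizer and serialization) ----------
    def get_param(self, name: str) -> float:
        if name.startswith("root_f"):
            f = self.root_fT if name[5:7] == "fT" else self.root_fD
            return f[int(name[-1]) - 1]
        if name.startswith("fT") or name.startswith("fD"):
            f = self.fT if name[1] == "T" else self.fD
            return f[int(name[-1]) - 1]
        return float(getattr(self, name))

    def with_params(self, values: dict[str, float]) -> "LossModelSpec":
        fT, fD = list(self.fT), list(self.fD)
        rfT = list(self.root_fT) if self.root_fT else [1.0, 1.0, 1.0]
        rfD = list(self.root_fD) if self.root_fD else [1.0, 1.0, 1.0]
        kw: dict = {}
        for name, val in values.items():
            if name in ("fT1", "fT2"):
                fT[int(name[-1]) - 1] = val
            elif name in ("fD1", "fD2"):
                fD[int(name[-1]) - 1] = val
            elif name in ("root_fT1", "root_fT2"):
                rfT[int(name[-1]) - 1] = val
            elif name in ("root_fD1", "root_fD2"):
                rfD[int(name[-1]) - 1] = val
            else:
                kw[name] = val
        kw["fT"], kw["fD"] = tuple(fT), tuple(fD)
        if self.variant is Variant.G3_ROOTSPEC:
            kw["root_fT"], kw["root_fD"] = tuple(rfT), tuple(rfD)
        return replace(self, **kw)


def free_parameter_names(variant: Variant) -> tuple[str, ...]:
    return _FREE_PARAMS[Variant(variant)]


def free_parameter_count(spec: LossModelSpec | Variant) -> int:
    """Number of free loss-model parameters (branch lengths and HMM
    persistence excluded: they are shared across compared variants)."""
    variant = spec.variant if isinstance(spec, LossModelSpec) else Variant(spec)
    return len(_FREE_PARAMS[variant])


def build_generator(spec: LossModelSpec, branch_class: str = "non_root") -> np.ndarray:
    """Instantaneous rate matrix of the loss chain on one branch class.

    Each surviving copy ``g`` in state ``s`` is lost at rate ``fT[g]`` when
    ``|s| = 3`` and ``sigma * fD[g]`` when ``|s| = 2``; single-copy states are
    absorbing.  On the root branch, G3_ROOT adds arrival transitions out of the
    start state and G3_ROOTSPEC swaps in its root-specific parameters.

    For G3_ROOT this is the seven-state collapsed view (arrival rates written
    onto the shared two-subgenome row).  The likelihood itself uses
    :func:`root_chain`, which separates the pre-arrival state so that the
    last subgenome can arrive only once.
    """
    if branch_class not in ("root", "non_root"):
        raise ValueError("branch_class must be 'root' or 'non_root'")
    sigma, fT, fD = spec.sigma, spec.fT, spec.fD
    if branch_class == "root" and spec.variant is Variant.G3_ROOTSPEC:
        sigma, fT, fD = spec.root_sigma, spec.root_fT, spec.root_fD
    Q = np.zeros((N_STATES, N_STATES))
    for i, s in enumerate(STATES):
        if len(s) == 1:
            continue
        for g in s:
            j = STATE_INDEX[s - {g}]
            Q[i, j] = fT[g - 1] if len(s) == 3 else sigma * fD[g - 1]
    if branch_class == "root" and spec.variant is Variant.G3_ROOT:
        start = frozenset(SUBGENOMES) - {spec.last_subgenome}
        i = STATE_INDEX[start]
        others = sorted(start)
        full = frozenset(SUBGENOMES)
        Q[i, STATE_INDEX[full]] += spec.tau
        # beta12 targets the D state missing the larger prior subgenome,
        # beta13 the one missing the smaller; for last_subgenome=1 these are
        # exactly D12 and D13.
        Q[i, STATE_INDEX[full - {others[1]}]] += spec.beta12
        Q[i, STATE_INDEX[full - {others[0]}]] += spec.beta13
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _reachable_mask(Q: np.ndarray) -> np.ndarray:
    n = Q.shape[0]
    adj = (Q > 0) | np.eye(n, dtype=bool)
    reach = adj.copy()
    for _ in range(n):
        new = reach @ adj
        if (new == reach).all():
            break
        reach = new
    return reach


def transition_probabilities(Q: np.ndarray, nu: float) -> np.ndarray:
    """``P = expm(Q * nu)`` with round-off cleaned up.

    Uses an eigendecomposition when the eigenvector basis is well conditioned,
    falling back to scaling-and-squaring.  Negative round-off entries are
    clamped to zero, structurally unreachable entries zeroed, and rows
    renormalized to sum to one.
    """
    if nu < 0:
        raise ValueError("branch length nu must be >= 0")
    if nu == 0:
        return np.eye(Q.shape[0])
    A = Q * nu
    P = None
    try:
        w, V = np.linalg.eig(A)
        cond = np.linalg.cond(V)
        if np.isfinite(cond) and cond < 1e8:
            P = (V @ np.diag(np.exp(w)) @ np.linalg.inv(V)).real
    except np.linalg.LinAlgError:
        P = None
    if P is None or not np.all(np.isfinite(P)):
        P = scipy.linalg.expm(A)
    P[~_reachable_mask(Q)] = 0.0
    np.clip(P, 0.0, 1.0, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


@dataclass(frozen=True)
class RootChain:
    """The copy-number chain on the root branch, possibly augmented.

    For the two-step (G3_ROOT) model the arrival of the last subgenome can
    happen only once, so the root branch runs on an augmented state space
    that distinguishes the *pre-arrival* two-subgenome state (and the
    single-copy states reached from it) from the identical-looking
    post-arrival states.  ``projection[j]`` maps each augmented state to the
    seven-state space it collapses to at the end of the branch;
    ``pre_arrival[j]`` flags states in which the last subgenome has not yet
    arrived.  For all other variants this is simply the seven-state chain.
    """

    Q: np.ndarray
    start: int
    projection: np.ndarray
    pre_arrival: np.ndarray
    state_sets: tuple


def root_chain(spec: LossModelSpec) -> RootChain:
    """Generator, start state and projection of the root-branch chain."""
    if spec.variant is not Variant.G3_ROOT:
        Q = build_generator(spec, "root")
        return RootChain(Q=Q, start=spec.root_state,
                         projection=np.arange(N_STATES),
                         pre_arrival=np.zeros(N_STATES, dtype=bool),
                         state_sets=STATES)
    last = spec.last_subgenome
    full = frozenset(SUBGENOMES)
    m1, m2 = sorted(full - {last})
    n_ext = N_STATES + 3
    PRE, S1P, S2P = N_STATES, N_STATES + 1, N_STATES + 2
    Q = np.zeros((n_ext, n_ext))
    Q[:N_STATES, :N_STATES] = build_generator(spec, "non_root")
    np.fill_diagonal(Q, 0.0)
    # arrivals out of the pre-arrival state
    Q[PRE, STATE_INDEX[full]] = spec.tau
    Q[PRE, STATE_INDEX[full - {m2}]] = spec.beta12
    Q[PRE, STATE_INDEX[full - {m1}]] = spec.beta13
    # pre-arrival sigma-losses stay in the pre-arrival block
    Q[PRE, S1P] = spec.sigma * spec.fD[m2 - 1]  # lose m2, keep m1
    Q[PRE, S2P] = spec.sigma * spec.fD[m1 - 1]  # lose m1, keep m2
    np.fill_diagonal(Q, -Q.sum(axis=1))
    projection = np.concatenate([
        np.arange(N_STATES),
        [STATE_INDEX[frozenset({m1, m2})], STATE_INDEX[frozenset({m1})],
         STATE_INDEX[frozenset({m2})]],
    ])
    pre = np.zeros(n_ext, dtype=bool)
    pre[[PRE, S1P, S2P]] = True
    state_sets = STATES + (frozenset({m1, m2}), frozenset({m1}), frozenset({m2}))
    return RootChain(Q=Q, start=PRE, projection=projection, pre_arrival=pre,
                     state_sets=state_sets)


def root_branch_row(spec: LossModelSpec, nu: float) -> tuple[np.ndarray, np.ndarray, RootChain]:
    """Distribution over states at the bottom of the root branch.

    Returns ``(row7, row_ext, chain)``: the seven-state collapsed
    distribution, the distribution over the (possibly augmented) root chain,
    and the chain itself.
    """
    chain = root_chain(spec)
    P = transition_probabilities(chain.Q, nu)
    row_ext = P[chain.start]
    row7 = np.zeros(N_STATES)
    np.add.at(row7, chain.projection, row_ext)
    return row7, row_ext, chain


# -- serialization ----------------------------------------------------------------

def spec_to_dict(spec: LossModelSpec) -> dict:
    d: dict = {"variant": spec.variant.value, "sigma": spec.sigma,
               "fT1": spec.fT[0], "fT2": spec.fT[1], "fD1": spec.fD[0], "fD2": spec.fD[1],
               "last_subgenome": spec.last_subgenome}
    if spec.variant is Variant.G3_ROOTSPEC:
        d.update(root_sigma=spec.root_sigma,
                 root_fT1=spec.root_fT[0], root_fT2=spec.root_fT[1],
                 root_fD1=spec.root_fD[0], root_fD2=spec.root_fD[1])
    if spec.variant is Variant.G3_ROOT:
        d.update(tau=spec.tau, beta12=spec.beta12, beta13=spec.beta13)
    return d


def spec_from_dict(d: dict) -> LossModelSpec:
    variant = Variant(d["variant"])
    kw = dict(
        variant=variant,
        sigma=float(d.get("sigma", 1.0)),
        fT=(float(d.get("fT1", 1.0)), float(d.get("fT2", 1.0)), 1.0),
        fD=(float(d.get("fD1", 1.0)), float(d.get("fD2", 1.0)), 1.0),
        last_subgenome=int(d.get("last_subgenome", 1)),
    )
    if variant is Variant.G3_ROOTSPEC:
        kw.update(
            root_sigma=float(d["root_sigma"]),
            root_fT=(float(d.get("root_fT1", 1.0)), float(d.get("root_fT2", 1.0)), 1.0),
            root_fD=(float(d.get("root_fD1", 1.0)), float(d.get("root_fD2", 1.0)), 1.0),
        )
    if variant is Variant.G3_ROOT:
        kw.update(tau=float(d["tau"]), beta12=float(d["beta12"]), beta13=float(d["beta13"]))
    return LossModelSpec(**kw)


def save_spec(spec: LossModelSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh)


def load_spec(path) -> LossModelSpec:
    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh))
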