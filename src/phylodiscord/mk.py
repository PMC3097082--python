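"""Mk models for discrete morphological characters: likelihood, model
fitting, likelihood-ratio tests, and marginal ancestral state reconstruction.

The Mk model is a continuous-time Markov chain on k states.  Three
parameterizations of the rate matrix Q are supported:

* ER  -- equal rates: one shared rate for every transition;
* SYM -- symmetric rates: one rate per unordered state pair
  (k(k-1)/2 parameters), forward and reverse transitions equal;
* ARD -- all rates different: one rate per ordered pair (k(k-1)).

Likelihoods use Felsenstein's pruning algorithm with per-character
rescaling; transition probabilities are matrix exponentials computed by
eigendecomposition (symmetric generators) or scipy's expm.  The root prior
is uniform over states by default and configurable to a custom vector.
Missing states ('?') enter as all-ones partial likelihood vectors, so they
inform the reconstruction only through topology and branch lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import chi2

from .errors import PhyloError, ValidationError
from .trees import Tree

__all__ = [
    "MISSING",
    "CharacterMatrix",
    "RateModel",
    "ModelFit",
    "ASRResult",
    "LRTResult",
    "ConvergenceError",
    "n_params",
    "build_rate_matrix",
    "transition_probs",
    "log_likelihood",
    "fit_model",
    "likelihood_ratio_test",
    "marginal_asr",
]

MISSING = "?"
RATE_BOUNDS = (1e-8, 1e3)
_KINDS = ("ER", "SYM", "ARD")


class ConvergenceError(PhyloError):
    def __init__(self, message, best_fit=None):
        super().__init__(message)
        self.best_fit = best_fit


@dataclass
class CharacterMatrix:
    """taxon -> list of states (one entry per character); '?' = missing."""

    data: dict
    alphabet: list
    names: list | None = None

    def __post_init__(self):
        if len(self.alphabet) < 2:
            raise ValidationError("alphabet must have k >= 2 states")
        if len(set(self.alphabet)) != len(self.alphabet):
            raise ValidationError("alphabet states must be unique")
        self.data = {
            t: list(states) if not isinstance(states, list) else states
            for t, states in self.data.items()
        }
        n = {len(v) for v in self.data.values()}
        if len(n) > 1:
            raise ValidationError("taxa have differing numbers of characters")
        allowed = set(self.alphabet) | {MISSING}
        for taxon, states in self.data.items():
            bad = set(states) - allowed
            if bad:
                raise ValidationError(
                    f"states {sorted(bad)} for {taxon!r} not in alphabet"
                )

    @property
    def n_characters(self) -> int:
        return len(next(iter(self.data.values())))

    @property
    def k(self) -> int:
        return len(self.alphabet)


def read_character_tsv(path, character: str, alphabet=None) -> CharacterMatrix:
    """Load one named character from a long-format TSV
    (columns taxon, character, state)."""
    table = pd.read_csv(path, sep="\t", dtype=str).fillna(MISSING)
    sub = table[table["character"] == character]
    if sub.empty:
        raise ValidationError(f"character {character!r} not found in {path}")
    data = {row["taxon"]: [row["state"]] for _, row in sub.iterrows()}
    if alphabet is None:
        alphabet = sorted({s for (s,) in map(tuple, data.values()) if s != MISSING})
    return CharacterMatrix(data, list(alphabet), names=[character])


def n_params(kind: str, k: int) -> int:
    if kind == "ER":
        return 1
    if kind == "SYM":
        return k * (k - 1) // 2
    if kind == "ARD":
        return k * (k - 1)
    raise ValidationError(f"unknown model kind {kind!r}; expected one of {_KINDS}")


@dataclass
class RateModel:
    """An Mk rate-matrix parameterization (generator has zero row sums)."""

    kind: str
    k: int
    params: np.ndarray
    generator: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        self.params = np.asarray(self.params, dtype=float)
        expected = n_params(self.kind, self.k)
        if self.params.shape != (expected,):
            raise ValidationError(
                f"{self.kind} with k={self.k} needs {expected} rates, "
                f"got {self.params.size}"
            )
        if np.any(self.params <= 0):
            raise ValidationError("rates must be positive")
        if self.generator is None:
            self.generator = _fill_generator(self.kind, self.k, self.params)


def _fill_generator(kind: str, k: int, params: np.ndarray) -> np.ndarray:
    Q = np.zeros((k, k))
    if kind == "ER":
        Q[:] = params[0]
    elif kind == "SYM":
        idx = 0
        for i in range(k):
            for j in range(i + 1, k):  # upper triangle, row-major
                Q[i, j] = Q[j, i] = params[idx]
                idx += 1
    else:  # ARD, row-major over off-diagonals
        idx = 0
        for i in range(k):
            for j in range(k):
                if i != j:
                    Q[i, j] = params[idx]
                    idx += 1
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def build_rate_matrix(kind: str, k: int, params) -> RateModel:
    return RateModel(kind=kind, k=k, params=np.asarray(params, dtype=float))


class _Propagator:
    """P(t) for a fixed generator, batched over branch lengths."""

    def __init__(self, Q: np.ndarray):
        self.Q = Q
        self.symmetric = np.allclose(Q, Q.T)
        self._eig = None
        if self.symmetric:
            w, U = np.linalg.eigh(Q)
            self._eig = (w, U, U.T)
        else:
            w, V = np.linalg.eig(Q)
            try:
                Vinv = np.linalg.inv(V)
                if np.linalg.cond(V) < 1e8:
                    self._eig = (w, V, Vinv)
            except np.linalg.LinAlgError:
                pass

    def __call__(self, ts: np.ndarray) -> np.ndarray:
        ts = np.asarray(ts, dtype=float)
        if self._eig is not None:
            w, V, Vinv = self._eig
            ewt = np.exp(np.multiply.outer(ts, w))
            P = np.einsum("ik,...k,kj->...ij", V, ewt, Vinv)
            P = np.real(P)
        else:  # defective generator: fall back to expm per length
            P = np.stack([expm(self.Q * t) for t in np.atleast_1d(ts)])
            P = P.reshape(ts.shape + self.Q.shape)
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=-1, keepdims=True)
        return P


def transition_probs(model: RateModel, t: float) -> np.ndarray:
    """Row-stochastic matrix exp(Q t)."""
    if t < 0:
        raise ValidationError("branch length must be >= 0")
    return _Propagator(model.generator)(np.array([t]))[0]


# ---------------------------------------------------------------------------
# pruning engine


class _PruningEngine:
    """Tree + data preprocessed once; likelihood evaluated per generator."""

    def __init__(self, tree: Tree, chars: CharacterMatrix):
        self.k = chars.k
        state_index = {s: i for i, s in enumerate(chars.alphabet)}
        nodes = list(tree.postorder())
        self.index = {id(n): i for i, n in enumerate(nodes)}
        self.nodes = nodes
        self.children = [
            [self.index[id(c)] for c in n.children] for n in nodes
        ]
        self.lengths = np.zeros(len(nodes))
        for n in nodes:
            if n is tree.root:
                continue
            if n.length is None:
                raise ValidationError(
                    "branch lengths are required for Mk likelihoods"
                )
            self.lengths[self.index[id(n)]] = n.length
        leaf_names = [n.name for n in nodes if n.is_leaf]
        missing = [name for name in leaf_names if name not in chars.data]
        if missing:
            raise ValidationError(f"no character data for leaves: {missing}")
        n_chars = chars.n_characters
        self.n_chars = n_chars
        self.tips = {}
        for n in nodes:
            if not n.is_leaf:
                continue
            partial = np.zeros((n_chars, self.k))
            for c, state in enumerate(chars.data[n.name]):
                if state == MISSING:
                    partial[c, :] = 1.0
                else:
                    partial[c, state_index[state]] = 1.0
            self.tips[self.index[id(n)]] = partial
        # unique branch lengths for batched propagators
        self.unique_ts, self.t_of_node = np.unique(
            self.lengths, return_inverse=True
        )

    def down_pass(self, Q: np.ndarray):
        """Partial likelihoods and per-character log scaling factors."""
        P = _Propagator(Q)(self.unique_ts)
        partials = [None] * len(self.nodes)
        log_scale = np.zeros(self.n_chars)
        for i, kids in enumerate(self.children):
            if not kids:
                partials[i] = self.tips[i]
                continue
            acc = np.ones((self.n_chars, self.k))
            for c in kids:
                acc *= partials[c] @ P[self.t_of_node[c]].T
            top = acc.max(axis=1)
            top[top == 0.0] = 1.0
            acc = acc / top[:, None]
            log_scale += np.log(top)
            partials[i] = acc
        return partials, log_scale, P

    def loglik(self, Q: np.ndarray, prior: np.ndarray) -> float:
        partials, log_scale, _ = self.down_pass(Q)
        site = partials[-1] @ prior  # root is last in postorder
        if np.any(site <= 0):
            return -np.inf
        return float(np.sum(np.log(site) + log_scale))


def _root_prior(prior, k: int) -> np.ndarray:
    if prior is None or (isinstance(prior, str) and prior == "uniform"):
        return np.full(k, 1.0 / k)
    prior = np.asarray(prior, dtype=float)
    if prior.shape != (k,) or np.any(prior < 0) or not np.isclose(prior.sum(), 1):
        raise ValidationError("root prior must be a length-k probability vector")
    return prior


def log_likelihood(
    tree: Tree, chars: CharacterMatrix, model: RateModel, root_prior="uniform"
) -> float:
    """Pruning-algorithm log likelihood (characters independent, summed)."""
    if model.k != chars.k:
        raise ValidationError("model and data disagree on the number of states")
    engine = _PruningEngine(tree, chars)
    return engine.loglik(model.generator, _root_prior(root_prior, model.k))


@dataclass
class ModelFit:
    model: RateModel
    log_likelihood: float
    converged: bool
    n_starts: int


def _start_rates(start: int, n: int) -> np.ndarray:
    rng = np.random.default_rng(start)  # seed = start index (deterministic)
    return 10.0 ** rng.uniform(-2.0, 1.0, size=n)


def fit_model(
    tree: Tree,
    chars: CharacterMatrix,
    kind: str,
    n_starts: int = 5,
    root_prior="uniform",
) -> ModelFit:
    """Maximize the Mk likelihood over positive rates.

    Rates are optimized in log space within [1e-8, 1e3] by L-BFGS-B.  The
    first start is the maximum-likelihood *equal-rates* point (found by a
    1-D bounded search), which makes the fitted likelihoods respect the
    ER <= SYM <= ARD nesting numerically; the remaining ``n_starts - 1``
    starts are deterministic random draws (seeds 1..n_starts-1).
    """
    k = chars.k
    npar = n_params(kind, k)
    engine = _PruningEngine(tree, chars)
    prior = _root_prior(root_prior, k)
    lo, hi = np.log(RATE_BOUNDS[0]), np.log(RATE_BOUNDS[1])

    def neg(logp):
        Q = _fill_generator(kind, k, np.exp(logp))
        return -engine.loglik(Q, prior)

    scalar = minimize_scalar(
        lambda x: neg(np.full(npar, x)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    best = None
    any_ok = False
    for start in range(n_starts):
        if start == 0:
            x0 = np.full(npar, float(scalar.x))
        else:
            x0 = np.clip(np.log(_start_rates(start, npar)), lo, hi)
        res = minimize(
            neg,
            x0,
            method="L-BFGS-B",
            bounds=[(lo, hi)] * npar,
            options={"ftol": 1e-12, "gtol": 1e-9, "maxiter": 500},
        )
        any_ok = any_ok or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    rates = np.exp(best.x)
    fit = ModelFit(
        model=build_rate_matrix(kind, k, rates),
        log_likelihood=-float(best.fun),
        converged=any_ok,
        n_starts=n_starts,
    )
    if not any_ok:
        raise ConvergenceError(
            f"no {kind} start converged ({n_starts} starts)", best_fit=fit
        )
    return fit


@dataclass
class LRTResult:
    statistic: float
    df: int
    p: float
    nested_kind: str
    general_kind: str


def likelihood_ratio_test(nested_fit: ModelFit, general_fit: ModelFit) -> LRTResult:
    """Chi-square LRT between nested Mk parameterizations (ER < SYM < ARD)."""
    order = {kind: i for i, kind in enumerate(_KINDS)}
    nk, gk = nested_fit.model.kind, general_fit.model.kind
    if order[nk] >= order[gk]:
        raise ValidationError(f"{nk} is not nested within {gk}")
    if nested_fit.model.k != general_fit.model.k:
        raise ValidationError("fits have different state counts")
    k = nested_fit.model.k
    df = n_params(gk, k) - n_params(nk, k)
    if df == 0:  # e.g. ER vs SYM at k=2: the same parameterization
        raise ValidationError(
            f"{nk} and {gk} coincide for k={k} (no extra parameters to test)"
        )
    stat = max(0.0, 2.0 * (general_fit.log_likelihood - nested_fit.log_likelihood))
    return LRTResult(
        statistic=stat, df=df, p=float(chi2.sf(stat, df)), nested_kind=nk,
        general_kind=gk,
    )


@dataclass
class ASRResult:
    """Scaled marginal likelihoods: node clade -> (n_chars, k) array, rows
    summing to 1."""

    node_likelihoods: dict  # frozenset(clade) -> np.ndarray
    model: RateModel
    log_likelihood: float
    alphabet: list


def marginal_asr(
    tree: Tree, chars: CharacterMatrix, model: RateModel, root_prior="uniform"
) -> ASRResult:
    """Per-internal-node marginal likelihood of each state given all tips.

    Combines the down-pass partials from each node's subtree with an
    up-pass carrying the likelihood contribution of the rest of the tree,
    then normalizes per node and character.
    """
    if model.k != chars.k:
        raise ValidationError("model and data disagree on the number of states")
    engine = _PruningEngine(tree, chars)
    prior = _root_prior(root_prior, model.k)
    partials, log_scale, P = engine.down_pass(model.generator)

    n = len(engine.nodes)
    ups = [None] * n
    root_idx = n - 1
    ups[root_idx] = np.broadcast_to(prior, (engine.n_chars, model.k)).copy()
    site = partials[root_idx] @ prior
    total_ll = float(np.sum(np.log(site) + log_scale))

    # preorder = reversed postorder for this node ordering
    for i in range(n - 1, -1, -1):
        kids = engine.children[i]
        if not kids:
            continue
        for c in kids:
            sib = np.ones_like(ups[i])
            for other in kids:
                if other != c:
                    sib *= partials[other] @ P[engine.t_of_node[other]].T
            ups[c] = (ups[i] * sib) @ P[engine.t_of_node[c]]

    clades = {}
    for node, clade in tree.clades(include_leaves=False):
        i = engine.index[id(node)]
        joint = partials[i] * ups[i]
        norm = joint.sum(axis=1, keepdims=True)
        clades[clade] = joint / norm
    return ASRResult(
        node_likelihoods=clades,
        model=model,
        log_likelihood=total_ll,
        alphabet=list(chars.alphabet),
    )
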