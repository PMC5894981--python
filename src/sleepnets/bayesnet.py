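"""Discrete Bayesian-network engine.

Everything here is written from first principles for fully discrete
variables: maximum-likelihood / Dirichlet-smoothed CPT estimation, the BIC
score, K2 ordered greedy structure search, exact inference by enumeration,
and ancestral sampling.  Variable counts stay small (a dozen or so, with
cardinalities of at most five), so enumeration over the unobserved joint is
always tractable.

Structural zeros
----------------
Bouts are maximal runs, so a stage variable can never equal the stage
variable at the adjacent lag.  Such "never equal" constraints are declared
as variable pairs; they mask impossible child cells (probability exactly 0)
and exclude impossible parent configurations from the free-parameter count
of the BIC penalty.

Scoring uses MLE parameters; prediction and inference default to a uniform
Dirichlet prior (pseudo-count 1), an uninformed prior that adds no bias.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .datapoints import ADJACENT_STAGE_PAIRS, VARIABLE_CARDS

Constraint = tuple[str, str]  # the two variables may never take equal values

_EPS = 1e-12
_TOL = 1e-9  # strict-improvement threshold in greedy search


def stage_constraints(variables: list[str]) -> list[Constraint]:
    """The adjacent-lag never-equal constraints active among ``variables``."""
    vs = set(variables)
    return [p for p in ADJACENT_STAGE_PAIRS if p[0] in vs and p[1] in vs]


@dataclass(frozen=True)
class VariableSpec:
    name: str
    cardinality: int
    labels: tuple[str, ...] = ()

    def __post_init__(self):
        if self.cardinality < 2:
            raise ValueError(f"{self.name}: cardinality must be >= 2")
        if self.labels and len(set(self.labels)) != self.cardinality:
            raise ValueError(f"{self.name}: labels must be unique, one per category")


@dataclass
class NetworkStructure:
    """Node order, cardinalities and parent sets; parents always precede
    their child in the order (the K2 constraint), which also guarantees
    acyclicity."""

    order: list[str]
    cards: dict[str, int]
    parents: dict[str, list[str]] = field(default_factory=dict)
    constraints: list[Constraint] = field(default_factory=list)

    def __post_init__(self):
        if len(set(self.order)) != len(self.order):
            raise ValueError("invalid order: duplicate variables")
        pos = {v: i for i, v in enumerate(self.order)}
        for v in self.order:
            self.parents.setdefault(v, [])
        for child, ps in self.parents.items():
            for p in ps:
                if pos[p] >= pos[child]:
                    raise ValueError(f"parent {p} does not precede child {child}")

    def edges(self) -> set[tuple[str, str]]:
        return {(p, c) for c, ps in self.parents.items() for p in ps}

    def to_dict(self) -> dict:
        return {"order": list(self.order), "cards": dict(self.cards),
                "parents": {k: list(v) for k, v in self.parents.items()},
                "constraints": [list(c) for c in self.constraints]}

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkStructure":
        return cls(order=list(d["order"]), cards=dict(d["cards"]),
                   parents={k: list(v) for k, v in d["parents"].items()},
                   constraints=[tuple(c) for c in d.get("constraints", [])])


def _grids(cards: list[int]) -> list[np.ndarray]:
    return list(np.indices(cards)) if cards else []


def _family_masks(child: str, parents: list[str], cards: dict[str, int],
                  constraints: list[Constraint]
                  ) -> tuple[np.ndarray, np.ndarray]:
    """(cell mask over (*parent_cards, child_card), parent-config validity).

    A cell is masked (False) when a never-equal constraint between the child
    and a parent is violated; a parent configuration is invalid when two
    parents bound by a constraint are equal.
    """
    pc = [cards[p] for p in parents]
    cc = cards[child]
    mask = np.ones(tuple(pc) + (cc,), dtype=bool)
    config_valid = np.ones(tuple(pc), dtype=bool)
    if constraints:
        pgrid = _grids(pc)
        cgrid = np.arange(cc)
        for a, b in constraints:
            if child in (a, b):
                other = b if a == child else a
                if other in parents:
                    i = parents.index(other)
                    eq = pgrid[i][..., None] == cgrid  # broadcast over child axis
                    mask &= ~eq
            elif a in parents and b in parents:
                ia, ib = parents.index(a), parents.index(b)
                config_valid &= pgrid[ia] != pgrid[ib]
    return mask, config_valid


def _family_counts(data: pd.DataFrame, child: str, parents: list[str],
                   cards: dict[str, int]) -> np.ndarray:
    dims = [cards[p] for p in parents] + [cards[child]]
    cols = [data[p].to_numpy() for p in parents] + [data[child].to_numpy()]
    flat = np.ravel_multi_index(cols, dims) if len(dims) > 1 else cols[0]
    return np.bincount(flat, minlength=int(np.prod(dims))).reshape(dims)


def _free_parameters(mask: np.ndarray, config_valid: np.ndarray) -> int:
    per_row = mask.reshape(-1, mask.shape[-1]).sum(axis=1) - 1
    per_row = np.maximum(per_row, 0)
    return int(per_row[config_valid.reshape(-1)].sum())


@dataclass
class CPT:
    """Conditional probability table of one variable given its parents.

    ``probs`` has shape (*parent_cardinalities, child_cardinality); each
    structurally valid row sums to 1 over unmasked cells and masked cells
    are exactly 0."""

    child: str
    parents: list[str]
    probs: np.ndarray
    mask: np.ndarray
    config_valid: np.ndarray

    @property
    def n_free_parameters(self) -> int:
        return _free_parameters(self.mask, self.config_valid)


def fit_cpt(data: pd.DataFrame, child: str, parents: list[str],
            cards: dict[str, int], constraints: list[Constraint],
            pseudo_count: float) -> CPT:
    mask, config_valid = _family_masks(child, parents, cards, constraints)
    counts = _family_counts(data, child, parents, cards).astype(float)
    counts += pseudo_count * mask
    counts *= mask  # structural zeros stay exactly 0
    totals = counts.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(totals > 0, counts / np.maximum(totals, _EPS), 0.0)
    return CPT(child=child, parents=list(parents), probs=probs,
               mask=mask, config_valid=config_valid)


@dataclass
class DiscreteBayesianNetwork:
    """A structure plus fitted CPTs; supports exact inference by enumeration
    and ancestral sampling."""

    structure: NetworkStructure
    cpts: dict[str, CPT]
    n_train: int
    pseudo_count: float

    # -- inference ---------------------------------------------------------
    def posterior(self, target: str, evidence: dict[str, int] | None = None
                  ) -> np.ndarray:
        """Exact posterior P(target | evidence) by enumeration over the
        unobserved joint.  With no evidence this is the marginal."""
        evidence = dict(evidence or {})
        cards = self.structure.cards
        if target not in cards:
            raise ValueError(f"unknown target {target!r}")
        if target in evidence:
            raise ValueError("target cannot appear in evidence")
        for v, val in evidence.items():
            if v not in cards:
                raise ValueError(f"unknown evidence variable {v!r}")
            if not (0 <= int(val) < cards[v]):
                raise ValueError(f"invalid evidence: {v}={val}")
        unobs = [v for v in self.structure.order if v not in evidence]
        axis = {v: i for i, v in enumerate(unobs)}
        shape = tuple(cards[v] for v in unobs)
        joint = np.ones(shape)
        for child, cpt in self.cpts.items():
            fam = cpt.parents + [child]
            idx = tuple(int(evidence[v]) if v in evidence else slice(None)
                        for v in fam)
            sub = cpt.probs[idx]
            free = [v for v in fam if v not in evidence]
            # put this factor's free dims into global axis order, pad with 1s
            perm = np.argsort([axis[v] for v in free])
            sub = np.transpose(sub, perm) if sub.ndim > 1 else sub
            bshape = [1] * len(unobs)
            for v in free:
                bshape[axis[v]] = cards[v]
            joint = joint * sub.reshape(bshape)
        sum_axes = tuple(i for v, i in axis.items() if v != target)
        vec = joint.sum(axis=sum_axes) if sum_axes else joint
        total = vec.sum()
        if total <= 0:
            raise ValueError("impossible evidence")
        return vec / total

    def posterior_batch(self, target: str, evidence: pd.DataFrame) -> np.ndarray:
        """Posterior for each row of an evidence table (deduplicated: the
        enumeration runs once per unique configuration)."""
        cols = [c for c in evidence.columns if c in self.structure.cards
                and c != target]
        arr = evidence[cols].to_numpy()
        uniq, inv = np.unique(arr, axis=0, return_inverse=True)
        out = np.empty((len(uniq), self.structure.cards[target]))
        for i, row in enumerate(uniq):
            out[i] = self.posterior(target, dict(zip(cols, (int(v) for v in row))))
        return out[inv]

    # -- generation --------------------------------------------------------
    def sample(self, n: int, seed: int | np.random.Generator = 0) -> pd.DataFrame:
        """Ancestral sampling in node order; reproducible given seed."""
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        out: dict[str, np.ndarray] = {}
        for v in self.structure.order:
            cpt = self.cpts[v]
            if cpt.parents:
                rows = cpt.probs[tuple(out[p] for p in cpt.parents)]
            else:
                rows = np.broadcast_to(cpt.probs, (n, len(cpt.probs)))
            totals = rows.sum(axis=1)
            if n and not np.all(totals > 0):
                raise ValueError("cannot sample: reached an all-zero CPT row")
            cdf = np.cumsum(rows / totals[:, None], axis=1)
            u = rng.random(n)
            out[v] = np.minimum((u[:, None] > cdf).sum(axis=1),
                                rows.shape[1] - 1).astype(np.int64)
        return pd.DataFrame(out)

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "structure": self.structure.to_dict(),
            "n_train": self.n_train,
            "pseudo_count": self.pseudo_count,
            # rows flattened row-major over parent configurations in node order
            "cpts": {v: cpt.probs.reshape(-1, cpt.probs.shape[-1]).tolist()
                     for v, cpt in self.cpts.items()},
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "DiscreteBayesianNetwork":
        structure = NetworkStructure.from_dict(d["structure"])
        cpts = {}
        for child, flat in d["cpts"].items():
            parents = structure.parents[child]
            mask, config_valid = _family_masks(
                child, parents, structure.cards, structure.constraints)
            probs = np.asarray(flat, float).reshape(mask.shape)
            cpts[child] = CPT(child, list(parents), probs, mask, config_valid)
        return cls(structure=structure, cpts=cpts,
                   n_train=int(d["n_train"]),
                   pseudo_count=float(d["pseudo_count"]))


def fit_parameters(structure: NetworkStructure, data: pd.DataFrame,
                   pseudo_count: float = 1.0) -> DiscreteBayesianNetwork:
    """Estimate every CPT: row = (count + pseudo_count) / total over
    unmasked cells.  pseudo_count 0 gives the MLE (used for scoring);
    the default 1 is a uniform Dirichlet prior for prediction."""
    for v in structure.order:
        if v not in data.columns:
            raise ValueError(f"missing variable {v!r} in data")
    cpts = {
        v: fit_cpt(data, v, structure.parents[v], structure.cards,
                   structure.constraints, pseudo_count)
        for v in structure.order
    }
    return DiscreteBayesianNetwork(structure=structure, cpts=cpts,
                                   n_train=len(data),
                                   pseudo_count=pseudo_count)


def family_bic(data: pd.DataFrame, child: str, parents: list[str],
               cards: dict[str, int], constraints: list[Constraint]) -> float:
    """BIC contribution of one family: maximised log-likelihood minus
    (ln N / 2) x free parameters.  Decomposable, so the K2 search only
    rescores the family it is modifying."""
    n = len(data)
    if n == 0:
        raise ValueError("no data")
    mask, config_valid = _family_masks(child, parents, cards, constraints)
    counts = _family_counts(data, child, parents, cards).astype(float)
    totals = counts.sum(axis=-1, keepdims=True)
    pos = counts > 0
    ll = float(np.sum(counts[pos] * np.log(counts[pos]
                                           / np.broadcast_to(totals, counts.shape)[pos])))
    penalty = 0.5 * np.log(n) * _free_parameters(mask, config_valid)
    return ll - penalty


def bic_score(structure: NetworkStructure, data: pd.DataFrame) -> float:
    """Network BIC (higher, i.e. closer to zero, is better)."""
    return sum(
        family_bic(data, v, structure.parents[v], structure.cards,
                   structure.constraints)
        for v in structure.order
    )


def k2_search(data: pd.DataFrame, node_order: list[str],
              cards: dict[str, int] | None = None,
              constraints: list[Constraint] | None = None,
              max_parents: int | None = None) -> NetworkStructure:
    """K2 ordered greedy hill climbing under the BIC score.

    For each variable in order, repeatedly add the single preceding
    variable whose addition most improves the family BIC; stop when no
    addition improves (strictly) or ``max_parents`` is reached.
    Deterministic: ties go to the earliest candidate in the node order.
    """
    if len(set(node_order)) != len(node_order):
        raise ValueError("invalid order: duplicate variables")
    cards = cards or {v: VARIABLE_CARDS.get(v, max(2, int(data[v].max()) + 1))
                      for v in node_order}
    constraints = (stage_constraints(node_order) if constraints is None
                   else constraints)
    if len(data) == 0:
        raise ValueError("no data")
    cap = max_parents if max_parents is not None else len(node_order)
    parents: dict[str, list[str]] = {}
    for i, child in enumerate(node_order):
        chosen: list[str] = []
        best = family_bic(data, child, chosen, cards, constraints)
        candidates = node_order[:i]
        while len(chosen) < cap:
            gain_best, pick = _TOL, None
            for cand in candidates:
                if cand in chosen:
                    continue
                s = family_bic(data, child, chosen + [cand], cards, constraints)
                if s - best > gain_best:
                    gain_best, pick = s - best, cand
            if pick is None:
                break
            chosen.append(pick)
            best += gain_best
        parents[child] = chosen
    return NetworkStructure(order=list(node_order), cards=dict(cards),
                            parents=parents, constraints=list(constraints))


# ---------------------------------------------------------------------------
# scikit-learn estimator


class BayesianNetworkClassifier(ClassifierMixin, BaseEstimator):
    """Predict one discrete sleep variable from the others with a
    structure-learned Bayesian network.

    ``fit(X, y)`` joins the target back onto the evidence table, runs the
    K2 search over the model's node order (unless a fixed structure is
    supplied), and fits Dirichlet-smoothed CPTs.  ``predict_proba`` is the
    exact posterior over the target given each row's evidence.

    Parameters
    ----------
    target : name of the predicted variable (default ``"stage_t"``).
    node_order : K2 ordering over all variables incl. the target; defaults
        to the package-wide causal ordering restricted to the columns seen.
    max_parents : optional cap on parents per variable (the BIC penalty is
        otherwise self-limiting).
    pseudo_count : Dirichlet pseudo-count for prediction CPTs (scoring
        always uses the MLE).
    structure : optional pre-learned :class:`NetworkStructure`; skips the
        search.

    Attributes
    ----------
    network_ : the fitted :class:`DiscreteBayesianNetwork`.
    structure_ : its :class:`NetworkStructure`.
    classes_ : integer category codes of the target.
    """

    def __init__(self, target: str = "stage_t", node_order: list[str] | None = None,
                 max_parents: int | None = None, pseudo_count: float = 1.0,
                 structure: NetworkStructure | None = None):
        self.target = target
        self.node_order = node_order
        self.max_parents = max_parents
        self.pseudo_count = pseudo_count
        self.structure = structure

    def _order(self, columns: list[str]) -> list[str]:
        if self.node_order is not None:
            return list(self.node_order)
        from .models import FULL_NODE_ORDER
        known = [v for v in FULL_NODE_ORDER if v in columns]
        extra = [c for c in columns if c not in FULL_NODE_ORDER]
        return extra + known

    def fit(self, X: pd.DataFrame, y) -> "BayesianNetworkClassifier":
        y = np.asarray(y)
        cols = [c for c in X.columns if c in VARIABLE_CARDS or
                (self.node_order and c in self.node_order)]
        data = X[cols].copy()
        data[self.target] = y
        if (data.to_numpy() < 0).any():
            raise ValueError("training data contains missing (-1) codes; "
                             "filter to complete cases first")
        order = self._order(list(data.columns))
        if self.structure is not None:
            self.structure_ = self.structure
        else:
            self.structure_ = k2_search(data, order,
                                        max_parents=self.max_parents)
        self.network_ = fit_parameters(self.structure_, data,
                                       pseudo_count=self.pseudo_count)
        self.classes_ = np.arange(self.network_.structure.cards[self.target])
        self.n_features_in_ = X.shape[1]
        self.evidence_vars_ = [v for v in order if v != self.target]
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "network_"):
            raise ValueError("classifier is not fitted")
        ev = X[[v for v in self.evidence_vars_ if v in X.columns]]
        return self.network_.posterior_batch(self.target, ev)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        # ties broken towards the lowest category index (np.argmax)
        return self.predict_proba(X).argmax(axis=1)


# ---------------------------------------------------------------------------
# random networks for simulation studies


def random_network(rng: np.random.Generator, n_vars: int = 6,
                   card: int = 3, p_edge: float = 0.4,
                   max_parents: int = 2, concentration: float = 0.25,
                   min_effect: float = 0.2) -> DiscreteBayesianNetwork:
    """A random DAG (in a fixed topological order) with spiky Dirichlet
    CPTs whose parent effects are bounded away from independence: each
    parent must shift its child's conditional distribution by at least
    ``min_effect`` in total-variation distance somewhere in the table."""
    order = [f"X{i}" for i in range(n_vars)]
    cards = {v: card for v in order}
    parents: dict[str, list[str]] = {order[0]: []}
    for i in range(1, n_vars):
        pool = [order[j] for j in range(i) if rng.random() < p_edge]
        rng.shuffle(pool)
        parents[order[i]] = sorted(pool[:max_parents], key=order.index)
    structure = NetworkStructure(order=order, cards=cards, parents=parents)
    cpts = {}
    for v in order:
        ps = parents[v]
        shape = tuple(cards[p] for p in ps) + (card,)
        for _ in range(200):
            probs = rng.dirichlet([concentration] * card,
                                  size=int(np.prod(shape[:-1], dtype=int))
                                  ).reshape(shape)
            probs = np.maximum(probs, 0.01)
            probs /= probs.sum(axis=-1, keepdims=True)
            if _parents_effective(probs, len(ps), min_effect):
                break
        mask = np.ones(shape, bool)
        cpts[v] = CPT(v, list(ps), probs, mask, np.ones(shape[:-1], bool))
    return DiscreteBayesianNetwork(structure=structure, cpts=cpts,
                                   n_train=0, pseudo_count=0.0)


def _parents_effective(probs: np.ndarray, n_parents: int, min_effect: float) -> bool:
    for axis in range(n_parents):
        rows = np.moveaxis(probs, axis, 0)
        rows = rows.reshape(rows.shape[0], -1, probs.shape[-1])
        tv = 0.5 * np.abs(rows[:, None] - rows[None]).sum(axis=-1)
        if tv.max(axis=(0, 1)).min() < min_effect:
            return False
    return True
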