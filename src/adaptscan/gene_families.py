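"""Gene-family expansion and contraction under a birth-death model.

Each family's copy number evolves along an ultrametric species tree (in
million years) by a linear birth-death process with equal per-gene birth
and death rates lambda.  With alpha = lambda*t / (1 + lambda*t), the
transition probability from i to j copies over a branch of duration t is

    P(j | i) = sum_{k=0}^{min(i,j)} C(i,k) C(i+j-k-1, i-1)
               alpha^(i+j-2k) (1-2*alpha)^k        (i >= 1)

with extinction absorbing (P(0|0) = 1).  The two-lambda model gives the
focal terminal branch its own rate.  Families are filtered with the
usual two rules before fitting: any species with more than ``copy_cap``
copies (annotation artifacts dominate such families), and families whose
members all fall in a single child clade of the root (their birth cannot
be dated on the tree).

Ancestral copy numbers are joint maximum-likelihood states from a
max-product pruning pass; a family counts as "highly" changed when it
changed on the focal branch and the focal species holds more than
``high_threshold`` copies (an |delta| rule is available by flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln

from .divergence import TreeError
from .io_formats import ConfigurationError


class ParameterError(ValueError):
    pass


@dataclass
class BirthDeathModel:
    """Per-branch-class birth-death rates over a compiled tree partition."""

    lambdas: dict[int, float]  # class -> rate (events/gene/My)
    n_max: int
    partition: str = "focal_vs_rest"

    def __post_init__(self) -> None:
        for cls, lam in self.lambdas.items():
            if lam <= 0:
                raise ParameterError(f"lambda for class {cls} must be positive")


@dataclass
class FamilyEvolutionResult:
    family_id: str
    ancestral_counts: dict[str, int]
    delta: int
    direction: str  # expanded | contracted | unchanged
    highly_changed: bool
    focal_count: int = 0
    parent_count: int = 0


# ---------------------------------------------------------------------------
# Transition probabilities


def bd_alpha(lam: float, t: float) -> float:
    if lam <= 0 or t <= 0:
        raise ParameterError("lambda and t must be positive")
    alpha = lam * t / (1.0 + lam * t)
    if alpha >= 0.5:
        raise ParameterError(
            f"alpha = {alpha:.4f} >= 1/2 (lambda*t = {lam * t:.4f} too large)"
        )
    return alpha


def bd_transition_prob(i: int, j: int, lam: float, t: float) -> float:
    """P(j child copies | i parent copies) over duration t."""
    alpha = bd_alpha(lam, t)
    if i == 0:
        return 1.0 if j == 0 else 0.0
    k = np.arange(min(i, j) + 1)
    logbin = gammaln(i + 1) - gammaln(k + 1) - gammaln(i - k + 1)
    logbin += gammaln(i + j - k) - gammaln(i) - gammaln(j - k + 1)
    terms = np.exp(logbin) * alpha ** (i + j - 2 * k) * (1 - 2 * alpha) ** k
    return float(terms.sum())


def bd_transition_matrix(lam: float, t: float, n_max: int) -> np.ndarray:
    """(n_max+1) x (n_max+1) matrix of P(j|i); row 0 is the absorbing state."""
    alpha = bd_alpha(lam, t)
    N = n_max
    P = np.zeros((N + 1, N + 1))
    P[0, 0] = 1.0
    j = np.arange(N + 1)
    for i in range(1, N + 1):
        k = np.arange(min(i, N) + 1)
        # terms[k, j]; invalid k > min(i, j) get -inf log-binomials
        with np.errstate(invalid="ignore"):
            logbin = (
                gammaln(i + 1)
                - gammaln(k + 1)
                - gammaln(i - k + 1)
            )[:, None] + (
                gammaln(i + j[None, :] - k[:, None])
                - gammaln(i)
                - gammaln(j[None, :] - k[:, None] + 1)
            )
        valid = k[:, None] <= np.minimum(i, j[None, :])
        power = i + j[None, :] - 2 * k[:, None]
        terms = np.where(
            valid,
            np.exp(logbin) * alpha ** power * (1 - 2 * alpha) ** k[:, None],
            0.0,
        )
        P[i] = terms.sum(axis=0)
    return P


# ---------------------------------------------------------------------------
# Tree compilation


@dataclass
class _CompiledUltrametric:
    postorder: list  # (node_idx, [(child_idx, edge_idx)])
    tip_species: dict[int, str]
    edge_duration: np.ndarray
    edge_class: np.ndarray
    root: int
    node_labels: dict[int, str]
    focal_edge: int | None


def compile_ultrametric(
    tree: dendropy.Tree, focal: str | None = None, tol: float = 1e-6
) -> _CompiledUltrametric:
    """Index a rooted ultrametric tree; branch classes split focal vs rest."""
    nodes = list(tree.preorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    depths: dict[int, float] = {index[id(tree.seed_node)]: 0.0}
    postorder = []
    tip_species: dict[int, str] = {}
    node_labels: dict[int, str] = {}
    edge_duration: list[float] = []
    edge_class: list[int] = []
    focal_edge = None
    children_of: dict[int, list[tuple[int, int]]] = {}
    for node in nodes:
        i = index[id(node)]
        node_labels[i] = (
            node.taxon.label if node.taxon else f"node{i}"
        )
        if node.is_leaf():
            tip_species[i] = node.taxon.label
        children_of[i] = []
        for child in node.child_nodes():
            if child.edge.length is None:
                raise TreeError("ultrametric tree has an edge without length")
            jdx = index[id(child)]
            depths[jdx] = depths[i] + child.edge.length
            eidx = len(edge_duration)
            edge_duration.append(float(child.edge.length))
            is_focal = child.is_leaf() and focal is not None and (
                child.taxon.label == focal
            )
            edge_class.append(1 if is_focal else 0)
            if is_focal:
                focal_edge = eidx
            children_of[i].append((jdx, eidx))
    tip_depths = {i: depths[i] for i in tip_species}
    dmax = max(tip_depths.values())
    for i, d in tip_depths.items():
        if abs(d - dmax) > tol * max(dmax, 1.0):
            raise TreeError(
                f"tree is not ultrametric: tip {tip_species[i]!r} has depth "
                f"{d:.6g} vs {dmax:.6g}"
            )
    if focal is not None and focal_edge is None:
        raise ConfigurationError(f"focal species {focal!r} not a tip of the tree")
    for node in reversed(nodes):  # reversed preorder = a valid postorder
        i = index[id(node)]
        if i not in tip_species:
            postorder.append((i, children_of[i]))
    return _CompiledUltrametric(
        postorder=postorder,
        tip_species=tip_species,
        edge_duration=np.array(edge_duration),
        edge_class=np.array(edge_class),
        root=index[id(tree.seed_node)],
        node_labels=node_labels,
        focal_edge=focal_edge,
    )


# ---------------------------------------------------------------------------
# Filtering


def filter_families(
    table: pd.DataFrame,
    tree: dendropy.Tree,
    copy_cap: int = 100,
    clade_rule: str = "root_clades",
) -> pd.DataFrame:
    """Drop families failing the copy cap or present in only one root clade.

    ``clade_rule='single_species'`` instead drops families whose copies
    all sit in one species.
    """
    keep = np.ones(len(table), dtype=bool)
    keep &= ~(table.values > copy_cap).any(axis=1)
    if clade_rule == "root_clades":
        root_children = tree.seed_node.child_nodes()
        clades = [
            {l.taxon.label for l in child.leaf_iter()} for child in root_children
        ]
        for r, (fam, row) in enumerate(table.iterrows()):
            present = {sp for sp, n in row.items() if n > 0}
            if not present:
                keep[r] = False
                continue
            if any(present <= clade for clade in clades):
                keep[r] = False
    elif clade_rule == "single_species":
        keep &= (table.values > 0).sum(axis=1) > 1
    else:
        raise ConfigurationError(f"unknown clade rule {clade_rule!r}")
    return table.loc[keep]


# ---------------------------------------------------------------------------
# Likelihood


def _transition_stack(
    ct: _CompiledUltrametric, lambdas: dict[int, float], n_max: int
) -> list[np.ndarray]:
    cache: dict[tuple[float, float], np.ndarray] = {}
    stack = []
    for dur, cls in zip(ct.edge_duration, ct.edge_class):
        lam = lambdas[int(cls)]
        key = (lam, dur)
        if key not in cache:
            cache[key] = bd_transition_matrix(lam, dur, n_max)
        stack.append(cache[key])
    return stack


def _root_prior(n_max: int) -> np.ndarray:
    prior = np.ones(n_max + 1) / n_max
    prior[0] = 0.0  # a family observed at the tips existed at the root
    return prior


def table_log_likelihoods(
    table: pd.DataFrame,
    tree_or_compiled,
    model: BirthDeathModel,
    focal: str | None = None,
) -> np.ndarray:
    """Per-family log-likelihood, vectorized over the whole table."""
    ct = (
        tree_or_compiled
        if isinstance(tree_or_compiled, _CompiledUltrametric)
        else compile_ultrametric(tree_or_compiled, focal)
    )
    n_max = model.n_max
    if (table.values > n_max).any():
        raise ParameterError("a family count exceeds the model's state cap")
    P = _transition_stack(ct, model.lambdas, n_max)
    F = len(table)
    counts = {sp: table[sp].to_numpy() for sp in table.columns}
    partial: dict[int, np.ndarray] = {}
    logscale = np.zeros(F)
    for node, children in ct.postorder:
        L = np.ones((F, n_max + 1))
        for child, eidx in children:
            if child in ct.tip_species:
                sp = ct.tip_species[child]
                contrib = P[eidx][:, counts[sp]].T  # (F, n_max+1)
            else:
                contrib = partial.pop(child) @ P[eidx].T
            L *= contrib
        m = L.max(axis=1)
        m = np.where(m > 0, m, 1.0)
        L /= m[:, None]
        logscale += np.log(m)
        partial[node] = L
    lik = partial[ct.root] @ _root_prior(n_max)
    return np.log(np.maximum(lik, 1e-300)) + logscale


def family_log_likelihood(
    counts: dict[str, int] | pd.Series,
    tree: dendropy.Tree,
    model: BirthDeathModel,
    focal: str | None = None,
) -> float:
    """Log-likelihood of one family's counts."""
    df = pd.DataFrame([dict(counts)])
    return float(table_log_likelihoods(df, tree, model, focal)[0])


# ---------------------------------------------------------------------------
# Fitting


def fit_lambdas(
    table: pd.DataFrame,
    tree: dendropy.Tree,
    focal: str | None = None,
    two_lambda: bool = True,
    n_max: int | None = None,
) -> BirthDeathModel:
    """Maximum-likelihood birth-death rate(s) for a filtered count table.

    Two classes by default: the focal terminal branch vs everything else.
    The search is bounded so alpha < 1/2 on every branch.
    """
    if two_lambda and focal is None:
        raise ConfigurationError("two-lambda fitting needs a focal species")
    ct = compile_ultrametric(tree, focal if two_lambda else None)
    if n_max is None:
        n_max = int(table.values.max()) + 20
    classes = sorted(set(ct.edge_class.tolist())) if two_lambda else [0]
    lam_upper = []
    for cls in classes:
        tmax = ct.edge_duration[ct.edge_class == cls].max() if two_lambda else (
            ct.edge_duration.max()
        )
        lam_upper.append(0.999 / tmax)

    def obj(log_lams):
        lams = {cls: float(np.exp(ll)) for cls, ll in zip(classes, log_lams)}
        if not two_lambda:
            lams = {0: lams[0], 1: lams[0]}
        model = BirthDeathModel(lambdas=lams, n_max=n_max)
        return -float(table_log_likelihoods(table, ct, model).sum())

    x0 = np.log(np.full(len(classes), 0.001))
    bounds = [(np.log(1e-7), np.log(u)) for u in lam_upper]
    res = minimize(obj, x0, method="L-BFGS-B", bounds=bounds)
    if not res.success and not np.isfinite(res.fun):
        raise RuntimeError(f"lambda fit failed to converge: {res.message}")
    lams = {cls: float(np.exp(v)) for cls, v in zip(classes, res.x)}
    if not two_lambda:
        lams = {0: lams[0], 1: lams[0]}
    model = BirthDeathModel(lambdas=lams, n_max=n_max)
    model.lnL = float(-res.fun)
    return model


# ---------------------------------------------------------------------------
# Ancestral states and classification


def classify_family(
    counts: dict[str, int] | pd.Series,
    tree: dendropy.Tree,
    model: BirthDeathModel,
    focal: str,
    high_threshold: int = 10,
    high_rule: str = "family_size",
    family_id: str = "",
) -> FamilyEvolutionResult:
    """Joint-ML ancestral counts and the focal-branch change call.

    Ties in the max-product pass resolve to the smaller count.
    ``high_rule='family_size'`` calls a changed family "highly" changed
    when the focal species holds more than ``high_threshold`` copies;
    ``'delta'`` requires |delta| > high_threshold instead.
    """
    counts = dict(counts)
    ct = compile_ultrametric(tree, focal)
    n_max = model.n_max
    P = _transition_stack(ct, model.lambdas, n_max)
    V: dict[int, np.ndarray] = {}
    back: dict[int, dict[int, np.ndarray]] = {}
    for node, children in ct.postorder:
        logV = np.zeros(n_max + 1)
        back[node] = {}
        for child, eidx in children:
            with np.errstate(divide="ignore"):
                logP = np.log(P[eidx])
            if child in ct.tip_species:
                score = logP[:, counts[ct.tip_species[child]]]
            else:
                score = logP + V[child][None, :]  # (i, j)
                back[node][child] = np.argmax(score, axis=1)
                score = score.max(axis=1)
            logV += score
        V[node] = logV
    with np.errstate(divide="ignore"):
        root_score = V[ct.root] + np.log(_root_prior(n_max))
    states: dict[int, int] = {ct.root: int(np.argmax(root_score))}
    for node, children in reversed(ct.postorder):
        for child, _ in children:
            if child in ct.tip_species:
                states[child] = counts[ct.tip_species[child]]
            else:
                states[child] = int(back[node][child][states[node]])
    ancestral = {
        ct.node_labels[i]: s for i, s in states.items() if i not in ct.tip_species
    }
    focal_tip = next(i for i, sp in ct.tip_species.items() if sp == focal)
    parent = next(
        node for node, children in ct.postorder
        if any(c == focal_tip for c, _ in children)
    )
    focal_count = counts[focal]
    parent_count = states[parent]
    delta = focal_count - parent_count
    direction = "expanded" if delta > 0 else "contracted" if delta < 0 else "unchanged"
    if direction == "unchanged":
        highly = False
    elif high_rule == "family_size":
        highly = focal_count > high_threshold
    elif high_rule == "delta":
        highly = abs(delta) > high_threshold
    else:
        raise ConfigurationError(f"unknown high-change rule {high_rule!r}")
    return FamilyEvolutionResult(
        family_id=family_id,
        ancestral_counts=ancestral,
        delta=int(delta),
        direction=direction,
        highly_changed=bool(highly),
        focal_count=int(focal_count),
        parent_count=int(parent_count),
    )


def analyze_families(
    table: pd.DataFrame,
    tree: dendropy.Tree,
    focal: str,
    copy_cap: int = 100,
    high_threshold: int = 10,
    two_lambda: bool = True,
    high_rule: str = "family_size",
) -> tuple[BirthDeathModel, list[FamilyEvolutionResult]]:
    """Filter, fit, and classify every family: the module's main entry."""
    filtered = filter_families(table, tree, copy_cap=copy_cap)
    model = fit_lambdas(filtered, tree, focal=focal, two_lambda=two_lambda)
    results = [
        classify_family(
            row, tree, model, focal,
            high_threshold=high_threshold, high_rule=high_rule, family_id=str(fam),
        )
        for fam, row in filtered.iterrows()
    ]
    return model, results
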