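"""Branch-site test for positive selection on a focal lineage.

The model is the classic branch-site codon mixture (model A): sites fall
into four classes {0, 1, 2a, 2b} with nonsynonymous/synonymous ratios

=====  ==================  ==================
class  background branches  foreground branch
=====  ==================  ==================
0      omega0 (< 1)         omega0
1      1                    1
2a     omega0               omega2 (>= 1)
2b     1                    omega2
=====  ==================  ==================

with proportions (p0, p1, p2*p0/(p0+p1), p2*p1/(p0+p1)), p2 = 1-p0-p1.
The null fixes omega2 = 1; the alternative frees it.  Twice the
log-likelihood difference is referred to a chi-square with 1 degree of
freedom (the conservative convention; the 50:50 boundary mixture is
available by flag), p-values are corrected across orthogroups by
Benjamini-Hochberg, and selected sites are located by Bayes Empirical
Bayes over a parameter grid.

The substitution process is a GY94-style codon model: single-nucleotide
exchanges at rate pi_j, multiplied by kappa for transitions and by the
class omega for nonsynonymous changes; codon frequencies are F3x4
estimated from the alignment.  Likelihoods use Felsenstein pruning over
the 61 sense codons with per-pattern scaling; the tree is traversed from
the focal tip's parent so the four site classes share the two background
prunings (omega0 and 1) and differ only in the foreground factor.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.linalg import eigh, expm
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .codons import (
    N_CODONS,
    NUCLEOTIDES,
    PAIR_I,
    PAIR_IS_SYNONYMOUS,
    PAIR_IS_TRANSITION,
    PAIR_J,
    SENSE_CODONS,
    encode_codon_sequence,
)
from .divergence import TreeError
from .io_formats import Alignment, ConfigurationError

logger = logging.getLogger(__name__)

_TINY = 1e-300


# ---------------------------------------------------------------------------
# Parameters and results


@dataclass
class CodonModelParams:
    """Parameters of the branch-site mixture (M0 uses ``omega0`` alone)."""

    kappa: float
    omega0: float
    omega2: float = 1.0
    p0: float = 1.0
    p1: float = 0.0

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not (0 < self.omega0):
            raise ValueError("omega0 must be positive")
        if not (0 <= self.p0 <= 1 and 0 <= self.p1 <= 1 and self.p0 + self.p1 <= 1 + 1e-12):
            raise ValueError("invalid class proportions")

    @property
    def proportions(self) -> np.ndarray:
        """(p0, p1, p2a, p2b); p2 is split proportionally to p0:p1."""
        p2 = max(0.0, 1.0 - self.p0 - self.p1)
        denom = self.p0 + self.p1
        if denom <= 0:
            return np.array([0.0, 0.0, p2, 0.0])
        return np.array(
            [self.p0, self.p1, p2 * self.p0 / denom, p2 * self.p1 / denom]
        )

    @property
    def background_omegas(self) -> np.ndarray:
        return np.array([self.omega0, 1.0, self.omega0, 1.0])

    @property
    def foreground_omegas(self) -> np.ndarray:
        return np.array([self.omega0, 1.0, self.omega2, self.omega2])


@dataclass
class ModelFit:
    model: str
    lnL: float
    params: CodonModelParams
    branch_scale: float
    converged: bool
    n_starts: int
    n_evals: int = 0


@dataclass
class BranchSiteFit:
    """Null/alternative branch-site fits and the derived test for one gene."""

    orthogroup_id: str
    lnL_null: float
    lnL_alt: float
    params_null: CodonModelParams
    params_alt: CodonModelParams
    stat: float
    pvalue: float
    qvalue: float | None = None
    beb_fg_posterior: np.ndarray | None = None
    selected_sites: list[int] = field(default_factory=list)  # 1-based codons
    positively_selected: bool | None = None
    converged: bool = True


# ---------------------------------------------------------------------------
# Rate matrix and transition probabilities


def f3x4_frequencies(aln: Alignment, pseudocount: float = 0.5) -> np.ndarray:
    """F3x4 codon frequencies: per-codon-position nucleotide frequencies.

    A pseudocount keeps every sense-codon frequency strictly positive;
    stop codons are excluded and the vector renormalized.
    """
    counts = np.full((3, 4), pseudocount)
    nt_index = {n: i for i, n in enumerate(NUCLEOTIDES)}
    for rec in aln.records:
        seq = rec.seq.upper()
        for i, ch in enumerate(seq):
            if ch in nt_index:
                counts[i % 3, nt_index[ch]] += 1
    pos_freq = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            pos_freq[0, nt_index[c[0]]]
            * pos_freq[1, nt_index[c[1]]]
            * pos_freq[2, nt_index[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    return pi / pi.sum()


def codon_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """GY94-style 61x61 rate matrix (unnormalized; diagonal = -row sum)."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if omega < 0:
        raise ValueError("omega must be non-negative")
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_CODONS,) or (pi <= 0).any():
        raise ValueError("pi must be 61 strictly positive frequencies")
    rates = pi[PAIR_J].copy()
    rates[PAIR_IS_TRANSITION] *= kappa
    rates[~PAIR_IS_SYNONYMOUS] *= omega
    Q = np.zeros((N_CODONS, N_CODONS))
    Q[PAIR_I, PAIR_J] = rates
    Q[np.diag_indices_from(Q)] = -Q.sum(axis=1)
    return Q


def substitution_rate(Q: np.ndarray, pi: np.ndarray) -> float:
    """Expected substitutions per unit time at stationarity: -sum pi_i Q_ii."""
    return float(-(pi * np.diag(Q)).sum())


def transition_matrix(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt) with tiny negative entries clamped to zero."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    P = expm(Q * t)
    if (P < -1e-12).any():
        raise FloatingPointError("transition matrix has large negative entries")
    return np.clip(P, 0.0, None)


class _Eig:
    """Spectral form of a reversible Q for fast P(t) over many branches."""

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        d = np.sqrt(pi)
        S = Q * d[:, None] / d[None, :]
        w, E = eigh((S + S.T) / 2.0, check_finite=False)
        self.w = w
        self.A = E / d[:, None]
        self.B = (E * d[:, None]).T
        self.rate = substitution_rate(Q, pi)

    def P(self, t: float) -> np.ndarray:
        out = (self.A * np.exp(self.w * t)) @ self.B
        np.maximum(out, 0.0, out=out)
        return out

    def P_batch(self, ts: np.ndarray) -> np.ndarray:
        ew = np.exp(np.outer(ts, self.w))  # (E, 61)
        out = np.matmul(self.A[None, :, :] * ew[:, None, :], self.B)
        np.maximum(out, 0.0, out=out)
        return out


# ---------------------------------------------------------------------------
# Likelihood engine


class CodonLikelihood:
    """Pruning likelihood for one codon alignment on one tree.

    When ``foreground`` is given it must be a tip label; the traversal is
    rooted at that tip's parent so class-specific foreground factors can
    be attached to shared background prunings.  Branch lengths are taken
    from the tree (expected substitutions per codon site after M0
    rescaling; see :func:`fit_m0`).
    """

    def __init__(
        self,
        aln: Alignment,
        tree: dendropy.Tree,
        foreground: str | None = None,
        pi: np.ndarray | None = None,
    ):
        if aln.alphabet != "codon":
            raise ConfigurationError("selection analysis needs a codon alignment")
        self.aln = aln
        self.pi = f3x4_frequencies(aln) if pi is None else np.asarray(pi, float)
        labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
        if labels != sorted(aln.ids):
            raise ConfigurationError(
                "tree tips and alignment rows disagree: "
                f"{sorted(set(labels) ^ set(aln.ids))}"
            )
        X = np.stack([encode_codon_sequence(r.seq) for r in aln.records])
        self.n_sites = X.shape[1]
        patterns, inverse, counts = np.unique(
            X, axis=1, return_inverse=True, return_counts=True
        )
        self.Xp = patterns  # (rows, n_patterns)
        self.pattern_of_site = inverse
        self.weights = counts.astype(float)
        self.row_of_id = {rid: i for i, rid in enumerate(aln.ids)}
        self.foreground = foreground
        self._compile(tree)
        self._eig_cache: dict[tuple[float, float], _Eig] = {}

    # -- tree compilation ---------------------------------------------------

    def _compile(self, tree: dendropy.Tree) -> None:
        nodes = list(tree.preorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        adj: dict[int, list[tuple[int, float]]] = defaultdict(list)
        tip_row: dict[int, int] = {}
        for node in nodes:
            i = index[id(node)]
            if node.is_leaf():
                tip_row[i] = self.row_of_id[node.taxon.label]
            for child in node.child_nodes():
                if child.edge.length is None:
                    raise TreeError(
                        "branch length absent on edge above "
                        f"{child.taxon.label if child.taxon else 'an internal node'}"
                    )
                j = index[id(child)]
                adj[i].append((j, float(child.edge.length)))
                adj[j].append((i, float(child.edge.length)))
        self.tip_row = tip_row
        fg_node = None
        if self.foreground is not None:
            leaf = tree.find_node_with_taxon_label(self.foreground)
            if leaf is None:
                raise ConfigurationError(
                    f"foreground tip {self.foreground!r} not in tree"
                )
            fg_node = index[id(leaf)]
            (root, self.base_fg_len), = adj[fg_node]
            self.fg_row = tip_row[fg_node]
        else:
            root = next(
                i for i in range(len(nodes)) if i not in tip_row and adj[i]
            )
            self.fg_row = None
            self.base_fg_len = 0.0
        # iterative DFS from the pruning root, excluding the foreground edge
        post: list[tuple[int, list[tuple[int, int]]]] = []
        edge_lens: list[float] = []
        edge_child: list[int] = []
        stack = [(root, -1, False)]
        children_of: dict[int, list[tuple[int, int]]] = defaultdict(list)
        order: list[tuple[int, int]] = []
        while stack:
            node, parent, done = stack.pop()
            if done:
                order.append((node, parent))
                continue
            stack.append((node, parent, True))
            for nbr, length in adj[node]:
                if nbr == parent or nbr == fg_node:
                    continue
                eidx = len(edge_lens)
                edge_lens.append(length)
                edge_child.append(nbr)
                children_of[node].append((nbr, eidx))
                stack.append((nbr, node, False))
        for node, _ in order:
            if node not in self.tip_row:
                post.append((node, children_of[node]))
        self.root = root
        self.postorder = post
        self.base_edge_lens = np.array(edge_lens)
        self.edge_child = edge_child
        # current branch lengths (updated by fit_m0)
        self.edge_lens = self.base_edge_lens.copy()
        self.fg_len = self.base_fg_len

    def set_branch_scale(self, scale: float) -> None:
        self.edge_lens = self.base_edge_lens * scale
        self.fg_len = self.base_fg_len * scale

    def set_branch_lengths(self, lens: np.ndarray, fg_len: float) -> None:
        self.edge_lens = np.asarray(lens, float)
        self.fg_len = float(fg_len)

    # -- pruning ------------------------------------------------------------

    def _eig(self, kappa: float, omega: float) -> _Eig:
        key = (kappa, omega)
        if key not in self._eig_cache:
            if len(self._eig_cache) > 256:
                self._eig_cache.clear()
            self._eig_cache[key] = _Eig(
                codon_rate_matrix(kappa, omega, self.pi), self.pi
            )
        return self._eig_cache[key]

    def _tip_factor(self, P: np.ndarray, row: int) -> np.ndarray:
        x = self.Xp[row]
        contrib = P[:, np.clip(x, 0, None)]
        return np.where(x >= 0, contrib, 1.0)

    def _root_partial(self, Pstack: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Partial likelihoods at the pruning root, foreground edge excluded."""
        nP = self.Xp.shape[1]
        part: dict[int, np.ndarray] = {}
        logscale = np.zeros(nP)
        for node, children in self.postorder:
            F = np.ones((N_CODONS, nP))
            for child, eidx in children:
                P = Pstack[eidx]
                if child in self.tip_row:
                    F *= self._tip_factor(P, self.tip_row[child])
                else:
                    F *= P @ part.pop(child)
            m = F.max(axis=0)
            m = np.where(m > 0, m, 1.0)
            F /= m
            logscale += np.log(m)
            part[node] = F
        return part[self.root], logscale

    def _class_loglik(
        self, rest: np.ndarray, logscale: np.ndarray, P_fg: np.ndarray | None
    ) -> np.ndarray:
        """Per-pattern log-likelihood for one site class."""
        if self.fg_row is None or P_fg is None:
            L = self.pi @ rest
        else:
            L = self.pi @ (rest * self._tip_factor(P_fg, self.fg_row))
        return np.log(np.maximum(L, _TINY)) + logscale

    def _background_pruning(self, kappa: float, omega: float, rate_scale: float):
        eig = self._eig(kappa, omega)
        Pstack = eig.P_batch(self.edge_lens / rate_scale)
        return self._root_partial(Pstack)

    def loglik_m0(
        self,
        kappa: float,
        omega: float,
        branch_scale: float = 1.0,
    ) -> float:
        """Single-omega (M0) log-likelihood; branch lengths scaled by a factor."""
        eig = self._eig(kappa, omega)
        r = eig.rate
        saved = self.edge_lens, self.fg_len
        try:
            self.edge_lens = saved[0] * branch_scale
            self.fg_len = saved[1] * branch_scale
            rest, logscale = self._background_pruning(kappa, omega, r)
            P_fg = eig.P(self.fg_len / r) if self.fg_row is not None else None
            site_ll = self._class_loglik(rest, logscale, P_fg)
        finally:
            self.edge_lens, self.fg_len = saved
        return float(self.weights @ site_ll)

    def loglik_branch_site(self, params: CodonModelParams) -> float:
        """Model-A mixture log-likelihood at the current branch lengths."""
        if self.fg_row is None:
            raise ConfigurationError("branch-site model needs a marked foreground tip")
        props = params.proportions
        bg = params.background_omegas
        eigs = {w: self._eig(params.kappa, w) for w in set(bg) | {params.omega2}}
        r = float(sum(props[k] * eigs[bg[k]].rate for k in range(4)))
        rests = {
            w: self._root_partial(eigs[w].P_batch(self.edge_lens / r))
            for w in set(bg)
        }
        P_fg = {
            w: eigs[w].P(self.fg_len / r)
            for w in set(params.foreground_omegas)
        }
        class_ll = np.stack(
            [
                self._class_loglik(*rests[bg[k]], P_fg[params.foreground_omegas[k]])
                for k in range(4)
            ]
        )  # (4, nP)
        with np.errstate(divide="ignore"):
            logp = np.log(np.maximum(props, _TINY))[:, None]
        site_ll = logsumexp(class_ll + logp, axis=0)
        return float(self.weights @ site_ll)

    def class_site_logliks(
        self,
        kappa: float,
        omega0_grid: np.ndarray,
        omega2_grid: np.ndarray,
        rate_scale: float,
    ):
        """Per-pattern log-likelihoods of the four classes on parameter grids.

        Returns (ll0[a, s], ll1[s], ll2a[a, b, s], ll2b[b, s]) for omega0
        values ``a`` and omega2 values ``b``, at fixed kappa, branch
        lengths, and rate scaling (the BEB workhorse).
        """
        nP = self.Xp.shape[1]
        e1 = self._eig(kappa, 1.0)
        rest1, ls1 = self._root_partial(e1.P_batch(self.edge_lens / rate_scale))
        ll1 = self._class_loglik(rest1, ls1, e1.P(self.fg_len / rate_scale))
        P2 = [
            self._eig(kappa, w2).P(self.fg_len / rate_scale) for w2 in omega2_grid
        ]
        ll0 = np.empty((len(omega0_grid), nP))
        ll2a = np.empty((len(omega0_grid), len(omega2_grid), nP))
        ll2b = np.empty((len(omega2_grid), nP))
        for b, P in enumerate(P2):
            ll2b[b] = self._class_loglik(rest1, ls1, P)
        for a, w0 in enumerate(omega0_grid):
            e0 = self._eig(kappa, w0)
            rest0, ls0 = self._root_partial(
                e0.P_batch(self.edge_lens / rate_scale)
            )
            ll0[a] = self._class_loglik(rest0, ls0, e0.P(self.fg_len / rate_scale))
            for b, P in enumerate(P2):
                ll2a[a, b] = self._class_loglik(rest0, ls0, P)
        return ll0, ll1, ll2a, ll2b

    def expand_to_sites(self, per_pattern: np.ndarray) -> np.ndarray:
        return per_pattern[..., self.pattern_of_site]


def log_likelihood(
    aln: Alignment,
    tree: dendropy.Tree,
    model: str,
    params: CodonModelParams,
    foreground: str | None = None,
) -> float:
    """One-shot log-likelihood at given parameters and tree branch lengths.

    ``model`` is ``M0`` (single omega = ``params.omega0``), ``A_null``
    (omega2 forced to 1) or ``A_alt``.
    """
    engine = CodonLikelihood(aln, tree, foreground=foreground)
    if model == "M0":
        return engine.loglik_m0(params.kappa, params.omega0)
    if model not in ("A_null", "A_alt"):
        raise ConfigurationError(f"unknown model {model!r}")
    if foreground is None:
        raise ConfigurationError("A models need a foreground tip label")
    if model == "A_null":
        params = CodonModelParams(
            params.kappa, params.omega0, 1.0, params.p0, params.p1
        )
    return engine.loglik_branch_site(params)


# ---------------------------------------------------------------------------
# Fitting


_KAPPA_BOUNDS = (0.05, 50.0)
_OMEGA0_BOUNDS = (1e-4, 1.0)
_OMEGA2_BOUNDS = (1.0, 50.0)
_M0_OMEGA_BOUNDS = (1e-4, 10.0)
_SCALE_BOUNDS = (1e-3, 100.0)
_LOGIT_BOUNDS = (-12.0, 12.0)


def _props_to_ab(p0: float, p1: float) -> tuple[float, float]:
    p2 = max(1e-6, 1.0 - p0 - p1)
    return float(np.log(max(p0, 1e-6) / p2)), float(np.log(max(p1, 1e-6) / p2))


def _ab_to_props(a: float, b: float) -> tuple[float, float]:
    z = np.exp(a) + np.exp(b) + 1.0
    return float(np.exp(a) / z), float(np.exp(b) / z)


def fit_m0(
    engine: CodonLikelihood,
    mode: str = "scale",
    seed: int = 0,
    n_starts: int = 1,
    set_lengths: bool = True,
) -> ModelFit:
    """Fit the single-omega model; by default re-estimates one global
    branch-length scale factor on the input tree's relative lengths.

    ``mode='full'`` frees every branch length individually (slower; the
    scale mode is the pipeline default because input gene trees already
    carry ML relative branch lengths).  With ``set_lengths`` the fitted
    lengths are installed on the engine for subsequent branch-site fits.
    """
    rng = np.random.default_rng(seed)
    n_evals = 0

    if mode == "scale":
        def obj(x):
            nonlocal n_evals
            n_evals += 1
            return -engine.loglik_m0(x[0], x[1], branch_scale=x[2])

        bounds = [_KAPPA_BOUNDS, _M0_OMEGA_BOUNDS, _SCALE_BOUNDS]
        starts = [np.array([2.0, 0.3, 1.0])]
        for _ in range(n_starts - 1):
            starts.append(
                np.array(
                    [
                        np.exp(rng.uniform(np.log(0.5), np.log(8.0))),
                        np.exp(rng.uniform(np.log(0.02), np.log(2.0))),
                        np.exp(rng.uniform(np.log(0.2), np.log(5.0))),
                    ]
                )
            )
    elif mode == "full":
        nE = len(engine.base_edge_lens)

        def obj(x):
            nonlocal n_evals
            n_evals += 1
            saved = engine.edge_lens, engine.fg_len
            try:
                engine.edge_lens = x[2 : 2 + nE]
                engine.fg_len = x[2 + nE] if engine.fg_row is not None else 0.0
                return -engine.loglik_m0(x[0], x[1])
            finally:
                engine.edge_lens, engine.fg_len = saved

        extra = 1 if engine.fg_row is not None else 0
        bounds = (
            [_KAPPA_BOUNDS, _M0_OMEGA_BOUNDS]
            + [(1e-8, 50.0)] * (nE + extra)
        )
        base = np.concatenate(
            [
                [2.0, 0.3],
                np.maximum(engine.base_edge_lens, 1e-6),
                [max(engine.base_fg_len, 1e-6)] if extra else [],
            ]
        )
        starts = [base]
        for _ in range(n_starts - 1):
            jitter = rng.uniform(0.5, 2.0, size=base.shape)
            starts.append(np.clip(base * jitter, 1e-8, None))
    else:
        raise ConfigurationError(f"unknown M0 mode {mode!r}")

    best = None
    any_converged = False
    for x0 in starts:
        res = minimize(
            obj, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-7, "maxfun": 2000},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    x = best.x
    params = CodonModelParams(kappa=float(x[0]), omega0=float(x[1]))
    if mode == "scale":
        scale = float(x[2])
        if set_lengths:
            engine.set_branch_scale(scale)
    else:
        scale = 1.0
        if set_lengths:
            nE = len(engine.base_edge_lens)
            engine.set_branch_lengths(
                x[2 : 2 + nE], x[2 + nE] if engine.fg_row is not None else 0.0
            )
    return ModelFit(
        model=f"M0/{mode}",
        lnL=float(-best.fun),
        params=params,
        branch_scale=scale,
        converged=any_converged,
        n_starts=len(starts),
        n_evals=n_evals,
    )


_DEFAULT_START = dict(kappa=2.0, omega0=0.2, p0=0.7, p1=0.2, omega2=2.0)


def fit_branch_site(
    engine: CodonLikelihood,
    model: str = "alt",
    n_starts: int = 3,
    seed: int = 0,
) -> ModelFit:
    """Maximize the branch-site likelihood (model A or its omega2=1 null).

    Deterministic multi-start: the first start is the fixed default, the
    rest are perturbations drawn from a generator seeded with ``seed``.
    Branch lengths are whatever the engine currently holds (normally the
    M0 fit's).
    """
    if model not in ("alt", "null"):
        raise ConfigurationError(f"model must be 'alt' or 'null', got {model!r}")
    rng = np.random.default_rng(seed)
    free_w2 = model == "alt"
    n_evals = 0

    def unpack(x) -> CodonModelParams:
        p0, p1 = _ab_to_props(x[2], x[3])
        w2 = float(x[4]) if free_w2 else 1.0
        return CodonModelParams(
            kappa=float(x[0]), omega0=float(x[1]), omega2=w2, p0=p0, p1=p1
        )

    def obj(x):
        nonlocal n_evals
        n_evals += 1
        return -engine.loglik_branch_site(unpack(x))

    bounds = [_KAPPA_BOUNDS, _OMEGA0_BOUNDS, _LOGIT_BOUNDS, _LOGIT_BOUNDS]
    if free_w2:
        bounds.append(_OMEGA2_BOUNDS)

    d = _DEFAULT_START
    a0, b0 = _props_to_ab(d["p0"], d["p1"])
    starts = [np.array([d["kappa"], d["omega0"], a0, b0, d["omega2"]][: len(bounds)])]
    for _ in range(n_starts - 1):
        p0 = rng.uniform(0.4, 0.9)
        p1 = rng.uniform(0.02, 0.95 - p0)
        a, b = _props_to_ab(p0, p1)
        cand = [
            np.exp(rng.uniform(np.log(0.5), np.log(8.0))),
            np.exp(rng.uniform(np.log(0.01), np.log(0.9))),
            a,
            b,
            np.exp(rng.uniform(np.log(1.2), np.log(12.0))),
        ]
        starts.append(np.array(cand[: len(bounds)]))

    best = None
    any_converged = False
    for x0 in starts:
        res = minimize(
            obj, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-7, "maxfun": 2000},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    return ModelFit(
        model=f"A_{model}",
        lnL=float(-best.fun),
        params=unpack(best.x),
        branch_scale=1.0,
        converged=any_converged,
        n_starts=len(starts),
        n_evals=n_evals,
    )


# ---------------------------------------------------------------------------
# Test statistics


def lrt_pvalue(
    lnL_null: float, lnL_alt: float, convention: str = "chi2_1"
) -> tuple[float, float]:
    """LRT statistic 2(lnL_alt - lnL_null) and its p-value.

    ``chi2_1`` refers the statistic to chi-square with one degree of
    freedom (conservative for this boundary problem); ``mixture`` uses the
    50:50 mix of a point mass at zero and chi-square(1).
    """
    if lnL_alt < lnL_null - 1e-6:
        logger.warning(
            "alternative lnL (%.6f) below null (%.6f); statistic clamped to 0",
            lnL_alt,
            lnL_null,
        )
    stat = max(0.0, 2.0 * (lnL_alt - lnL_null))
    if convention == "chi2_1":
        p = float(chi2.sf(stat, df=1))
    elif convention == "mixture":
        p = 1.0 if stat == 0 else float(0.5 * chi2.sf(stat, df=1))
    else:
        raise ConfigurationError(f"unknown LRT convention {convention!r}")
    return stat, p


def fdr_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg q-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Bayes Empirical Bayes site identification


def beb_posteriors(
    engine: CodonLikelihood,
    alt_fit: ModelFit,
    n_bins: int = 10,
    omega2_max: float = 11.0,
    mode: str = "beb",
) -> np.ndarray:
    """Per-site posterior probability of the foreground classes (2a + 2b).

    BEB integrates over a uniform grid prior: ``n_bins`` interval
    midpoints for omega0 on (0, 1) and omega2 on (1, omega2_max), and the
    midpoints of an ``n_bins``-per-axis triangular grid over the (p0, p1)
    simplex, all cells equally weighted; kappa and branch lengths stay at
    their estimates.  ``mode='neb'`` plugs the MLEs in directly instead
    (cheaper, less reliable for small alignments).

    Returns an array of length n_sites (codons, original order).
    """
    if not alt_fit.converged:
        raise RuntimeError("BEB requires a converged alternative fit")
    mle = alt_fit.params
    if mode == "neb":
        props = mle.proportions
        bg = mle.background_omegas
        eigs = {w: _Eig(codon_rate_matrix(mle.kappa, w, engine.pi), engine.pi)
                for w in set(bg) | {mle.omega2}}
        r = float(sum(props[k] * eigs[bg[k]].rate for k in range(4)))
        ll0, ll1, ll2a, ll2b = engine.class_site_logliks(
            mle.kappa, np.array([mle.omega0]), np.array([mle.omega2]), r
        )
        logf = np.stack([ll0[0], ll1, ll2a[0, 0], ll2b[0]])  # (4, nP)
        with np.errstate(divide="ignore"):
            logw = np.log(np.maximum(props, _TINY))[:, None]
        post = np.exp(logf + logw - logsumexp(logf + logw, axis=0))
        fg = post[2] + post[3]
        return engine.expand_to_sites(fg)
    if mode != "beb":
        raise ConfigurationError(f"unknown BEB mode {mode!r}")

    w0_grid = (np.arange(n_bins) + 0.5) / n_bins
    w2_grid = 1.0 + (np.arange(n_bins) + 0.5) * (omega2_max - 1.0) / n_bins
    # mixture-level rate scaling fixed at the MLE (branch lengths keep
    # their substitutions-per-site meaning across the grid)
    props_mle = mle.proportions
    bg_mle = mle.background_omegas
    r = float(
        sum(
            props_mle[k]
            * substitution_rate(
                codon_rate_matrix(mle.kappa, bg_mle[k], engine.pi), engine.pi
            )
            for k in range(4)
        )
    )
    ll0, ll1, ll2a, ll2b = engine.class_site_logliks(mle.kappa, w0_grid, w2_grid, r)
    nP = ll1.shape[-1]

    # proportion grid: midpoints of the triangular subdivision of the simplex
    pgrid = []
    for i in range(n_bins):
        for j in range(n_bins - i):
            p0 = (i + 0.5) / n_bins
            p1 = (j + 0.5) / n_bins
            pgrid.append((p0, p1))
    # common per-pattern reference to keep exponentials in range
    c = np.max(
        np.concatenate(
            [ll0, ll1[None], ll2a.reshape(-1, nP), ll2b], axis=0
        ),
        axis=0,
    )
    f0 = np.exp(ll0 - c)  # (A, nP)
    f1 = np.exp(ll1 - c)  # (nP,)
    f2a = np.exp(ll2a - c)  # (A, B, nP)
    f2b = np.exp(ll2b - c)  # (B, nP)

    w = engine.weights

    def mixture(p0: float, p1: float):
        p2 = 1.0 - p0 - p1
        p2a = p2 * p0 / (p0 + p1)
        p2b = p2 * p1 / (p0 + p1)
        m = (
            p0 * f0[:, None, :]
            + p1 * f1[None, None, :]
            + p2a * f2a
            + p2b * f2b[None, :, :]
        )  # (A, B, nP)
        return p2a, p2b, np.maximum(m, _TINY)

    logM = np.empty((len(pgrid), n_bins, n_bins))  # (pcell, a, b)
    for g, (p0, p1) in enumerate(pgrid):
        _, _, m = mixture(p0, p1)
        logM[g] = np.log(m) @ w

    logW = logM - logsumexp(logM)  # log posterior weight of each grid point
    W = np.exp(logW)
    fg_post = np.zeros(nP)
    for g, (p0, p1) in enumerate(pgrid):
        p2a, p2b, m = mixture(p0, p1)
        frac = (p2a * f2a + p2b * f2b[None, :, :]) / m  # (A, B, nP)
        fg_post += np.einsum("ab,abs->s", W[g], frac)
    return engine.expand_to_sites(np.clip(fg_post, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Per-orthogroup driver


def branch_site_test(
    aln: Alignment,
    tree: dendropy.Tree,
    focal: str,
    orthogroup_id: str = "",
    n_starts: int = 3,
    seed: int = 0,
    branch_mode: str = "scale",
    lrt_convention: str = "chi2_1",
) -> BranchSiteFit:
    """Fit null and alternative branch-site models for one orthogroup.

    Branch lengths are estimated once under M0 (global rescaling of the
    input tree by default) and held fixed for both mixture fits.  The
    q-value and BEB fields are filled in later, across orthogroups.
    """
    engine = CodonLikelihood(aln, tree, foreground=focal)
    fit_m0(engine, mode=branch_mode, seed=seed)
    null = fit_branch_site(engine, "null", n_starts=n_starts, seed=seed)
    alt = fit_branch_site(engine, "alt", n_starts=n_starts, seed=seed + 1)
    if alt.lnL < null.lnL - 1e-6:
        # the null is nested in the alternative; reuse its optimum
        p = null.params
        alt = ModelFit(
            model="A_alt",
            lnL=null.lnL,
            params=CodonModelParams(p.kappa, p.omega0, 1.0, p.p0, p.p1),
            branch_scale=null.branch_scale,
            converged=null.converged,
            n_starts=alt.n_starts,
            n_evals=alt.n_evals,
        )
    stat, p = lrt_pvalue(null.lnL, alt.lnL, convention=lrt_convention)
    fit = BranchSiteFit(
        orthogroup_id=orthogroup_id,
        lnL_null=null.lnL,
        lnL_alt=alt.lnL,
        params_null=null.params,
        params_alt=alt.params,
        stat=stat,
        pvalue=p,
        converged=null.converged and alt.converged,
    )
    fit._engine = engine  # kept for BEB; not part of the public record
    fit._alt_fit = alt
    return fit


def finalize_selection(
    fits: list[BranchSiteFit],
    fdr_threshold: float = 0.05,
    beb_threshold: float = 0.95,
    beb_mode: str = "beb",
) -> list[BranchSiteFit]:
    """Apply BH-FDR across orthogroups and locate sites for significant ones.

    Non-converged fits are excluded from the FDR correction (and flagged),
    mirroring how failed optimizations are dropped rather than silently
    treated as evidence.
    """
    ok = [f for f in fits if f.converged]
    skipped = [f for f in fits if not f.converged]
    if skipped:
        logger.warning(
            "%d orthogroup fits did not converge; excluded from FDR", len(skipped)
        )
    qvals = fdr_bh([f.pvalue for f in ok])
    for f, q in zip(ok, qvals):
        f.qvalue = float(q)
        f.positively_selected = bool(q < fdr_threshold)
        if f.positively_selected and hasattr(f, "_engine"):
            fg = beb_posteriors(f._engine, f._alt_fit, mode=beb_mode)
            f.beb_fg_posterior = fg
            f.selected_sites = [int(i) + 1 for i in np.nonzero(fg > beb_threshold)[0]]
    return fits
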