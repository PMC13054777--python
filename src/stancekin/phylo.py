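"""Phylogenetic comparative machinery.

A rooted, branch-length-bearing tree induces the Brownian-motion (BM)
covariance C, where C[i, j] is the shared root-to-MRCA path length of tips i
and j. On that structure this module provides:

* PGLS — generalized least squares with the BM correlation (Pagel's lambda
  fixed at 1.0 by default; the lambda transform scales only off-diagonals);
* BM trait simulation along the tree (the engine behind the phylogenetic
  ANOVA null and the synthetic data generator);
* simulation-based phylogenetic ANOVA: the observed one-way F is referred to
  a null distribution of F statistics from BM simulations on the tree, with
  Holm-corrected pairwise tests.

Newick reading/writing and pruning are thin, validated wrappers over
dendropy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
from scipy import linalg, stats

from .errors import NameMismatchError, NewickParseError, SingularityError

log = logging.getLogger(__name__)


class Phylogeny:
    """Rooted tree with branch lengths, backed by a dendropy tree.

    Tip order (the order of :attr:`tip_labels`) is the tree's leaf-iteration
    order and fixes the row/column order of the BM covariance matrix.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            seen, dups = set(), set()
            for lbl in labels:
                (dups if lbl in seen else seen).add(lbl)
            raise NewickParseError(f"duplicate tip labels: {sorted(dups)}")
        self._tip_labels = tuple(labels)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, assume_unit_lengths: bool = False) -> "Phylogeny":
        return parse_newick(text, assume_unit_lengths=assume_unit_lengths)

    # -- basic properties --------------------------------------------------

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return self._tip_labels

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    def tip_depths(self) -> np.ndarray:
        """Root-to-tip path lengths, in tip order."""
        depths = {}
        for node in self._tree.preorder_node_iter():
            parent_depth = depths.get(node.parent_node, 0.0) if node.parent_node else 0.0
            depths[node] = parent_depth + (node.edge.length or 0.0)
        return np.array([depths[leaf] for leaf in self._tree.leaf_node_iter()])

    @property
    def depth(self) -> float:
        return float(self.tip_depths().max())

    def scaled(self, target_depth: float) -> "Phylogeny":
        """Copy of the tree with branch lengths rescaled to the given depth."""
        if self.depth <= 0:
            raise ValueError("cannot rescale a zero-depth tree")
        factor = target_depth / self.depth
        clone = self._tree.clone(depth=1)
        for edge in clone.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length * factor
        return Phylogeny(clone)

    def to_newick(self) -> str:
        s = self._tree.as_string(schema="newick", suppress_rooting=True)
        return s.strip() + ("\n" if not s.endswith("\n") else "")

    # -- pruning -----------------------------------------------------------

    def prune_to(self, keep: Sequence[str]) -> "Phylogeny":
        """Induced subtree on ``keep``; unifurcations collapsed, lengths summed.

        Root-to-tip distances of the kept tips are preserved.
        """
        keep = list(keep)
        missing = set(keep) - set(self._tip_labels)
        if missing:
            raise NameMismatchError(missing)
        clone = self._tree.clone(depth=1)
        taxa = [t for t in clone.taxon_namespace if t.label in set(keep)]
        clone.retain_taxa(taxa)
        return Phylogeny(clone)

    # -- BM covariance -----------------------------------------------------

    def bm_covariance(self, perturb_zero_length: bool = False) -> np.ndarray:
        """BM covariance: C[i, j] = shared root-to-MRCA path length.

        With ``perturb_zero_length``, zero-length branches are treated as
        1e-8 x tree depth so the matrix stays invertible (logged).
        """
        eps = 1e-8 * max(self.depth, 1.0) if perturb_zero_length else 0.0
        n = self.n_tips
        index = {lbl: i for i, lbl in enumerate(self._tip_labels)}
        C = np.zeros((n, n))
        depths: dict = {}
        tipsets: dict = {}
        n_perturbed = 0
        for node in self._tree.preorder_node_iter():
            length = node.edge.length or 0.0
            if perturb_zero_length and node.parent_node is not None and length == 0.0:
                length = eps
                n_perturbed += 1
            parent_depth = depths.get(node.parent_node, 0.0) if node.parent_node else 0.0
            depths[node] = parent_depth + (length if node.parent_node is not None else 0.0)
        if n_perturbed:
            log.info("bm_covariance: perturbed %d zero-length branches by %g", n_perturbed, eps)
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                i = index[node.taxon.label]
                tipsets[node] = [i]
                C[i, i] = depths[node]
            else:
                child_sets = [tipsets[c] for c in node.child_nodes()]
                d = depths[node]
                for a in range(len(child_sets)):
                    for b in range(a + 1, len(child_sets)):
                        for i in child_sets[a]:
                            for j in child_sets[b]:
                                C[i, j] = C[j, i] = d
                tipsets[node] = [i for s in child_sets for i in s]
        return C

    def __repr__(self):
        return f"Phylogeny(n_tips={self.n_tips}, depth={self.depth:.4g})"


def parse_newick(text: str, assume_unit_lengths: bool = False) -> Phylogeny:
    """Parse a rooted Newick string; branch lengths are mandatory by default.

    Raises :class:`NewickParseError` for malformed input, duplicate tips, or
    missing branch lengths (unless ``assume_unit_lengths``).
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    if tree.seed_node is None or not any(tree.leaf_node_iter()):
        raise NewickParseError("empty tree")
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.edge.length is None:
            if assume_unit_lengths:
                node.edge.length = 1.0
            else:
                where = node.taxon.label if node.taxon else "internal node"
                raise NewickParseError(f"missing branch length at {where}")
        elif node.edge.length < 0:
            raise NewickParseError("negative branch length")
    return Phylogeny(tree)


def pagel_lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Pagel's lambda transform: multiply off-diagonal covariances by lambda."""
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lambda must be in [0, 1]")
    out = lam * np.asarray(C, dtype=float)
    np.fill_diagonal(out, np.diag(C))
    return out


@dataclass
class PGLSFit:
    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    t_stat: float
    df: int
    p: float
    r2: float
    sigma2: float
    lam: float
    n: int


def pgls_fit(
    y: np.ndarray, x: np.ndarray, C: np.ndarray, lam: float = 1.0
) -> PGLSFit:
    """PGLS of y on x under covariance C (Pagel's lambda fixed, default 1).

    beta = (X' C^-1 X)^-1 X' C^-1 y with an intercept column; the residual
    variance sits on n - 2 df; R^2 is the coefficient of determination in the
    whitened space, 1 - RSS_w / TSS_w, with TSS_w centered at the GLS mean.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    C = np.asarray(C, dtype=float)
    n = y.size
    if x.size != n or C.shape != (n, n):
        raise ValueError("dimension mismatch")
    if np.ptp(x) == 0:
        raise SingularityError("constant predictor")
    if lam != 1.0:
        C = pagel_lambda_transform(C, lam)
    try:
        cho = linalg.cho_factor(C, lower=True)
    except linalg.LinAlgError as exc:
        raise SingularityError(f"covariance not positive definite: {exc}") from exc

    X = np.column_stack([np.ones(n), x])
    CiX = linalg.cho_solve(cho, X)
    Ciy = linalg.cho_solve(cho, y)
    XtCiX = X.T @ CiX
    try:
        XtCiX_inv = np.linalg.inv(XtCiX)
    except np.linalg.LinAlgError as exc:
        raise SingularityError("collinear design") from exc
    beta = XtCiX_inv @ (X.T @ Ciy)
    resid = y - X @ beta
    df = n - 2
    rss_w = float(resid @ linalg.cho_solve(cho, resid))
    sigma2 = rss_w / df
    cov_beta = sigma2 * XtCiX_inv
    se = np.sqrt(np.diag(cov_beta))
    t_stat = beta[1] / se[1]
    p = 2.0 * float(stats.t.sf(abs(t_stat), df))

    # GLS grand mean for the whitened total sum of squares
    ones = np.ones(n)
    Ci1 = linalg.cho_solve(cho, ones)
    mu = float(ones @ Ciy) / float(ones @ Ci1)
    dev = y - mu
    tss_w = float(dev @ linalg.cho_solve(cho, dev))
    r2 = 1.0 - rss_w / tss_w if tss_w > 0 else float("nan")

    return PGLSFit(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        se_slope=float(se[1]),
        se_intercept=float(se[0]),
        t_stat=float(t_stat),
        df=df,
        p=p,
        r2=float(r2),
        sigma2=float(sigma2),
        lam=lam,
        n=n,
    )


def simulate_bm(
    tree: Phylogeny,
    sigma2: float,
    root_value: float = 0.0,
    rng: np.random.Generator | int | None = None,
    n_reps: int = 1,
) -> np.ndarray:
    """Simulate Brownian-motion trait values at the tips.

    Normal increments along each branch with variance sigma2 x branch length.
    Returns an (n_reps, n_tips) array in tip order; pass ``n_reps=1`` and take
    row 0 for a single replicate.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    rng = np.random.default_rng(rng)
    index = {lbl: i for i, lbl in enumerate(tree.tip_labels)}
    out = np.empty((n_reps, tree.n_tips))
    values: dict = {}
    for node in tree._tree.preorder_node_iter():
        if node.parent_node is None:
            values[node] = np.full(n_reps, float(root_value))
        else:
            length = node.edge.length or 0.0
            incr = rng.normal(0.0, math.sqrt(sigma2 * length), size=n_reps)
            values[node] = values[node.parent_node] + incr
        if node.is_leaf():
            out[:, index[node.taxon.label]] = values[node]
    return out


@dataclass
class PhylAnovaResult:
    f_obs: float
    p_phyl: float
    n_sim: int
    df1: int
    df2: int
    pairwise: list[tuple[str, str, float, float]] = field(default_factory=list)


def _anova_f(Y: np.ndarray, group_idx: list[np.ndarray]) -> np.ndarray:
    """Classical one-way F for each row of Y given per-group column indices."""
    Y = np.atleast_2d(Y)
    n = Y.shape[1]
    k = len(group_idx)
    grand = Y.mean(axis=1, keepdims=True)
    ssb = np.zeros(Y.shape[0])
    ssw = np.zeros(Y.shape[0])
    for idx in group_idx:
        sub = Y[:, idx]
        m = sub.mean(axis=1, keepdims=True)
        ssb += idx.size * ((m - grand) ** 2).ravel()
        ssw += ((sub - m) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (k - 1)) / (ssw / (n - k))
    f = np.where(ssb == 0, 0.0, f)  # constant traits carry no signal
    return np.where((ssw == 0) & (ssb > 0), np.inf, f)


def gls_rate_estimate(y: np.ndarray, C: np.ndarray) -> float:
    """BM rate from the grand-mean GLS model: (y-mu)' C^-1 (y-mu) / (n-1)."""
    y = np.asarray(y, dtype=float)
    n = y.size
    cho = linalg.cho_factor(C, lower=True)
    ones = np.ones(n)
    Ci1 = linalg.cho_solve(cho, ones)
    mu = float(ones @ linalg.cho_solve(cho, y)) / float(ones @ Ci1)
    dev = y - mu
    return float(dev @ linalg.cho_solve(cho, dev)) / (n - 1)


def phyl_anova(
    y: Mapping[str, float] | np.ndarray,
    groups: Mapping[str, str] | Sequence[str],
    tree: Phylogeny,
    n_sim: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> PhylAnovaResult:
    """Simulation-based phylogenetic ANOVA.

    The observed one-way F of ``y`` across ``groups`` is compared with F
    statistics recomputed (groups fixed) on ``n_sim`` BM simulations along the
    tree, at the BM rate estimated from ``y`` by the grand-mean GLS estimator.
    p = (1 + #{F_sim >= F_obs}) / (1 + n_sim), so p is never zero. Pairwise
    pooled-variance t statistics get the same simulation treatment with Holm
    adjustment.
    """
    labels = tree.tip_labels
    if isinstance(y, Mapping):
        missing = set(labels) - set(y)
        if missing:
            raise NameMismatchError(missing)
        yv = np.array([float(y[lbl]) for lbl in labels])
    else:
        yv = np.asarray(y, dtype=float)
        if yv.size != len(labels):
            raise ValueError("y length must match the number of tips")
    if isinstance(groups, Mapping):
        missing = set(labels) - set(groups)
        if missing:
            raise NameMismatchError(missing)
        gv = [groups[lbl] for lbl in labels]
    else:
        gv = list(groups)
        if len(gv) != len(labels):
            raise ValueError("groups length must match the number of tips")

    cats = sorted(set(gv))
    if len(cats) < 2:
        raise ValueError("need at least two groups")
    group_idx = [np.array([i for i, g in enumerate(gv) if g == c]) for c in cats]
    n, k = yv.size, len(cats)

    f_obs = float(_anova_f(yv[None, :], group_idx)[0])

    C = tree.bm_covariance(perturb_zero_length=True)
    sigma2 = gls_rate_estimate(yv, C)
    rng = np.random.default_rng(rng)
    sims = simulate_bm(tree, sigma2, 0.0, rng=rng, n_reps=n_sim)
    f_sim = _anova_f(sims, group_idx)
    p_phyl = (1.0 + float((f_sim >= f_obs).sum())) / (1.0 + n_sim)

    # pairwise pooled t (MSE from the full one-way ANOVA), simulation nulls
    def pairwise_t(Y: np.ndarray) -> np.ndarray:
        Y = np.atleast_2d(Y)
        means = np.stack([Y[:, idx].mean(axis=1) for idx in group_idx], axis=1)
        ssw = sum(
            ((Y[:, idx] - Y[:, idx].mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
            for idx in group_idx
        )
        mse = ssw / (n - k)
        ts = []
        for a in range(k):
            for b in range(a + 1, k):
                se = np.sqrt(mse * (1.0 / group_idx[a].size + 1.0 / group_idx[b].size))
                diff = means[:, a] - means[:, b]
                with np.errstate(divide="ignore", invalid="ignore"):
                    t = diff / se
                ts.append(np.where(diff == 0, 0.0, t))
        return np.stack(ts, axis=1)

    t_obs = pairwise_t(yv[None, :])[0]
    t_sim = pairwise_t(sims)
    raw = [
        (1.0 + float((np.abs(t_sim[:, m]) >= abs(t_obs[m])).sum())) / (1.0 + n_sim)
        for m in range(t_obs.size)
    ]
    from .stats import holm_adjust

    adj = holm_adjust(raw)
    pair_labels = [(cats[a], cats[b]) for a in range(k) for b in range(a + 1, k)]
    pairwise = [
        (a, b, float(t_obs[m]), adj[m]) for m, (a, b) in enumerate(pair_labels)
    ]
    return PhylAnovaResult(
        f_obs=f_obs, p_phyl=p_phyl, n_sim=n_sim, df1=k - 1, df2=n - k, pairwise=pairwise
    )
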