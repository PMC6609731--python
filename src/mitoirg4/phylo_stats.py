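"""Phylogenetic paired t-test for per-species paired measurements.

The per-species paired differences d = x - y are modelled as multivariate
normal with mean mu * 1 and covariance sigma^2 * V(lambda), where V is the
Brownian-motion covariance implied by a rooted tree with branch lengths
(cov of two tips = shared root-to-MRCA path length) and lambda is Pagel's
lambda scaling the off-diagonal entries. lambda is profiled over [0, 1] by
bounded 1-D maximum likelihood; mu and sigma^2 follow in closed form by
generalised least squares. The t statistic is mu-hat over its GLS standard
error (unbiased variance estimate), referred to a Student-t distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import dendropy
import numpy as np
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

log = logging.getLogger(__name__)


@dataclass
class PhyloTree:
    """A rooted tree with tip labels, branch lengths and its BM covariance."""

    tree: dendropy.Tree
    tip_labels: list[str]
    vcv: np.ndarray  # Brownian covariance, lambda = 1

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def is_star(self) -> bool:
        """True when no pair of tips shares path length (lambda has no effect)."""
        off = self.vcv - np.diag(np.diag(self.vcv))
        return bool(np.all(off == 0))


def _tree_vcv(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(tips)) != len(tips):
        raise ValueError("duplicate tip labels")
    idx = {t: i for i, t in enumerate(tips)}
    n = len(tips)
    V = np.zeros((n, n))

    root = tree.seed_node
    depths: dict = {root: 0.0}
    tipsets: dict = {}
    for node in tree.preorder_node_iter():
        if node is not root:
            bl = node.edge.length
            if bl is None:
                raise ValueError("tree has missing branch lengths")
            if bl < 0:
                raise ValueError("negative branch length")
            depths[node] = depths[node.parent_node] + bl
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tipsets[node] = [idx[node.taxon.label]]
            V[tipsets[node][0], tipsets[node][0]] = depths[node]
        else:
            child_sets = [tipsets[c] for c in node.child_nodes()]
            for a in range(len(child_sets)):
                for b in range(a + 1, len(child_sets)):
                    for i in child_sets[a]:
                        for j in child_sets[b]:
                            V[i, j] = V[j, i] = depths[node]
            tipsets[node] = [i for cs in child_sets for i in cs]
    return tips, V


def read_newick(path: str | Path, *, grafen: bool = False) -> PhyloTree:
    """Read a rooted newick tree with branch lengths.

    Trees lacking branch lengths are rejected unless ``grafen=True``, in
    which case Grafen's method assigns node heights proportional to clade
    size (an explicit opt-in, never silent).
    """
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    return from_dendropy(tree, grafen=grafen)


def from_dendropy(tree: dendropy.Tree, *, grafen: bool = False) -> PhyloTree:
    missing = any(
        nd.edge.length is None for nd in tree.preorder_node_iter() if nd is not tree.seed_node
    )
    if missing:
        if not grafen:
            raise ValueError(
                "tree has branches without lengths; pass grafen=True to assign "
                "Grafen branch lengths explicitly"
            )
        _grafen_lengths(tree)
    tips, V = _tree_vcv(tree)
    return PhyloTree(tree=tree, tip_labels=tips, vcv=V)


def _grafen_lengths(tree: dendropy.Tree) -> None:
    n_total = len(tree.leaf_nodes())
    heights = {}
    for node in tree.postorder_node_iter():
        n = len(node.leaf_nodes())
        heights[node] = 0.0 if node.is_leaf() else (n - 1) / max(1, n_total - 1)
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            node.edge.length = heights[node.parent_node] - heights[node]


def phylo_vcv(tree: PhyloTree, lam: float) -> np.ndarray:
    """Pagel's lambda transform: off-diagonals scaled, diagonals unchanged."""
    if not 0 <= lam <= 1:
        raise ValueError("lambda must be in [0, 1]")
    V = tree.vcv
    return lam * V + (1 - lam) * np.diag(np.diag(V))


@dataclass(frozen=True)
class PairedPhyloTestResult:
    mu_hat: float
    lambda_hat: float
    se_mu: float
    t_stat: float
    df: int
    p: float
    logLik: float
    sigma2_hat: float


def _gls_fit(d: np.ndarray, V: np.ndarray) -> tuple[float, float, float, float]:
    """Closed-form (mu, sigma2_ML, logLik, one_Vinv_one) given V(lambda)."""
    n = d.size
    jitter = 0.0
    while True:
        try:
            c = cho_factor(V + jitter * np.eye(n), lower=True)
            break
        except np.linalg.LinAlgError:
            if jitter == 0.0:
                jitter = 1e-10
                log.warning("singular phylogenetic covariance; adding 1e-10 jitter")
            else:
                jitter *= 10
            if jitter > 1e-4:
                raise
    one = np.ones(n)
    Vi_one = cho_solve(c, one)
    Vi_d = cho_solve(c, d)
    denom = one @ Vi_one
    mu = (one @ Vi_d) / denom
    r = d - mu
    rss = r @ cho_solve(c, r)
    sigma2 = rss / n
    logdet = 2 * np.sum(np.log(np.diag(c[0])))
    with np.errstate(divide="ignore"):
        logL = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return float(mu), float(sigma2), float(logL), float(denom)


def phyl_paired_ttest(
    tree: PhyloTree,
    x: Mapping[str, float],
    y: Mapping[str, float],
    *,
    df: Optional[int] = None,
    tol: float = 1e-8,
    p_method: str = "sup",
) -> PairedPhyloTestResult:
    """Test whether the mean paired difference across species is zero.

    ``x`` and ``y`` are keyed by tip label and must be complete. Degrees of
    freedom default to n - 2 (one each for mu and the profiled lambda); on a
    star tree lambda drops out of the likelihood and df = n - 1, which makes
    the test collapse exactly onto the classical paired t-test. Pass ``df``
    to override.

    Point estimates (mu, sigma^2, lambda) are maximum likelihood. The
    reported p-value is, by default (``p_method="sup"``), the supremum over
    lambda in [0, 1] of the exact fixed-lambda GLS t-test p: for every fixed
    lambda the t statistic is exactly Student-t under the null, so the
    supremum is a finite-sample valid p-value whatever the true lambda.
    Plugging the estimated lambda straight into the t-test
    (``p_method="plugin"``, the construction mirrored from the R
    implementation this test follows) ignores the uncertainty in lambda and
    over-rejects badly in small samples (empirically ~3x the nominal level
    on 12-tip trees with strong phylogenetic signal); it is kept as an
    option for comparability. ``t_stat`` is the t at the lambda attaining
    the reported p, so ``p == 2 * T.sf(|t_stat|, df)`` always holds.
    """
    n = tree.n_tips
    if n < 3:
        raise ValueError("need at least 3 tips")
    missing = [t for t in tree.tip_labels if t not in x or t not in y]
    if missing:
        raise ValueError(f"missing paired values for tips: {missing}")
    d = np.array([x[t] - y[t] for t in tree.tip_labels], dtype=float)

    if p_method not in ("sup", "plugin"):
        raise ValueError("p_method must be 'sup' or 'plugin'")

    def t_at(lam: float) -> float:
        mu_l, s2_l, _, den_l = _gls_fit(d, phylo_vcv(tree, lam))
        se_l = np.sqrt(s2_l * n / (n - 1) / den_l)
        return mu_l / se_l if se_l > 0 else 0.0

    if tree.is_star:
        lam_hat = 1.0  # unidentifiable: V(lambda) is constant in lambda
        mu, sigma2, logL, denom = _gls_fit(d, tree.vcv)
        eff_df = df if df is not None else n - 1
        t_stat = t_at(1.0)
    else:
        def neg_profile(lam: float) -> float:
            return -_gls_fit(d, phylo_vcv(tree, lam))[2]

        res = optimize.minimize_scalar(
            neg_profile, bounds=(0.0, 1.0), method="bounded",
            options={"xatol": tol},
        )
        lam_hat = float(res.x)
        # guard the profile optimum against the boundary values
        for lam_b in (0.0, 1.0):
            if neg_profile(lam_b) < res.fun:
                lam_hat = lam_b
        mu, sigma2, logL, denom = _gls_fit(d, phylo_vcv(tree, lam_hat))
        eff_df = df if df is not None else n - 2
        if p_method == "plugin":
            t_stat = t_at(lam_hat)
        else:
            # supremum-p: the least-extreme t over lambda (coarse grid, then
            # local refinement; |t(lambda)| need not be unimodal)
            grid = np.linspace(0.0, 1.0, 41)
            tvals = np.array([t_at(l) for l in grid])
            i = int(np.argmin(np.abs(tvals)))
            lo, hi = grid[max(0, i - 1)], grid[min(len(grid) - 1, i + 1)]
            ref = optimize.minimize_scalar(
                lambda l: abs(t_at(l)), bounds=(lo, hi), method="bounded",
                options={"xatol": tol},
            )
            t_stat = t_at(float(ref.x)) if abs(ref.fun) < np.abs(tvals[i]) else float(tvals[i])

    rss_unbiased = sigma2 * n / (n - 1)
    se = float(np.sqrt(rss_unbiased / denom))
    p = float(2 * stats.t.sf(abs(t_stat), eff_df))
    return PairedPhyloTestResult(
        mu_hat=mu, lambda_hat=lam_hat, se_mu=se, t_stat=float(t_stat),
        df=eff_df, p=p, logLik=logL, sigma2_hat=sigma2,
    )
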