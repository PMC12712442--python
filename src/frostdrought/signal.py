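"""Phylogenetic signal statistics and Brownian ancestral states.

Implements Blomberg's K with a tip-permutation test and Pagel's lambda by
profile maximum likelihood with likelihood-ratio tests against lambda = 0
(no signal) and lambda = 1 (pure Brownian motion), plus maximum-likelihood
ancestral state estimation under Brownian motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy import optimize, stats

from .trees import PhyloCovariance, _chol_solve, lambda_transform, phylo_weighted_mean, vcv

__all__ = ["SignalResult", "blomberg_k", "pagel_lambda_ml", "bm_ancestral_states"]


@dataclass(frozen=True)
class SignalResult:
    """A phylogenetic signal estimate with its significance tests.

    ``p_vs_0`` tests departure from no signal (permutation for K, LRT for
    lambda); ``p_vs_1`` tests lambda against pure Brownian motion (K: None).
    """

    statistic: str  # "K" or "lambda"
    estimate: float
    p_vs_0: float
    p_vs_1: float | None
    n: int
    loglik: float | None = None
    n_permutations: int | None = None
    flat_profile: bool = False

    def as_row(self, trait: str) -> dict:
        return {
            "trait": trait,
            "method": self.statistic,
            "estimate": self.estimate,
            "p_vs_0": self.p_vs_0,
            "p_vs_1": self.p_vs_1,
            "n": self.n,
        }


def _k_ratio(x: np.ndarray, Cinv_x: np.ndarray, w: np.ndarray,
             w_sum: float, expected: float) -> float:
    """K for one trait vector given precomputed C^-1 x and C^-1 1."""
    a = float(w @ x) / w_sum
    dev = x - a
    mse0 = float(dev @ dev)
    mse = float(dev @ (Cinv_x - a * w))
    return (mse0 / mse) / expected


def blomberg_k(x: np.ndarray, C: PhyloCovariance, n_perm: int = 1000,
               seed: int | None = None) -> SignalResult:
    """Blomberg's K with a permutation test of tip labels.

    K = [MSE0/MSE] / E_BM[MSE0/MSE], where MSE0 is the ordinary mean squared
    deviation from the GLS mean, MSE the phylogenetically corrected one, and
    the denominator its Brownian-motion expectation
    (tr C - n / (1'C^-1 1)) / (n - 1).  The p-value against no signal uses
    the (1 + b) / (1 + B) convention over uniform tip permutations.
    """
    x = np.asarray(x, dtype=float)
    n = C.n
    if x.shape[0] != n:
        raise ValueError("trait vector and covariance dimension disagree")
    if n < 4:
        raise ValueError("need at least 4 species")
    if np.ptp(x) == 0:
        raise ValueError("trait has zero variance; K undefined")
    cf = sla.cho_factor(C.matrix, lower=True)
    ones = np.ones(n)
    w = sla.cho_solve(cf, ones)
    w_sum = float(w @ ones)
    expected = (float(np.trace(C.matrix)) - n / w_sum) / (n - 1)
    k_obs = _k_ratio(x, sla.cho_solve(cf, x), w, w_sum, expected)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        xp = rng.permutation(x)
        if _k_ratio(xp, sla.cho_solve(cf, xp), w, w_sum, expected) >= k_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return SignalResult("K", k_obs, p, None, n, n_permutations=n_perm)


def _profile_loglik(x: np.ndarray, C: PhyloCovariance, lam: float) -> float:
    """MVN log-likelihood at lambda with root state and rate profiled out."""
    n = C.n
    Cl = lambda_transform(C, lam).matrix
    cf = sla.cho_factor(Cl, lower=True)
    ones = np.ones(n)
    w = sla.cho_solve(cf, ones)
    a = float(w @ x) / float(w @ ones)
    dev = x - a
    quad = float(dev @ sla.cho_solve(cf, dev))
    sigma2 = quad / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)


def pagel_lambda_ml(x: np.ndarray, C: PhyloCovariance) -> SignalResult:
    """Pagel's lambda by profile ML on [0, 1] with LRTs vs 0 and vs 1.

    The likelihood is multivariate normal with covariance
    sigma^2 * C(lambda); root state and sigma^2 are profiled analytically and
    lambda is found by bounded scalar optimization.  P-values use the
    chi-square(1) reference for 2*[l(lhat) - l(0 or 1)] (the plain reference
    is used even at the lambda = 1 boundary).
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] != C.n:
        raise ValueError("trait vector and covariance dimension disagree")
    if C.n < 4:
        raise ValueError("need at least 4 species")

    def nll(lam: float) -> float:
        return -_profile_loglik(x, C, lam)

    res = optimize.minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                                   options={"xatol": 1e-6})
    lam_hat = float(res.x)
    ll_hat = -float(res.fun)
    ll0 = _profile_loglik(x, C, 0.0)
    ll1 = _profile_loglik(x, C, 1.0)
    # the bounded optimizer never evaluates exactly at the bounds
    for lam_b, ll_b in ((0.0, ll0), (1.0, ll1)):
        if ll_b > ll_hat:
            lam_hat, ll_hat = lam_b, ll_b
    grid = [ll0, _profile_loglik(x, C, 0.25), _profile_loglik(x, C, 0.5),
            _profile_loglik(x, C, 0.75), ll1]
    flat = (max(grid) - min(grid)) < 1e-8
    p0 = float(stats.chi2.sf(max(2.0 * (ll_hat - ll0), 0.0), df=1))
    p1 = float(stats.chi2.sf(max(2.0 * (ll_hat - ll1), 0.0), df=1))
    return SignalResult("lambda", lam_hat, p0, p1, C.n, loglik=ll_hat,
                        flat_profile=flat)


def bm_ancestral_states(tree: dendropy.Tree, traits: dict[str, float] | pd.Series
                        ) -> pd.DataFrame:
    """ML ancestral states under Brownian motion for every internal node.

    The ML state at a node is the GLS root estimate of the tree re-rooted at
    that node.  Internal nodes are labelled ``node_<k>`` in preorder (existing
    labels are kept).  Returns a DataFrame with columns node, estimate.
    """
    traits = dict(traits)
    tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    missing = [t for t in tips if t not in traits]
    if missing:
        raise ValueError(f"traits missing for tips: {missing[:5]}")
    work = tree.clone(depth=1)
    internal = []
    for k, node in enumerate(work.preorder_internal_node_iter()):
        if not node.label:
            node.label = f"node_{k}"
        internal.append(node)
    rows = []
    for node in internal:
        rerooted = _reroot_clone(work, node.label)
        Cv = vcv(rerooted)
        xv = np.array([traits[s] for s in Cv.species])
        rows.append({"node": node.label,
                     "estimate": phylo_weighted_mean(xv, Cv)})
    return pd.DataFrame(rows)


def _reroot_clone(tree: dendropy.Tree, label: str) -> dendropy.Tree:
    clone = tree.clone(depth=1)
    target = None
    for node in clone.preorder_internal_node_iter():
        if node.label == label:
            target = node
            break
    if target is clone.seed_node:
        return clone
    clone.reroot_at_node(target, update_bipartitions=False,
                         suppress_unifurcations=True)
    return clone
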