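"""Phylogenetic signal in continuous traits: Blomberg's K, Pagel's lambda,
and Abouheif/Moran's I.

* **Blomberg's K** compares the observed ratio of trait variance (around the
  phylogenetic GLS mean) to the variance of GLS residuals against its
  expectation under Brownian motion on the tree; K = 1 is the Brownian
  expectation, K > 1 stronger-than-Brownian signal, K near 0 no signal.
  Significance comes from tip-label permutations of the trait.
* **Pagel's lambda** scales the off-diagonal elements of the Brownian
  covariance by a factor lambda in [0, lambda_max] and maximizes the
  Gaussian likelihood; lambda = 0 is a star phylogeny (no signal).  The test
  is a likelihood-ratio test against lambda = 0 (chi-square, 1 df).
* **Abouheif/Moran's I** is Moran's autocorrelation index computed with the
  Abouheif proximity matrix (product of inverse direct-descendant counts
  along the path between two tips, diagonal zero, row-normalized); the
  one-sided test permutes tip labels.

All metrics are invariant to adding a constant to the trait; K and I are
also invariant to positive rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy import stats as sps

from .tree import Phylogeny, normalize_label

__all__ = [
    "SignalResult",
    "blomberg_k",
    "pagel_lambda",
    "abouheif_moran",
    "abouheif_proximity",
    "signal_table",
]


@dataclass
class SignalResult:
    trait: str
    metric: str
    estimate: float
    p: float
    n_tips: int
    aux: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "aux"}
        return d


def _align(phylo: Phylogeny, trait: pd.Series) -> tuple[Phylogeny, np.ndarray]:
    """Prune the tree to the trait's species and return aligned values."""
    trait = trait.dropna()
    trait.index = [normalize_label(i) for i in trait.index]
    names = [n for n in trait.index if n in phylo]
    missing = sorted(set(trait.index) - set(names))
    if missing:
        raise KeyError(f"trait species absent from phylogeny: {missing}")
    if len(names) < 4:
        raise ValueError("need trait values for at least 4 tips")
    sub = phylo if len(names) == phylo.n_tips else phylo.prune_to(names)
    x = trait.loc[list(sub.taxa)].to_numpy(dtype=float)
    if np.std(x) == 0:
        raise ValueError("constant trait: signal undefined")
    return sub, x


# ------------------------------------------------------------------ Blomberg K
def _k_statistic(x: np.ndarray, C: np.ndarray, solve) -> float:
    n = x.size
    one = np.ones(n)
    Cinv_x = solve(x)
    Cinv_1 = solve(one)
    ahat = float(one @ Cinv_x) / float(one @ Cinv_1)
    dev = x - ahat
    mse0 = float(dev @ dev) / (n - 1)
    mse = float(dev @ solve(dev)) / (n - 1)
    expected = (np.trace(C) - n / float(one @ Cinv_1)) / (n - 1)
    return (mse0 / mse) / expected


def blomberg_k(
    phylo: Phylogeny,
    trait: pd.Series,
    R: int = 999,
    rng: np.random.Generator | None = None,
) -> SignalResult:
    """Blomberg's K with a tip-permutation test (one-sided: K larger than
    under a random reshuffle of the trait across tips)."""
    sub, x = _align(phylo, trait)
    C = sub.bm_covariance()
    try:
        cho = linalg.cho_factor(C)
    except linalg.LinAlgError:
        # zero-length terminal pairs make C singular; jitter the diagonal
        C = C + np.eye(C.shape[0]) * (1e-10 * np.trace(C) / C.shape[0])
        cho = linalg.cho_factor(C)
    solve = lambda v: linalg.cho_solve(cho, v)  # noqa: E731
    k_obs = _k_statistic(x, C, solve)
    rng = np.random.default_rng() if rng is None else rng
    exceed = 0
    for _ in range(R):
        k_perm = _k_statistic(rng.permutation(x), C, solve)
        exceed += k_perm >= k_obs
    p = (exceed + 1) / (R + 1)
    return SignalResult(
        trait=str(trait.name), metric="K", estimate=float(k_obs), p=float(p),
        n_tips=x.size, aux={"R": R},
    )


# --------------------------------------------------------------- Pagel lambda
def _lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


def _profile_loglik(x: np.ndarray, V: np.ndarray) -> float:
    n = x.size
    try:
        cho = linalg.cho_factor(V)
    except linalg.LinAlgError:
        return -np.inf
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    one = np.ones(n)
    Vi_x = linalg.cho_solve(cho, x)
    Vi_1 = linalg.cho_solve(cho, one)
    ahat = float(one @ Vi_x) / float(one @ Vi_1)
    dev = x - ahat
    sigma2 = float(dev @ linalg.cho_solve(cho, dev)) / n
    if sigma2 <= 0:
        return -np.inf
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)


def _lambda_max(C: np.ndarray, hi: float = 2.0) -> float:
    """Largest lambda keeping the scaled covariance positive definite."""

    def pd_ok(lam: float) -> bool:
        try:
            linalg.cho_factor(_lambda_cov(C, lam))
            return True
        except linalg.LinAlgError:
            return False

    if pd_ok(hi):
        return hi
    lo, up = 0.0, hi
    for _ in range(50):
        mid = 0.5 * (lo + up)
        if pd_ok(mid):
            lo = mid
        else:
            up = mid
    return lo


def pagel_lambda(phylo: Phylogeny, trait: pd.Series) -> SignalResult:
    """Maximum-likelihood Pagel's lambda with a likelihood-ratio test vs
    lambda = 0 (chi-square with 1 df)."""
    sub, x = _align(phylo, trait)
    C = sub.bm_covariance()
    lam_max = _lambda_max(C)
    res = optimize.minimize_scalar(
        lambda lam: -_profile_loglik(x, _lambda_cov(C, lam)),
        bounds=(0.0, lam_max * (1 - 1e-9)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    if not res.success:
        raise RuntimeError(
            f"lambda optimization failed (bounds 0..{lam_max:.4g}): {res.message}"
        )
    lam_hat = float(res.x)
    ll1 = -float(res.fun)
    ll0 = _profile_loglik(x, _lambda_cov(C, 0.0))
    # the boundary can beat the interior optimum at the xatol resolution
    if ll0 > ll1:
        lam_hat, ll1 = 0.0, ll0
    lrt = max(0.0, 2.0 * (ll1 - ll0))
    p = float(sps.chi2.sf(lrt, df=1))
    return SignalResult(
        trait=str(trait.name), metric="lambda", estimate=lam_hat, p=p,
        n_tips=x.size,
        aux={"loglik": ll1, "loglik_lambda0": ll0, "lrt": lrt, "lambda_max": lam_max},
    )


# --------------------------------------------------------- Abouheif / Moran I
def abouheif_proximity(phylo: Phylogeny) -> np.ndarray:
    """Abouheif proximity matrix A (diagonal 0, not row-normalized).

    A_ij is the product over the internal nodes on the path between tips i
    and j (the MRCA counted once) of 1 / (number of direct descendants of
    the node).
    """
    n = phylo.n_tips
    A = np.zeros((n, n))
    acc = np.ones(n)  # running product of 1/dd below the current node
    for rec in phylo.nodes:
        dd = rec["n_children"]
        sets = rec["child_tip_sets"]
        for a in range(len(sets)):
            for b in range(a + 1, len(sets)):
                ia = sets[a][:, None]
                jb = sets[b][None, :]
                val = acc[ia] * acc[jb] / dd
                A[ia, jb] = val
                A[jb.T, ia.T] = val.T
        acc[rec["tips"]] *= 1.0 / dd
    return A


def abouheif_moran(
    phylo: Phylogeny,
    trait: pd.Series,
    R: int = 999,
    rng: np.random.Generator | None = None,
) -> SignalResult:
    """Moran's I with the Abouheif proximity, tested by tip permutation
    (one-sided for positive autocorrelation)."""
    sub, x = _align(phylo, trait)
    A = abouheif_proximity(sub)
    W = A / A.sum(axis=1, keepdims=True)
    z = x - x.mean()

    def moran(v: np.ndarray) -> float:
        return float(v @ W @ v) / float(v @ v)

    i_obs = moran(z)
    rng = np.random.default_rng() if rng is None else rng
    exceed = 0
    for _ in range(R):
        zp = rng.permutation(z)
        exceed += moran(zp) >= i_obs
    p = (exceed + 1) / (R + 1)
    return SignalResult(
        trait=str(trait.name), metric="moranI", estimate=i_obs, p=float(p),
        n_tips=x.size, aux={"R": R},
    )


# -------------------------------------------------------------------- summary
def signal_table(
    phylo: Phylogeny,
    traits: pd.DataFrame,
    R: int = 999,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """All three metrics for every trait column (rows: trait x metric)."""
    rng = np.random.default_rng() if rng is None else rng
    rows = []
    for name in traits.columns:
        tr = traits[name]
        rows.append(blomberg_k(phylo, tr, R=R, rng=rng).as_dict())
        rows.append(pagel_lambda(phylo, tr).as_dict())
        rows.append(abouheif_moran(phylo, tr, R=R, rng=rng).as_dict())
    return pd.DataFrame(rows)
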