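"""Environmental distances and turnover-environment permutation regressions.

Environmental distance between plots is the Euclidean distance in the space
of the leading principal components of the log-transformed (where strictly
positive) and z-scored environmental variables; the PC set retained is the
smallest reaching a target share of total variance (default 90%).  Pairwise
turnover is first residualized on geographic distance (ordinary least
squares on the plot x/y Euclidean distances), then regressed on
environmental distance; significance comes from a permutation test that
shuffles the response across pairs.

Pairwise distance observations are not independent; the permutation test is
applied at the pair level (as with permutation ANOVA on distance tables).
A plot-level Mantel-style permutation is available via ``permute='plots'``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from .io import AnalysisBundle

__all__ = [
    "env_distance",
    "spatial_distance",
    "residualize_on_space",
    "perm_regression",
    "stagewise_association",
    "subsample_association",
    "AssociationResult",
]

logger = logging.getLogger(__name__)

_COORD_COLS = ("x", "y")


def _pair_index(plots: list[str]) -> pd.MultiIndex:
    return pd.MultiIndex.from_tuples(
        list(combinations(plots, 2)), names=["plot_i", "plot_j"]
    )


def env_distance(
    env: pd.DataFrame, variance_target: float = 0.90
) -> tuple[pd.Series, dict]:
    """Pairwise environmental distances from a PCA of the plot variables.

    Strictly positive variables are log-transformed; signed variables (e.g.
    northness/eastness) pass through untransformed and are listed in the
    returned metadata.  Constant variables are dropped with a warning.
    Returns (pair-indexed distance Series, metadata dict with the retained
    PC count, explained variance and transform log).
    """
    vars_df = env.drop(columns=[c for c in _COORD_COLS if c in env.columns])
    if vars_df.shape[1] < 2:
        raise ValueError("need at least 2 environmental variables")
    if vars_df.shape[0] < 2:
        raise ValueError("need at least 2 plots")
    logged, passed, dropped = [], [], []
    cols = {}
    for name in vars_df.columns:
        col = vars_df[name].to_numpy(dtype=float)
        if np.nanstd(col) == 0:
            dropped.append(name)
            logger.warning("constant environmental variable dropped: %s", name)
            continue
        if np.all(col > 0):
            col = np.log(col)
            logged.append(name)
        else:
            passed.append(name)
        cols[name] = col
    if len(cols) < 2:
        raise ValueError("fewer than 2 usable environmental variables")
    Xm = np.column_stack(list(cols.values()))
    Xm = (Xm - Xm.mean(axis=0)) / Xm.std(axis=0, ddof=1)
    pca = PCA()
    scores = pca.fit_transform(Xm)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_pc = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    n_pc = min(n_pc, scores.shape[1])
    dist = pdist(scores[:, :n_pc])
    meta = {
        "n_pc": n_pc,
        "explained_variance": float(cum[n_pc - 1]),
        "log_transformed": logged,
        "untransformed": passed,
        "dropped": dropped,
    }
    return pd.Series(dist, index=_pair_index(list(env.index)), name="env_dist"), meta


def spatial_distance(env: pd.DataFrame) -> pd.Series:
    """Euclidean geographic distance between plots from x/y coordinates."""
    for c in _COORD_COLS:
        if c not in env.columns:
            raise ValueError(f"environment table lacks coordinate column {c!r}")
    d = pdist(env[list(_COORD_COLS)].to_numpy(dtype=float))
    return pd.Series(d, index=_pair_index(list(env.index)), name="spatial_dist")


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """slope, intercept, R^2 of y on x by least squares."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    vx = x.var()
    if vx == 0:
        return float("nan"), float(y.mean()), float("nan")
    slope = np.cov(x, y, ddof=0)[0, 1] / vx
    intercept = y.mean() - slope * x.mean()
    vy = y.var()
    r2 = 0.0 if vy == 0 else float((slope**2) * vx / vy)
    return float(slope), float(intercept), r2


def residualize_on_space(
    turnover: pd.Series, spatial: pd.Series
) -> tuple[pd.Series, dict]:
    """Residuals of pairwise turnover after OLS on geographic distance.

    With zero-variance spatial distances the residuals are the centered
    turnover values (warning logged).  Pairs with undefined turnover are
    dropped.
    """
    joined = pd.concat([turnover.rename("y"), spatial.rename("x")], axis=1).dropna()
    if joined.shape[0] < 3:
        raise ValueError("need at least 3 defined pairs to residualize")
    x = joined["x"].to_numpy()
    y = joined["y"].to_numpy()
    if x.var() == 0:
        logger.warning("zero-variance spatial distances; returning centered values")
        resid = y - y.mean()
        info = {"slope": 0.0, "intercept": float(y.mean()), "r2": float("nan")}
    else:
        slope, intercept, r2 = _ols(x, y)
        resid = y - (intercept + slope * x)
        info = {"slope": slope, "intercept": intercept, "r2": r2}
    return pd.Series(resid, index=joined.index, name="resid_turnover"), info


@dataclass
class AssociationResult:
    scope: str
    slope: float
    r2: float
    p: float
    n_pairs: int
    n_perm: int
    low_power: bool = False

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def perm_regression(
    y: pd.Series | np.ndarray,
    x: pd.Series | np.ndarray,
    n_perm: int = 5000,
    rng: np.random.Generator | None = None,
    alternative: str = "two-sided",
    scope: str = "",
) -> AssociationResult:
    """OLS of y on x with a permutation test on the slope.

    p = (r + 1)/(P + 1), r = permutations of y whose |slope| reaches the
    observed |slope| (one-sided 'greater' compares signed slopes).  Zero
    variance in x or y flags the p-value as undefined.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    slope, _, r2 = _ols(x, y)
    if x.var() == 0 or y.var() == 0:
        return AssociationResult(scope, slope, r2, float("nan"), n, n_perm, True)
    rng = np.random.default_rng() if rng is None else rng
    # slope under y-permutation: cov(x, y_perm) / var(x); vectorized
    xc = x - x.mean()
    yc = y - y.mean()
    perms = np.empty((n_perm, n))
    for i in range(n_perm):
        perms[i] = rng.permutation(yc)
    null_slopes = perms @ xc / (n * x.var())
    if alternative == "two-sided":
        r = int(np.sum(np.abs(null_slopes) >= abs(slope) - 1e-15))
    elif alternative == "greater":
        r = int(np.sum(null_slopes >= slope - 1e-15))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = (r + 1) / (n_perm + 1)
    return AssociationResult(scope, slope, r2, float(p), n, n_perm)


def _pairs_series(pairs: pd.DataFrame, column: str = "statistic") -> pd.Series:
    idx = pd.MultiIndex.from_frame(pairs[["plot_i", "plot_j"]])
    return pd.Series(pairs[column].to_numpy(), index=idx, name=column)


def stagewise_association(
    bundle: AnalysisBundle,
    mode: str = "presence",
    n_perm: int = 5000,
    rng: np.random.Generator | None = None,
    variance_target: float = 0.90,
) -> pd.DataFrame:
    """Turnover-environment association per scope.

    Scopes: overall, pooled within-stage, between-stage, and each single
    stage.  Turnover is residualized on spatial distance within each scope
    before the permutation regression.  Stages with fewer than 3 defined
    pairs are flagged low-power (and skipped when a regression is
    impossible).
    """
    from .turnover import pairwise_turnover

    if bundle.env is None:
        raise ValueError("bundle has no environmental table")
    rng = np.random.default_rng() if rng is None else rng
    pairs = pairwise_turnover(bundle, mode)
    turn = _pairs_series(pairs)
    envd, _ = env_distance(bundle.env, variance_target)
    spat = spatial_distance(bundle.env)

    scopes: dict[str, pd.DataFrame] = {
        "overall": pairs,
        "within-stage": pairs[pairs["group"] == "within"],
        "between-stage": pairs[pairs["group"] == "between"],
    }
    for stage in sorted(pairs.loc[pairs["group"] == "within", "stage_pair"].unique()):
        scopes[f"stage {stage}"] = pairs[
            (pairs["group"] == "within") & (pairs["stage_pair"] == stage)
        ]

    rows = []
    for scope, sub in scopes.items():
        sub = sub[sub["defined"]]
        idx = pd.MultiIndex.from_frame(sub[["plot_i", "plot_j"]])
        if len(idx) < 3:
            rows.append(
                AssociationResult(scope, float("nan"), float("nan"), float("nan"),
                                  len(idx), n_perm, True).as_dict()
            )
            continue
        y = turn.loc[idx]
        resid, _ = residualize_on_space(y, spat.loc[idx])
        res = perm_regression(
            resid, envd.loc[resid.index], n_perm=n_perm, rng=rng, scope=scope
        )
        res.low_power = len(idx) < 6
        rows.append(res.as_dict())
    return pd.DataFrame(rows)


def subsample_association(
    bundle: AnalysisBundle,
    k: int = 4,
    mode: str = "presence",
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
    variance_target: float = 0.90,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Stage-wise association recomputed over all k-plot subsets.

    Controls for unequal stage sizes: for each stage with >= k plots, every
    C(n, k) subset of plots is enumerated, the turnover-environment
    regression is rerun on the subset's pairs, and the mean R^2 and the
    fraction of significant subsets are reported.
    """
    from .turnover import pairwise_turnover

    if bundle.env is None:
        raise ValueError("bundle has no environmental table")
    rng = np.random.default_rng() if rng is None else rng
    pairs = pairwise_turnover(bundle, mode)
    turn = _pairs_series(pairs)
    envd, _ = env_distance(bundle.env, variance_target)
    spat = spatial_distance(bundle.env)
    stages = bundle.stages
    rows = []
    for stage in sorted({str(s) for s in stages}):
        plots = [p for p in bundle.plots if str(stages.loc[p]) == stage]
        if len(plots) < k:
            rows.append(
                dict(stage=stage, n_plots=len(plots), n_subsets=0,
                     mean_r2=float("nan"), mean_slope=float("nan"),
                     frac_significant=float("nan"),
                     note=f"fewer than {k} plots; skipped")
            )
            continue
        r2s, slopes, sig = [], [], []
        for subset in combinations(plots, k):
            idx = pd.MultiIndex.from_tuples(
                [tuple(sorted(pr, key=bundle.plots.index)) for pr in combinations(subset, 2)],
                names=["plot_i", "plot_j"],
            )
            y = turn.loc[idx].dropna()
            if len(y) < 3:
                continue
            resid, _ = residualize_on_space(y, spat.loc[y.index])
            res = perm_regression(
                resid, envd.loc[resid.index], n_perm=n_perm, rng=rng,
                scope=f"stage {stage}",
            )
            r2s.append(res.r2)
            slopes.append(res.slope)
            sig.append(res.p <= alpha if np.isfinite(res.p) else False)
        rows.append(
            dict(stage=stage, n_plots=len(plots), n_subsets=len(r2s),
                 mean_r2=float(np.mean(r2s)) if r2s else float("nan"),
                 mean_slope=float(np.mean(slopes)) if slopes else float("nan"),
                 frac_significant=float(np.mean(sig)) if sig else float("nan"),
                 note="")
        )
    return pd.DataFrame(rows)
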