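"""Tip-shuffle ("1p") null model, null distributions, and significance.

The 1p randomization shuffles species names across the phylogeny of the
*regional species pool* while leaving the community matrix untouched.  It
therefore preserves (i) the number of species within each community,
(ii) species turnover between communities, (iii) spatial autocorrelation of
overall abundances and occurrence frequencies, (iv) each species' occurrence
frequency across the landscape, and (v) species identities within each
successional stage.  Operationally a shuffle is a uniform permutation of the
pool's tip indices applied to the pool cophenetic matrix.

p-values use the add-one rank convention p = (r + 1) / (R + 1), where r
counts replicates at least as extreme as the observation, so p is never zero
and the test is exact under exchangeability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps

from .io import AnalysisBundle
from .turnover import pair_deltas, pairwise_statistic

__all__ = [
    "shuffle_tips_1p",
    "NullDistribution",
    "SignificanceResult",
    "null_distribution",
    "significance",
    "stage_statistic_fn",
    "plot_count_sensitivity",
]


def shuffle_tips_1p(n_pool: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random permutation of the pool tip indices.

    ``perm[i]`` is the tip whose distances species ``i`` receives; applying
    the permutation to the rows/columns of the pool cophenetic matrix is
    equivalent to shuffling species names across the pool phylogeny.
    """
    return rng.permutation(n_pool)


@dataclass
class NullDistribution:
    """Replicate values of a statistic under a randomization null."""

    label: str
    replicates: np.ndarray

    @property
    def n(self) -> int:
        return int(np.sum(np.isfinite(self.replicates)))

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.replicates)) if self.n else float("nan")

    @property
    def sd(self) -> float:
        # denominator R - 1
        return float(np.nanstd(self.replicates, ddof=1)) if self.n > 1 else float("nan")

    def quantile(self, q) -> np.ndarray:
        """Type-7 (linear interpolation) quantiles of the replicates."""
        return np.nanquantile(self.replicates, q, method="linear")

    @property
    def ci95(self) -> tuple[float, float]:
        lo, hi = self.quantile([0.025, 0.975])
        return float(lo), float(hi)


@dataclass
class SignificanceResult:
    observed: float
    null_mean: float
    null_sd: float
    ses: float
    p_low: float
    p_high: float
    p_two_sided: float
    ci_low: float
    ci_high: float
    outside_ci: bool
    n_replicates: int

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def null_distribution(
    statistic: Callable[[np.ndarray], float],
    bundle: AnalysisBundle,
    R: int = 999,
    rng: np.random.Generator | None = None,
    shuffler: Callable[[np.random.Generator], np.ndarray] | None = None,
    label: str = "statistic",
) -> NullDistribution:
    """Null distribution of ``statistic`` under independent pool shuffles.

    ``statistic`` receives the community-species cophenetic submatrix (under
    a shuffled pool) and returns a scalar.  ``shuffler`` defaults to the full
    1p shuffle; depth-restricted analyses pass a partial shuffler instead.
    Aborts when the statistic is undefined in more than half the replicates.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    n_pool = bundle.pool.n_tips
    if shuffler is None:
        shuffler = lambda g: shuffle_tips_1p(n_pool, g)  # noqa: E731
    reps = np.empty(R)
    for r in range(R):
        perm = shuffler(rng)
        reps[r] = statistic(bundle.community_distances(perm))
    n_bad = int(np.sum(~np.isfinite(reps)))
    if n_bad > R / 2:
        raise RuntimeError(
            f"statistic undefined in {n_bad}/{R} null replicates; "
            "the configuration cannot support a randomization test"
        )
    return NullDistribution(label=label, replicates=reps)


def significance(observed: float, null: NullDistribution) -> SignificanceResult:
    """Observed-vs-null comparison: SES, rank p-values, 95% CI exceedance.

    SES = (obs - null mean) / null sd; NaN (flagged) when the null is
    degenerate (sd = 0).  One-sided p-values use (r + 1)/(R + 1); the
    two-sided p is twice the smaller tail, capped at 1.
    """
    reps = null.replicates[np.isfinite(null.replicates)]
    R = reps.size
    mean, sd = null.mean, null.sd
    ses = float("nan")
    if np.isfinite(sd) and sd > 0 and np.isfinite(observed):
        ses = (observed - mean) / sd
    if np.isfinite(observed) and R:
        # strictly-more-extreme counting; for the continuous turnover
        # statistics ties with replicates are a null event
        r_high = int(np.sum(reps > observed))
        r_low = int(np.sum(reps < observed))
        p_high = (r_high + 1) / (R + 1)
        p_low = (r_low + 1) / (R + 1)
        p_two = min(1.0, 2.0 * min(p_low, p_high))
    else:
        p_high = p_low = p_two = float("nan")
    lo, hi = (
        NullDistribution(null.label, reps).ci95 if R else (float("nan"),) * 2
    )
    outside = bool(np.isfinite(observed) and (observed < lo or observed > hi))
    return SignificanceResult(
        observed=float(observed),
        null_mean=mean,
        null_sd=sd,
        ses=ses,
        p_low=p_low,
        p_high=p_high,
        p_two_sided=p_two,
        ci_low=lo,
        ci_high=hi,
        outside_ci=outside,
        n_replicates=R,
    )


# ------------------------------------------------------- statistic functionals
def stage_statistic_fn(
    bundle: AnalysisBundle,
    mode: str,
    scope: str = "within",
    stage: str | None = None,
    convention: str = "mean",
    pair_mask_fn: Callable[[np.ndarray], np.ndarray] | None = None,
) -> Callable[[np.ndarray], float]:
    """Build a scalar turnover functional for randomization tests.

    ``scope``: "within" (pairs in the same stage, optionally restricted to
    one stage or a collection of stages), "between" (cross-stage pairs) or
    "overall".
    ``convention``: "mean" (mean of pairwise statistics) or "pooled"
    (group-level ratio).  ``pair_mask_fn`` maps the (possibly shuffled)
    distance matrix to a species-pair mask, enabling depth restriction where
    the mask must follow the shuffled distances.
    """
    counts = bundle.counts
    stages = np.asarray([str(s) for s in bundle.stages.loc[bundle.plots]])
    same = stages[:, None] == stages[None, :]
    P = len(stages)
    iu = np.triu_indices(P, k=1)
    if scope == "within":
        sel = same[iu]
        if stage is not None:
            wanted = {str(stage)} if isinstance(stage, str) else {
                str(s) for s in np.atleast_1d(stage)
            }
            sel = sel & np.isin(stages[iu[0]], list(wanted))
    elif scope == "between":
        sel = ~same[iu]
    elif scope == "overall":
        sel = np.ones(iu[0].size, dtype=bool)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    rows, cols = iu[0][sel], iu[1][sel]
    if rows.size == 0:
        raise ValueError("no plot pairs in the requested scope")
    plot_sel = np.unique(np.concatenate([rows, cols]))

    def fn(D: np.ndarray) -> float:
        mask = pair_mask_fn(D) if pair_mask_fn is not None else None
        dw, da = pair_deltas(counts, D, mode, mask)
        if convention == "mean":
            stat = pairwise_statistic(dw, da)[rows, cols]
            return float(np.nanmean(stat)) if np.isfinite(stat).any() else float("nan")
        dw_g = dw[plot_sel]
        da_g = da[rows, cols]
        if not (np.isfinite(dw_g).any() and np.isfinite(da_g).any()):
            return float("nan")
        return float(1.0 - np.nanmean(dw_g) / np.nanmean(da_g))

    return fn


# ------------------------------------------------- plot-count sensitivity test
def plot_count_sensitivity(
    scenario_config,
    n_runs: int = 100,
    mode: str = "presence",
    seed: int | None = None,
    forced_effect: bool = False,
) -> dict:
    """Does per-stage turnover merely track the number of plots per stage?

    For each simulated dataset, the Pearson correlation between the per-stage
    mean within-stage turnover and the stage plot count is recorded; under
    neutral assembly the mean correlation should be close to zero.  With
    ``forced_effect`` the simulator widens each stage's environmental window
    in proportion to its plot count (a positive control in which turnover
    *must* scale with plot count).

    Returns a dict with per-run correlations, their mean, and flags.
    """
    from . import synthetic  # local import to avoid a cycle
    from .turnover import pairwise_turnover

    counts_per_stage = np.asarray(scenario_config.plots_per_stage, dtype=float)
    if np.all(counts_per_stage == counts_per_stage[0]):
        return {
            "correlations": np.full(n_runs, np.nan),
            "mean_correlation": float("nan"),
            "defined": False,
            "note": "identical plot counts across stages; correlation undefined",
        }
    ss = np.random.SeedSequence(seed)
    correlations = np.empty(n_runs)
    for run, child in enumerate(ss.spawn(n_runs)):
        cfg = scenario_config.replace(seed=int(child.generate_state(1)[0] % 2**31))
        if forced_effect:
            cfg = cfg.replace(stage_window_scale_by_count=True)
        bundle = synthetic.generate_bundle(cfg)
        pairs = pairwise_turnover(bundle, mode)
        within = pairs[(pairs["group"] == "within") & pairs["defined"]]
        per_stage = within.groupby("stage_pair")["statistic"].mean()
        stage_order = sorted(per_stage.index)
        n_plots = bundle.stages.value_counts()
        x = np.array([float(n_plots[s]) for s in stage_order])
        y = per_stage.loc[stage_order].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            correlations[run] = np.nan
        else:
            correlations[run] = sps.pearsonr(x, y).statistic
    return {
        "correlations": correlations,
        "mean_correlation": float(np.nanmean(correlations)),
        "defined": True,
        "note": "",
    }
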