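"""Simulation experiments: null-model calibration, power, signal recovery.

These are the package's standard self-diagnostics, run over many synthetic
datasets generated under the study design (27 plots in stages 5/4/5/6/7,
143 community species from a 410-species pool, root age 128 Myr):

* ``neutral_calibration`` - exactness of the 1p randomization test: under
  neutral (lottery) assembly the two-sided p-value of within-stage turnover
  must be uniform, so the rejection rate at alpha equals alpha.
* ``deep_filtering_power`` - recovery of a planted deep clade-sorting
  signal in the late successional stages: positive significant within-stage
  turnover, an environment association confined to the late stages, and a
  depth profile significant only above the planted clade-split age.
* ``signal_recovery`` - Brownian traits give Blomberg K near 1 and Pagel
  lambda near 1; white noise gives lambda near 0; an intermediate lambda is
  recovered.
* ``nodesig_hypergeometric_gof`` - the tip-shuffle null of a node count
  follows the closed-form hypergeometric law.

One pool phylogeny is shared across a run's datasets: the randomization
tests are conditional on the tree.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .depth import depth_profile
from .env import stagewise_association
from .nullmodels import (
    null_distribution,
    shuffle_tips_1p,
    significance,
    stage_statistic_fn,
)
from .signal import blomberg_k, pagel_lambda
from .synthetic import (
    ScenarioConfig,
    evolve_trait,
    generate_bundle,
    planted_split_age,
    simulate_tree,
)
from .tree import Phylogeny

__all__ = [
    "neutral_calibration",
    "deep_filtering_power",
    "signal_recovery",
    "nodesig_hypergeometric_gof",
]


def _spawn_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % 2**31)


def neutral_calibration(
    n_datasets: int = 500,
    R: int = 199,
    alpha: float = 0.05,
    seed: int | None = None,
    pool: Phylogeny | None = None,
    mode: str = "presence",
) -> dict:
    """Type-I error of the within-stage turnover test under neutral assembly.

    Returns the p-values, the rejection rate at ``alpha`` and the binomial
    95% interval the rate should fall in when the test is exact.
    """
    ss = np.random.SeedSequence(seed)
    s_pool, s_data, s_null = ss.spawn(3)
    if pool is None:
        pool = simulate_tree(410, seed=_spawn_seed(s_pool))
        pool.cophenetic()
    rng = np.random.default_rng(s_null)
    pvals = np.empty(n_datasets)
    for i, child in enumerate(s_data.spawn(n_datasets)):
        cfg = ScenarioConfig(seed=_spawn_seed(child))
        bundle = generate_bundle(cfg, pool=pool, with_traits=False)
        fn = stage_statistic_fn(bundle, mode, scope="within")
        obs = fn(bundle.community_distances())
        null = null_distribution(fn, bundle, R=R, rng=rng)
        pvals[i] = significance(obs, null).p_two_sided
    rate = float(np.mean(pvals <= alpha))
    half = 1.96 * np.sqrt(alpha * (1 - alpha) / n_datasets)
    return {
        "pvalues": pvals,
        "rejection_rate": rate,
        "alpha": alpha,
        "binomial_ci": (alpha - half, alpha + half),
        "n_datasets": n_datasets,
        "R": R,
    }


def deep_filtering_power(
    n_datasets: int = 100,
    R: int = 199,
    n_perm: int = 499,
    alpha: float = 0.05,
    seed: int | None = None,
    pool: Phylogeny | None = None,
    n_depth_datasets: int = 30,
    split_age_target: float = 100.0,
) -> dict:
    """Pattern recovery under the planted deep clade-sorting scenario.

    Measures, across datasets: (i) the fraction with significantly positive
    within-late-stage presence turnover (power); (ii) the fraction showing
    the late-only environment-association pattern (some late stage
    significant, no early stage significant); (iii) depth selectivity -- the
    rate of significant positive SES at thresholds below vs above the
    planted clade-split age (profiled on the first ``n_depth_datasets``
    datasets).
    """
    ss = np.random.SeedSequence(seed)
    s_pool, s_data, s_rng = ss.spawn(3)
    if pool is None:
        pool = simulate_tree(410, seed=_spawn_seed(s_pool))
        pool.cophenetic()
    split = planted_split_age(pool, split_age_target)
    grid = np.array([0.4 * split, 0.7 * split, split + 5.0,
                     min(128.0, pool.root_age)])
    rng = np.random.default_rng(s_rng)

    late_sig = np.zeros(n_datasets, dtype=bool)
    late_only_env = np.zeros(n_datasets, dtype=bool)
    shallow_hits, deep_hits = [], []
    for i, child in enumerate(s_data.spawn(n_datasets)):
        cfg = ScenarioConfig(
            scenario="deep_filtering_late", seed=_spawn_seed(child),
            split_age_target=split_age_target,
        )
        bundle = generate_bundle(cfg, pool=pool, with_traits=False)

        # (i) within-late-stage turnover (stages 4-5 jointly) vs the 1p null
        fn = stage_statistic_fn(bundle, "presence", scope="within",
                                stage=("4", "5"))
        obs = fn(bundle.community_distances())
        res = significance(obs, null_distribution(fn, bundle, R=R, rng=rng))
        late_sig[i] = res.p_high <= alpha and res.observed > 0

        # (ii) environment association confined to the late stages
        assoc = stagewise_association(
            bundle, n_perm=n_perm, rng=rng
        ).set_index("scope")
        late_p = [assoc.loc[f"stage {s}", "p"] for s in ("4", "5")]
        early_p = [assoc.loc[f"stage {s}", "p"] for s in ("1", "2", "3")]
        late_only_env[i] = (
            any(p <= alpha for p in late_p)
            and not any(p <= alpha for p in early_p)
        )

        # (iii) depth selectivity on a subset of datasets
        if i < n_depth_datasets:
            prof = depth_profile(
                bundle, grid=grid, R=R, rng=rng, stages=["4", "5"],
                alpha=alpha,
            )
            pos_sig = prof["significant"] & (prof["ses"] > 0)
            shallow_hits.extend(pos_sig[prof["threshold"] < split])
            deep_hits.extend(pos_sig[prof["threshold"] > split])

    return {
        "power_late_turnover": float(late_sig.mean()),
        "frac_late_only_env": float(late_only_env.mean()),
        "depth_sig_rate_below_split": (
            float(np.mean(shallow_hits)) if shallow_hits else float("nan")
        ),
        "depth_sig_rate_above_split": (
            float(np.mean(deep_hits)) if deep_hits else float("nan")
        ),
        "planted_split_age": split,
        "grid": grid,
        "n_datasets": n_datasets,
        "n_depth_datasets": n_depth_datasets,
    }


def signal_recovery(
    n_tips: int = 128,
    n_sims: int = 200,
    seed: int | None = None,
) -> dict:
    """Estimator recovery for Blomberg K and Pagel lambda on simulated traits."""
    ss = np.random.SeedSequence(seed)
    s_tree, s_sim = ss.spawn(2)
    tree = simulate_tree(n_tips, seed=_spawn_seed(s_tree))
    tree.cophenetic()
    rng = np.random.default_rng(s_sim)

    def series(x):
        return pd.Series(x, index=tree.taxa, name="trait")

    k_bm, lam_bm = [], []
    for _ in range(n_sims):
        x = evolve_trait(tree, "BM", rng=rng)
        k_bm.append(blomberg_k(tree, series(x), R=0).estimate)
        lam_bm.append(pagel_lambda(tree, series(x)).estimate)
    lam_white = [
        pagel_lambda(tree, series(evolve_trait(tree, "white", rng=rng))).estimate
        for _ in range(n_sims // 2)
    ]
    lam_half = [
        pagel_lambda(
            tree, series(evolve_trait(tree, "lambda", lam=0.5, rng=rng))
        ).estimate
        for _ in range(n_sims // 2)
    ]
    return {
        "mean_K_bm": float(np.mean(k_bm)),
        "median_lambda_bm": float(np.median(lam_bm)),
        "mean_lambda_white": float(np.mean(lam_white)),
        "mean_lambda_half": float(np.mean(lam_half)),
        "n_sims": n_sims,
        "n_tips": n_tips,
    }


def nodesig_hypergeometric_gof(
    n_pool: int = 64,
    richness: int = 20,
    n_draws: int = 4000,
    seed: int | None = None,
) -> dict:
    """Chi-square GOF of the shuffle-null node count vs Hypergeom(N, c, m)."""
    ss = np.random.SeedSequence(seed)
    s_tree, s_draw = ss.spawn(2)
    pool = simulate_tree(n_pool, seed=_spawn_seed(s_tree))
    rec = next(r for r in pool.nodes
               if n_pool // 6 <= r["tips"].size <= n_pool // 2)
    clade = set(rec["tips"].tolist())
    c = len(clade)
    rng = np.random.default_rng(s_draw)
    plot_idx = np.arange(richness)
    draws = np.array([
        len(clade & set(shuffle_tips_1p(n_pool, rng)[plot_idx].tolist()))
        for _ in range(n_draws)
    ])
    dist = sps.hypergeom(n_pool, c, richness)
    ks = np.arange(0, min(c, richness) + 1)
    expected = dist.pmf(ks) * n_draws
    observed = np.array([(draws == k).sum() for k in ks], dtype=float)
    obs_b, exp_b, acc_o, acc_e = [], [], 0.0, 0.0
    for o, e in zip(observed, expected):  # merge sparse tail bins
        acc_o += o
        acc_e += e
        if acc_e >= 5:
            obs_b.append(acc_o)
            exp_b.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0:
        obs_b[-1] += acc_o
        exp_b[-1] += acc_e
    exp_b = np.array(exp_b) * sum(obs_b) / sum(exp_b)
    stat, p = sps.chisquare(obs_b, exp_b)
    return {"p": float(p), "chi2": float(stat), "n_draws": n_draws,
            "clade_size": c, "richness": richness, "n_pool": n_pool}
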