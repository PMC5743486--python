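"""Phylogenetic alpha diversity and turnover (PIst / Bst).

The Hardy & Senterre decomposition partitions the mean phylogenetic distance
between distinct species (presence/absence mode) or between individuals of
distinct species (abundance mode) into within- and between-community
components:

    Delta_w(k)    mean distance within plot k          (alpha diversity, Myr)
    Delta_a(k,l)  mean distance across plots k and l   (Myr)

and expresses turnover as

    PIst = 1 - Delta_w / Delta_a        (presence/absence)
    Bst  = 1 - Delta*_w / Delta*_a      (abundance-weighted)

Positive values indicate phylogenetic clustering (species within plots more
related than species from different plots), negative values overdispersion.

Two aggregation conventions are exposed:

* pairwise: one statistic per unordered plot pair, using the symmetric form
  ``1 - mean(Delta_w(k), Delta_w(l)) / Delta_a(k, l)``; this is the form
  needed to regress turnover on pairwise environmental distance;
* pooled: the stage-level ratio ``1 - mean_k Delta_w / mean_{kl} Delta_a``
  over a group of plots, the original population-genetics-style estimator.

Cross-plot pairs of the *same* species are excluded from both numerator and
denominator ("distinct species"); undefined quantities (singleton plots,
no valid pair under a phylogenetic-depth mask) propagate as NaN, never as 0.

All functions are vectorized: with plot weight matrix ``W`` (binary presence
or relative abundance rows) and masked distance matrix ``D``, every
``Delta`` is a quadratic form ``W (D o M) W^T / (W M W^T)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .io import AnalysisBundle

__all__ = [
    "plot_weights",
    "pair_deltas",
    "alpha_within",
    "beta_between",
    "pairwise_statistic",
    "pairwise_turnover",
    "grouped_turnover",
    "pooled_statistic",
    "evenness",
    "MODES",
]

MODES = ("presence", "abundance")


def _check_mode(mode: str) -> None:
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")


def plot_weights(counts: np.ndarray, mode: str) -> np.ndarray:
    """Per-plot species weights: binary presence or relative abundances f_ik."""
    _check_mode(mode)
    counts = np.asarray(counts, dtype=float)
    if mode == "presence":
        return (counts > 0).astype(float)
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("every plot needs at least one individual")
    return counts / totals


def pair_deltas(
    counts: np.ndarray,
    D: np.ndarray,
    mode: str,
    pair_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """All within- and between-plot mean distances at once.

    Returns ``(delta_w, delta_a)`` where ``delta_w[k]`` is the mean
    within-plot distance (NaN when plot k has < 2 distinct species, or no
    retained pair under ``pair_mask``) and ``delta_a[k, l]`` the cross-plot
    mean distance (diagonal entries equal ``delta_w``).

    ``pair_mask`` is an optional symmetric boolean species-pair filter (used
    by phylogenetic-depth restriction); same-species pairs are always
    excluded.
    """
    W = plot_weights(counts, mode)
    S = D.shape[0]
    M = np.ones((S, S))
    np.fill_diagonal(M, 0.0)
    if pair_mask is not None:
        M = M * np.asarray(pair_mask, dtype=float)
    num = W @ (D * M) @ W.T
    den = W @ M @ W.T
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return np.diag(delta).copy(), delta


def alpha_within(
    plot_counts: np.ndarray, D: np.ndarray, mode: str
) -> float:
    """Mean phylogenetic distance within one plot (Delta_w, Myr).

    Presence mode: unweighted mean of d_ij over unordered pairs of distinct
    present species.  Abundance mode: sum f_i f_j d_ij / sum f_i f_j over
    i != j.  NaN when fewer than two distinct species are present.
    """
    dw, _ = pair_deltas(np.atleast_2d(plot_counts), D, mode)
    return float(dw[0])


def beta_between(
    counts_k: np.ndarray, counts_l: np.ndarray, D: np.ndarray, mode: str
) -> float:
    """Mean phylogenetic distance between two plots (Delta_a, Myr),
    excluding cross-plot pairs of the same species."""
    counts = np.vstack([np.asarray(counts_k), np.asarray(counts_l)])
    _, da = pair_deltas(counts, D, mode)
    return float(da[0, 1])


def pairwise_statistic(
    delta_w: np.ndarray, delta_a: np.ndarray
) -> np.ndarray:
    """Symmetric pairwise turnover matrix: 1 - mean(dw_k, dw_l) / da_kl."""
    dw_pair = 0.5 * (delta_w[:, None] + delta_w[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = 1.0 - dw_pair / delta_a
    stat[~np.isfinite(stat)] = np.nan
    np.fill_diagonal(stat, np.nan)
    return stat


def turnover_matrix(
    counts: np.ndarray,
    D: np.ndarray,
    mode: str,
    pair_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Pairwise PIst (presence) or Bst (abundance) matrix in one call."""
    dw, da = pair_deltas(counts, D, mode, pair_mask)
    return pairwise_statistic(dw, da)


# ------------------------------------------------------------------ records
@dataclass
class TurnoverSummary:
    grouping: str
    group: str
    statistic: str
    mean: float
    se: float
    n_pairs: int
    pooled: float

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def _stage_labels(bundle: AnalysisBundle) -> np.ndarray:
    return np.asarray([str(s) for s in bundle.stages.loc[bundle.plots]])


def pairwise_turnover(
    bundle: AnalysisBundle,
    mode: str,
    D: np.ndarray | None = None,
    pair_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """One record per unordered plot pair.

    Columns: plot_i, plot_j, stage_i, stage_j, group ("within"/"between"),
    stage_pair, delta_w_i, delta_w_j, delta_a, statistic, defined.
    Undefined pairs carry NaN and ``defined=False``; they are excluded from
    downstream means.
    """
    _check_mode(mode)
    if D is None:
        D = bundle.D
    counts = bundle.counts
    dw, da = pair_deltas(counts, D, mode, pair_mask)
    stat = pairwise_statistic(dw, da)
    plots = bundle.plots
    stages = _stage_labels(bundle)
    rows = []
    for i, j in combinations(range(len(plots)), 2):
        si, sj = stages[i], stages[j]
        within = si == sj
        rows.append(
            {
                "plot_i": plots[i],
                "plot_j": plots[j],
                "stage_i": si,
                "stage_j": sj,
                "group": "within" if within else "between",
                "stage_pair": si if within else f"{min(si, sj)}-{max(si, sj)}",
                "delta_w_i": dw[i],
                "delta_w_j": dw[j],
                "delta_a": da[i, j],
                "statistic": stat[i, j],
                "defined": bool(np.isfinite(stat[i, j])),
            }
        )
    return pd.DataFrame(rows)


def pooled_statistic(
    pairs: pd.DataFrame, plot_dw: dict[str, float] | None = None
) -> float:
    """Group-level ratio convention: 1 - mean(Delta_w) / mean(Delta_a).

    ``Delta_w`` is averaged over the distinct plots contributing to the
    group's pairs (each plot once), ``Delta_a`` over the group's defined
    pairs.
    """
    ok = pairs[pairs["defined"]]
    if ok.empty:
        return float("nan")
    dw_by_plot: dict[str, float] = {}
    for _, row in ok.iterrows():
        dw_by_plot[row["plot_i"]] = row["delta_w_i"]
        dw_by_plot[row["plot_j"]] = row["delta_w_j"]
    dw_vals = np.array([v for v in dw_by_plot.values() if np.isfinite(v)])
    da_vals = ok["delta_a"].to_numpy()
    if dw_vals.size == 0 or not np.isfinite(da_vals).any():
        return float("nan")
    return float(1.0 - dw_vals.mean() / np.nanmean(da_vals))


def _summarize(pairs: pd.DataFrame, grouping: str, group: str, statistic: str
               ) -> TurnoverSummary:
    vals = pairs.loc[pairs["defined"], "statistic"].to_numpy()
    n = vals.size
    mean = float(vals.mean()) if n else float("nan")
    se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else (0.0 if n == 1 else float("nan"))
    return TurnoverSummary(
        grouping=grouping,
        group=group,
        statistic=statistic,
        mean=mean,
        se=se,
        n_pairs=int(n),
        pooled=pooled_statistic(pairs),
    )


def grouped_turnover(pairs: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Aggregate pairwise records to the groupings used in the figures.

    Emits, per statistic: overall; pooled within-stage; pooled between-stage;
    each single stage; each stage pair.  Both the mean-of-pairwise values
    (with descriptive SE) and the pooled-ratio convention are reported.
    """
    stat_name = "PIst" if mode == "presence" else "Bst"
    out = [_summarize(pairs, "overall", "all", stat_name)]
    within = pairs[pairs["group"] == "within"]
    between = pairs[pairs["group"] == "between"]
    out.append(_summarize(within, "within-stage", "pooled", stat_name))
    out.append(_summarize(between, "between-stage", "pooled", stat_name))
    for stage in sorted(within["stage_pair"].unique()):
        out.append(
            _summarize(within[within["stage_pair"] == stage], "stage", stage, stat_name)
        )
    for sp in sorted(between["stage_pair"].unique()):
        out.append(
            _summarize(between[between["stage_pair"] == sp], "stage-pair", sp, stat_name)
        )
    return pd.DataFrame([s.as_dict() for s in out])


# ------------------------------------------------------------------ evenness
def evenness(plot_counts: np.ndarray) -> float:
    """Shannon evenness H / ln(S) in [0, 1] over species with positive counts.

    A single-species plot is returned as 0.0 (H = 0 and ln(1) = 0; the value
    is defined as zero evenness rather than left undefined).
    """
    counts = np.asarray(plot_counts, dtype=float)
    counts = counts[counts > 0]
    if counts.size == 0:
        raise ValueError("plot has no individuals")
    if counts.size == 1:
        return 0.0
    f = counts / counts.sum()
    H = -np.sum(f * np.log(f))
    return float(H / np.log(counts.size))


def alpha_table(bundle: AnalysisBundle) -> pd.DataFrame:
    """Per-plot alpha diversity: Delta_w in both modes, richness, evenness."""
    D = bundle.D
    counts = bundle.counts
    dw_p, _ = pair_deltas(counts, D, "presence")
    dw_a, _ = pair_deltas(counts, D, "abundance")
    return pd.DataFrame(
        {
            "plot": bundle.plots,
            "stage": _stage_labels(bundle),
            "richness": (counts > 0).sum(axis=1),
            "n_individuals": counts.sum(axis=1).astype(int),
            "delta_w_presence": dw_p,
            "delta_w_abundance": dw_a,
            "shannon_evenness": [evenness(c) for c in counts],
        }
    ).set_index("plot")
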