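"""Config-driven orchestration of the full analysis sequence.

``run`` executes, on any aligned bundle: per-plot alpha diversity and
evenness; overall / within-stage / between-stage turnover with tip-shuffle
null CIs; per-stage and stage-pair turnover; turnover-environment
permutation regressions; the phylogenetic-depth SES profile; the node
enrichment (nodesig) table; and trait phylogenetic signal.  Outputs are TSV
tables plus a JSON manifest recording the seed and parameters; undefined or
flagged quantities are counted in the manifest rather than silently
dropped.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clades, depth, env as env_mod, nullmodels, signal as signal_mod
from . import synthetic, turnover
from .io import AnalysisBundle, align_and_prune, read_community, read_env
from .io import read_newick, read_stage_map, read_traits

__all__ = ["RunConfig", "run", "load_bundle"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one analysis run needs.

    Either ``scenario`` (synthetic data) or the five input paths must be
    given.  ``modes`` selects presence/absence and/or abundance weighting;
    ``R_null`` the tip-shuffle replicates; ``n_perm`` the permutation count
    of the environment regressions.
    """

    outdir: str | Path = "phyloturn_out"
    scenario: str | None = None
    tree_path: str | None = None
    community_path: str | None = None
    stage_path: str | None = None
    env_path: str | None = None
    trait_path: str | None = None
    modes: tuple[str, ...] = ("presence", "abundance")
    R_null: int = 999
    n_perm: int = 5000
    grid_min: float = 30.0
    grid_max: float | None = None
    grid_step: float = 10.0
    variance_target: float = 0.90
    resample_k: int = 4
    seed: int | None = None

    def __post_init__(self):
        if self.R_null < 1 or self.n_perm < 1:
            raise ValueError("replicate counts must be positive")
        for m in self.modes:
            if m not in turnover.MODES:
                raise ValueError(f"unknown mode {m!r}")


def load_bundle(config: RunConfig) -> AnalysisBundle:
    if config.scenario:
        cfg = synthetic.ScenarioConfig(scenario=config.scenario, seed=config.seed)
        return synthetic.generate_bundle(cfg)
    needed = (config.tree_path, config.community_path, config.stage_path)
    if any(p is None for p in needed):
        raise ValueError("need scenario or tree/community/stage paths")
    pool = read_newick(config.tree_path)
    community = read_community(config.community_path)
    stages = read_stage_map(config.stage_path)
    env = read_env(config.env_path) if config.env_path else None
    traits = read_traits(config.trait_path) if config.trait_path else None
    return align_and_prune(pool, community, stages, env=env, traits=traits)


def run(config: RunConfig, bundle: AnalysisBundle | None = None) -> dict[str, Path]:
    """Execute the full analysis; returns the paths of the written tables."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if bundle is None:
        bundle = load_bundle(config)
    rng = np.random.default_rng(config.seed)
    written: dict[str, Path] = {}
    flags: dict[str, int] = {}

    def emit(name: str, df: pd.DataFrame, index=False) -> None:
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=index)
        written[name] = path

    # 1. alpha diversity / evenness
    alpha = turnover.alpha_table(bundle)
    emit("alpha_diversity", alpha, index=True)

    # 2-3. turnover summaries with null CIs, per mode
    grid_max = config.grid_max
    if grid_max is None:
        grid_max = min(128.0, bundle.pool.root_age)
    summaries, stage_rows = [], []
    for mode in config.modes:
        pairs = turnover.pairwise_turnover(bundle, mode)
        flags[f"undefined_pairs_{mode}"] = int((~pairs["defined"]).sum())
        grouped = turnover.grouped_turnover(pairs, mode)
        for scope in ("overall", "within", "between"):
            fn = nullmodels.stage_statistic_fn(
                bundle, mode,
                scope={"overall": "overall", "within": "within",
                       "between": "between"}[scope],
            )
            obs = fn(bundle.community_distances())
            null = nullmodels.null_distribution(
                fn, bundle, R=config.R_null, rng=rng, label=f"{mode}_{scope}"
            )
            res = nullmodels.significance(obs, null)
            summaries.append(dict(mode=mode, scope=scope, **res.as_dict()))
        stage_grouped = grouped.assign(mode=mode)
        # per-stage null tests
        for stage in sorted({str(s) for s in bundle.stages}):
            try:
                fn = nullmodels.stage_statistic_fn(
                    bundle, mode, scope="within", stage=stage
                )
            except ValueError:
                continue
            obs = fn(bundle.community_distances())
            if not np.isfinite(obs):
                flags[f"undefined_stage_{stage}_{mode}"] = 1
                continue
            null = nullmodels.null_distribution(
                fn, bundle, R=config.R_null, rng=rng, label=f"{mode}_stage{stage}"
            )
            res = nullmodels.significance(obs, null)
            stage_rows.append(dict(mode=mode, stage=stage, **res.as_dict()))
        emit(f"stage_turnover_{mode}", stage_grouped)
    emit("turnover_summary", pd.DataFrame(summaries))
    emit("stage_tests", pd.DataFrame(stage_rows))

    # 4. environment association
    if bundle.env is not None:
        assoc_frames = []
        for mode in config.modes:
            assoc = env_mod.stagewise_association(
                bundle, mode=mode, n_perm=config.n_perm, rng=rng,
                variance_target=config.variance_target,
            )
            assoc_frames.append(assoc.assign(mode=mode))
        emit("env_association", pd.concat(assoc_frames, ignore_index=True))
        sub = env_mod.subsample_association(
            bundle, k=config.resample_k, mode="presence",
            n_perm=min(config.n_perm, 999), rng=rng,
            variance_target=config.variance_target,
        )
        emit("subsample_association", sub)

    # 5. depth profile (presence mode, as in the headline analysis)
    grid = depth.threshold_grid(config.grid_min, grid_max, config.grid_step)
    profile = depth.depth_profile(
        bundle, mode="presence", grid=grid, R=config.R_null, rng=rng
    )
    emit("depth_profile", profile)

    # 6. nodesig
    ns = clades.nodesig(bundle, R=config.R_null, rng=rng)
    emit("nodesig", ns)

    # 7. trait signal
    if bundle.traits is not None:
        sig = signal_mod.signal_table(
            bundle.tree, bundle.traits, R=config.R_null, rng=rng
        )
        emit("signal", sig)

    manifest = {
        "config": {k: (str(v) if isinstance(v, Path) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "seed": config.seed,
        "n_plots": len(bundle.plots),
        "n_species": len(bundle.species),
        "n_pool": bundle.pool.n_tips,
        "flags": flags,
        "tables": {k: str(v) for k, v in written.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    written["manifest"] = outdir / "manifest.json"
    return written
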