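"""Synthetic chronosequence data with the structure the analyses assume.

The generator emulates a subtropical-forest successional study design:
27 plots in five successional stages (5/4/5/6/7 plots), a regional species
pool of 410 species on a dated ultrametric phylogeny with root age 128 Myr,
of which 143 species occur in the plots; skewed abundance distributions
that become more even toward late succession; and an underlying
environmental gradient, observed through noisy correlated variables, that
can drive clade-level species sorting.

Scenarios
---------
neutral
    Uniform lottery assembly from the community pool; the reference
    condition under which randomization tests must be exact.
filtering_conserved
    Gaussian niche filtering along the gradient with a Brownian (hence
    phylogenetically conserved) niche trait.
overdispersion
    Filtering plus a repulsion rule against co-occurring close relatives.
dominance_shift
    Near-constant composition with an evenness parameter increasing across
    stages (abundance shifts without species shifts).
deep_filtering_late
    Stages 1-3 neutral; stages 4-5 sort two anciently diverged clades to
    opposite gradient ends, planting a clustering signal that exists only
    at phylogenetic depths at or above the clade-split age.
"""

from __future__ import annotations

import dataclasses
import json
import random as _random
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .io import AnalysisBundle, align_and_prune
from .tree import Phylogeny

__all__ = [
    "ScenarioConfig",
    "SCENARIOS",
    "simulate_tree",
    "evolve_trait",
    "assemble_communities",
    "generate_bundle",
    "make_fixture",
    "gamma_statistic",
]

SCENARIOS = (
    "neutral",
    "filtering_conserved",
    "overdispersion",
    "dominance_shift",
    "deep_filtering_late",
)

ENV_VAR_NAMES = (
    "elevation", "slope", "northness", "eastness", "pH", "moisture",
    "CN_ratio", "PAR", "rfr_ratio", "P_total", "N_inorg",
)

TRAIT_NAMES = (
    "leaf_area", "SLA", "leaf_N", "leaf_P", "wood_density", "max_height",
)


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic dataset (defaults are the study design)."""

    scenario: str = "neutral"
    pool_size: int = 410
    n_community: int = 143
    plots_per_stage: tuple[int, ...] = (5, 4, 5, 6, 7)
    birth: float = 1.0
    death: float = 0.0
    root_age: float = 128.0
    # niche / filtering
    niche_model: str = "BM"              # BM | two_clade_shift
    niche_breadth: float = 0.5           # Gaussian kernel width (gradient units)
    shift_delta: float = 1.0             # clade niche offset (gradient units)
    split_age_target: float = 100.0      # planted clade-split age (Myr)
    repulsion_distance: float = 30.0     # min cophenetic distance (Myr)
    # abundance structure (per stage, early -> late)
    richness_mean: float = 30.0
    individuals_by_stage: tuple[int, ...] = (350, 290, 240, 200, 170)
    lognormal_sigma_by_stage: tuple[float, ...] = (1.6, 1.3, 1.0, 0.85, 0.7)
    # environment
    n_env_vars: int = 10
    latent_factors: int = 1
    env_noise_sd: float = 0.25
    spatial_autocorr: bool = False
    stage_window_scale_by_count: bool = False
    pad_to_target: bool = True
    seed: int | None = None

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        if any(p <= 0 for p in self.plots_per_stage):
            raise ValueError("plots per stage must be positive")
        if self.pool_size < self.n_community:
            raise ValueError("pool must be at least as large as the community target")
        if len(self.individuals_by_stage) != len(self.plots_per_stage):
            raise ValueError("individuals_by_stage must match plots_per_stage")
        if len(self.lognormal_sigma_by_stage) != len(self.plots_per_stage):
            raise ValueError("lognormal_sigma_by_stage must match plots_per_stage")

    def replace(self, **kw) -> "ScenarioConfig":
        return dataclasses.replace(self, **kw)


# ------------------------------------------------------------------ phylogeny
def simulate_tree(
    n_tips: int,
    birth: float = 1.0,
    death: float = 0.0,
    root_age_target: float = 128.0,
    seed: int | None = None,
    max_retries: int = 20,
) -> Phylogeny:
    """Ultrametric birth-death tree conditioned on ``n_tips``, rescaled so
    the root age equals ``root_age_target`` (Myr)."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if death >= birth:
        raise ValueError("death rate must be below birth rate")
    rng = _random.Random(seed)
    last_err: Exception | None = None
    for _ in range(max_retries):
        try:
            t = treesim.birth_death_tree(
                birth_rate=birth,
                death_rate=death,
                num_extant_tips=n_tips,
                rng=rng,
            )
            break
        except Exception as exc:  # full-extinction resample
            last_err = exc
    else:
        raise RuntimeError(f"tree simulation failed after {max_retries} tries: {last_err}")
    # The simulator stops at the instant of the n-th speciation, leaving the
    # final sister pair at zero distance.  Extend every extant tip by the
    # sojourn time at n lineages, Exp(n (b + d)) -- for a pure-birth process
    # this is exactly the distribution of the final internode interval
    # conditioned on n tips.
    extra = rng.expovariate(n_tips * (birth + death))
    for leaf in t.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    for i, leaf in enumerate(t.leaf_node_iter()):
        leaf.taxon.label = f"S{i + 1:04d}"
    phylo = Phylogeny(t, require_ultrametric=False)
    return phylo.rescale(root_age_target)


def gamma_statistic(phylo: Phylogeny) -> float:
    """Pybus-Harvey gamma from internode intervals (0 expected under pure
    birth; used as a generator diagnostic)."""
    depths = sorted(rec["depth"] for rec in phylo.nodes)
    n = phylo.n_tips
    if n < 3:
        raise ValueError("gamma needs at least 3 tips")
    times = np.array(depths + [phylo.height])
    u = np.diff(times)  # u[j-2] = interval with j lineages, j = 2..n
    k = np.arange(2, n + 1)
    ku = k * u
    T = ku.sum()
    partial = np.cumsum(ku)[:-1]  # sums for i = 2..n-1
    num = partial.mean() - T / 2.0
    return float(num / (T * np.sqrt(1.0 / (12.0 * (n - 2)))))


# --------------------------------------------------------------------- traits
def evolve_trait(
    phylo: Phylogeny,
    model: str = "BM",
    sigma: float = 1.0,
    lam: float = 1.0,
    delta: float = 2.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate a continuous trait on the tree.

    ``BM``: Brownian motion (Gaussian increments proportional to branch
    length, drawn from the tree covariance).  ``lambda``: BM on the
    lambda-transformed covariance.  ``white``: independent Gaussian noise.
    ``two_clade_shift``: BM plus +delta / -delta offsets for the two basal
    clades (deep niche conservatism).
    """
    rng = np.random.default_rng() if rng is None else rng
    n = phylo.n_tips
    if model == "white":
        return sigma * rng.standard_normal(n)
    C = phylo.bm_covariance() / phylo.height  # unit-depth scaling
    if model == "lambda":
        V = lam * C
        np.fill_diagonal(V, np.diag(C))
        C = V
    elif model not in ("BM", "two_clade_shift"):
        raise ValueError(f"unknown trait model {model!r}")
    L = np.linalg.cholesky(C + 1e-12 * np.eye(n))
    x = sigma * (L @ rng.standard_normal(n))
    if model == "two_clade_shift":
        root = next(rec for rec in phylo.nodes if rec["is_root"])
        first = root["child_tip_sets"][0]
        offsets = np.full(n, -delta / 2.0)
        offsets[first] = delta / 2.0
        x = x + offsets
    return x


def _planted_split(phylo: Phylogeny, target_age: float) -> dict:
    """Choose the internal node whose two sides become the sorted clades.

    Candidates are non-root internal nodes holding >= 15% of the pool with
    at least 5 tips on each side; the age closest to ``target_age`` wins.
    """
    n = phylo.n_tips
    best, best_score = None, np.inf
    for rec in phylo.nodes:
        if rec["is_root"]:
            continue
        if rec["tips"].size < max(10, int(0.15 * n)):
            continue
        sides = rec["child_tip_sets"]
        if len(sides) < 2 or min(s.size for s in sides) < 5:
            continue
        score = abs(rec["age"] - target_age)
        if score < best_score:
            best, best_score = rec, score
    if best is None:  # fall back: largest non-root clade
        cands = [r for r in phylo.nodes
                 if not r["is_root"] and len(r["child_tip_sets"]) >= 2]
        best = max(cands, key=lambda r: r["tips"].size)
    return best


def planted_split_age(phylo: Phylogeny, target_age: float = 100.0) -> float:
    """Age (Myr) of the clade split the deep-filtering scenario sorts on."""
    return float(_planted_split(phylo, target_age)["age"])


def _deep_niche(phylo: Phylogeny, cfg: ScenarioConfig,
                rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Niche for deep_filtering_late: +-delta on the two sides of the
    planted split, ~0 elsewhere; returns (niche, split age)."""
    rec = _planted_split(phylo, cfg.split_age_target)
    z = np.zeros(phylo.n_tips)
    sides = rec["child_tip_sets"]
    half = cfg.shift_delta
    z[np.concatenate(sides[: len(sides) // 2 or 1])] = half
    z[np.concatenate(sides[len(sides) // 2 or 1:])] = -half
    z[~np.isin(np.arange(phylo.n_tips), rec["tips"])] = 0.0
    z = z + 0.05 * rng.standard_normal(phylo.n_tips)
    return z, float(rec["age"])


# ----------------------------------------------------------------- assembly
def _gradient_positions(cfg: ScenarioConfig, rng: np.random.Generator
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Latent gradient position per plot and stage labels."""
    gs, stages = [], []
    n_stages = len(cfg.plots_per_stage)
    max_count = max(cfg.plots_per_stage)
    for s, n_plots in enumerate(cfg.plots_per_stage, start=1):
        span = 1.0
        if cfg.stage_window_scale_by_count:
            span = n_plots / max_count
        base = np.linspace(-span, span, n_plots)
        jitter = rng.uniform(-0.5, 0.5, n_plots) * (2 * span / max(n_plots, 2))
        gs.append(np.clip(base + jitter, -1.2, 1.2))
        stages.extend([str(s)] * n_plots)
    return np.concatenate(gs), np.asarray(stages)


def _sample_occupancy(
    weights: np.ndarray, richness: int, rng: np.random.Generator
) -> np.ndarray:
    """Weighted sampling of species without replacement."""
    w = np.clip(weights, 1e-12, None)
    p = w / w.sum()
    richness = min(richness, p.size)
    return rng.choice(p.size, size=richness, replace=False, p=p)


def _sample_repulsive(
    weights: np.ndarray, richness: int, D: np.ndarray, d_min: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Weighted sampling rejecting candidates closer than ``d_min`` (Myr) to
    any already-selected species; relaxes the rule if the pool runs dry."""
    order = _sample_occupancy(weights, weights.size, rng)  # weighted order
    chosen: list[int] = []
    skipped: list[int] = []
    for cand in order:
        if len(chosen) >= richness:
            break
        if chosen and D[cand, chosen].min() < d_min:
            skipped.append(cand)
            continue
        chosen.append(int(cand))
    for cand in skipped:  # relax when repulsion exhausts the pool
        if len(chosen) >= richness:
            break
        chosen.append(int(cand))
    return np.asarray(chosen, dtype=np.intp)


def assemble_communities(
    cfg: ScenarioConfig,
    pool: Phylogeny,
    niche: np.ndarray,
    seed: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, dict]:
    """Build (community counts, environment, stage map, manifest).

    Plots sit on a one-dimensional latent environmental gradient; occupancy
    follows the scenario (lottery, Gaussian niche kernel, repulsion, or a
    stage-dependent mix); abundances are lognormal with a stage-dependent
    evenness parameter; observed environmental variables are noisy
    transforms of the latent factors, and x/y coordinates are independent
    of the gradient unless ``spatial_autocorr`` is set.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_pool = pool.n_tips
    # community pool: the species that can occur in the plots
    comm_idx = np.sort(rng.choice(n_pool, size=cfg.n_community, replace=False))
    z = np.asarray(niche, dtype=float)[comm_idx]
    D_comm = pool.cophenetic()[np.ix_(comm_idx, comm_idx)]

    g, stages = _gradient_positions(cfg, rng)
    n_plots = g.size
    plot_ids = [f"P{i + 1:02d}" for i in range(n_plots)]
    stage_per_plot = stages
    n_stages = len(cfg.plots_per_stage)

    counts = np.zeros((n_plots, cfg.n_community), dtype=np.int64)
    w2 = 2.0 * cfg.niche_breadth**2
    for k in range(n_plots):
        s = int(stage_per_plot[k]) - 1
        richness = int(np.clip(rng.poisson(cfg.richness_mean), 5, cfg.n_community))
        kernel = np.exp(-((z - g[k]) ** 2) / w2)
        scen = cfg.scenario
        late = s >= n_stages - 2
        if scen == "neutral" or (scen == "deep_filtering_late" and not late):
            sel = _sample_occupancy(np.ones(cfg.n_community), richness, rng)
        elif scen in ("filtering_conserved", "deep_filtering_late"):
            sel = _sample_occupancy(kernel, richness, rng)
        elif scen == "overdispersion":
            sel = _sample_repulsive(kernel, richness, D_comm,
                                    cfg.repulsion_distance, rng)
        elif scen == "dominance_shift":
            # constant composition: one shared species set for every plot
            if k == 0:
                shared = _sample_occupancy(
                    np.ones(cfg.n_community), int(cfg.richness_mean), rng
                )
            sel = shared  # noqa: F821  (set on the first plot)
        else:  # pragma: no cover
            raise AssertionError(scen)
        sigma = cfg.lognormal_sigma_by_stage[s]
        ab = np.exp(sigma * rng.standard_normal(sel.size))
        n_ind = cfg.individuals_by_stage[s]
        counts[k, sel] = rng.multinomial(n_ind, ab / ab.sum())
        if scen == "dominance_shift":
            # constant composition means every shared species is recorded
            # in every plot; keep rare species at one individual
            counts[k, sel] = np.maximum(counts[k, sel], 1)
        if counts[k].sum() == 0:  # pragma: no cover - N >= 1 prevents this
            counts[k, rng.choice(sel)] = 1

    if cfg.pad_to_target and cfg.scenario != "dominance_shift":
        # every community-pool species is recorded somewhere (the community
        # table is, by construction, the set of occurring species)
        absent = np.flatnonzero(counts.sum(axis=0) == 0)
        for i in absent:
            counts[rng.integers(n_plots), i] += 1

    present = counts.sum(axis=0) > 0
    species = [pool.taxa[i] for i in comm_idx[present]]
    community = pd.DataFrame(counts[:, present], index=plot_ids, columns=species)

    env = _make_env(cfg, g, plot_ids, rng)
    stage_map = pd.Series(
        pd.Categorical(stage_per_plot,
                       categories=[str(i + 1) for i in range(n_stages)],
                       ordered=True),
        index=plot_ids, name="stage",
    )
    manifest = {
        "scenario": cfg.scenario,
        "n_pool": n_pool,
        "n_community_target": cfg.n_community,
        "n_community_present": int(present.sum()),
        "plots_per_stage": list(cfg.plots_per_stage),
        "gradient": g.tolist(),
    }
    return community, env, stage_map, manifest


def _make_env(cfg: ScenarioConfig, g: np.ndarray, plot_ids: list[str],
              rng: np.random.Generator) -> pd.DataFrame:
    n_plots = g.size
    n_vars = min(cfg.n_env_vars, len(ENV_VAR_NAMES))
    q = max(1, cfg.latent_factors)
    factors = np.empty((n_plots, q))
    factors[:, 0] = g
    if q > 1:
        factors[:, 1:] = rng.standard_normal((n_plots, q - 1))
    # unit-magnitude loadings with random sign: every observed descriptor
    # tracks the latent factors about as strongly as real topographic/soil
    # variables track a dominant moisture-light axis
    loadings = rng.choice([-1.0, 1.0], size=(q, n_vars))
    raw = factors @ loadings + cfg.env_noise_sd * rng.standard_normal((n_plots, n_vars))
    env = {}
    for j, name in enumerate(ENV_VAR_NAMES[:n_vars]):
        col = raw[:, j]
        if name in ("northness", "eastness"):
            env[name] = np.tanh(col)          # signed, in (-1, 1)
        else:
            env[name] = np.exp(0.5 * col + 1.0)  # strictly positive
    x = rng.uniform(0.0, 1000.0, n_plots)
    y = rng.uniform(0.0, 1000.0, n_plots)
    if cfg.spatial_autocorr:
        x = 500.0 * (g + 1.2) + rng.normal(0.0, 30.0, n_plots)
    env["x"], env["y"] = x, y
    return pd.DataFrame(env, index=plot_ids)


# ------------------------------------------------------------------ top level
def generate_bundle(
    cfg: ScenarioConfig,
    pool: Phylogeny | None = None,
    niche: np.ndarray | None = None,
    with_traits: bool = True,
) -> AnalysisBundle:
    """One synthetic dataset as an aligned :class:`AnalysisBundle`.

    ``pool`` / ``niche`` may be passed in to reuse an existing phylogeny
    across many simulated community datasets (the randomization tests are
    conditional on the tree).  The generation manifest is attached as
    ``bundle.manifest``.
    """
    ss = np.random.SeedSequence(cfg.seed)
    s_tree, s_niche, s_comm, s_trait = ss.spawn(4)
    manifest: dict = {"seed": cfg.seed}
    if pool is None:
        pool = simulate_tree(
            cfg.pool_size, cfg.birth, cfg.death, cfg.root_age,
            seed=int(s_tree.generate_state(1)[0] % 2**31),
        )
    if niche is None:
        rng_n = np.random.default_rng(s_niche)
        if cfg.scenario == "deep_filtering_late" or cfg.niche_model == "two_clade_shift":
            niche, split_age = _deep_niche(pool, cfg, rng_n)
            manifest["planted_split_age"] = split_age
        else:
            raw = evolve_trait(pool, "BM", rng=rng_n)
            niche = (raw - raw.mean()) / raw.std()
    community, env, stage_map, m2 = assemble_communities(
        cfg, pool, niche, seed=np.random.default_rng(s_comm)
    )
    manifest.update(m2)
    traits = None
    if with_traits:
        rng_t = np.random.default_rng(s_trait)
        cols = {
            name: evolve_trait(pool, "BM", sigma=1.0, rng=rng_t)
            for name in TRAIT_NAMES
        }
        traits = pd.DataFrame(cols, index=list(pool.taxa)).loc[
            list(community.columns)
        ]
    bundle = align_and_prune(pool, community, stage_map, env=env, traits=traits)
    bundle.manifest = manifest  # type: ignore[attr-defined]
    return bundle


def make_fixture(
    scenario: str, seed: int, outdir: str | Path, **overrides
) -> Path:
    """Write a complete on-disk bundle (Newick + 4 TSVs + manifest JSON).

    Deterministic given the seed: the same call produces byte-identical
    files.
    """
    cfg = ScenarioConfig(scenario=scenario, seed=seed, **overrides)
    bundle = generate_bundle(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "pool.nwk").write_text(bundle.pool.write_newick())
    bundle.community.to_csv(outdir / "community.tsv", sep="\t", index_label="plot")
    bundle.stages.to_frame().to_csv(outdir / "stages.tsv", sep="\t", index_label="plot")
    bundle.env.to_csv(outdir / "env.tsv", sep="\t", index_label="plot")
    if bundle.traits is not None:
        bundle.traits.to_csv(outdir / "traits.tsv", sep="\t", index_label="species")
    manifest = dict(bundle.manifest)  # type: ignore[attr-defined]
    manifest["config"] = dataclasses.asdict(cfg)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
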