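"""Synthetic paired-site successional datasets with known ground truth.

The generator emulates the statistical structure of a paired grassland-forest
land-abandonment survey so every downstream stage can be exercised and its
parameter recovery tested without any sequencing data:

* ``n_pairs`` site pairs, each one grassland sample (managed, recently
  abandoned or late-successional, assigned round-robin) plus one adjacent
  forest sample.
* Stage-dependent covariates (pH, C:N, SOC, LDMC, ...) follow configurable
  response shapes — flat, linear, unimodal or a step at a threshold stage —
  on top of Gaussian site noise.  Defaults place a threshold pH drop and
  C:N/SOC rises at the forest stage, the emblematic abiotic shifts of
  afforestation.
* Taxa belong to two guilds.  Generalists draw gene repertoires from a
  shared core pool per nutrient cycle (high repertoire overlap, smaller
  repertoires) and have high pH optima; specialists split into guilds with
  quasi-disjoint private gene blocks (disjointness parameter, 0 = share the
  core like generalists, 1 = fully private) and low pH optima.
* Community composition is Gaussian environmental filtering on pH only
  (width ``niche_width``) times a fixed lognormal taxon effect times a
  per-sample lognormal jitter; read counts are multinomial draws at a
  negative-binomial depth.
* Gene tables are the trait-matrix product of the OTU counts, optionally
  Poisson-resampled — a statistical stand-in for annotated shotgun output.
* SIR rates couple each substrate to the Shannon diversity of the C-cycling
  genes of its substrate class with slope ``sir_coupling_beta``.

All randomness flows through one seeded generator, so a config plus seed
reproduces a dataset byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .tables_io import (
    GRASSLAND_STAGES,
    SIR_SUBSTRATES,
    STAGES,
    FeatureTable,
    SampleFrame,
    TraitMatrix,
)

#: substrate assayed -> substrate class of the C-cycling genes degrading it
SUBSTRATE_CLASS_OF = {
    "glucose": "oligosaccharides",
    "glycine": "amino_acids",
    "oxalic_acid": "carboxylic_acids",
    "yeast": "mixed",
    "lignin": "lignin",
    "chitin": "chitin",
}

_COVARIATES = ("pH", "CN_ratio", "SOC", "total_N", "LDMC_cwm", "MAT", "MAP")

_SHAPE_PROFILE = {
    "flat": np.array([0.0, 0.0, 0.0, 0.0]),
    "linear": np.array([0.0, 1 / 3, 2 / 3, 1.0]),
    "unimodal": np.array([0.0, 1.0, 1.0, 0.0]),
}


@dataclass
class SimulationConfig:
    """Study conditions of one simulated gradient.

    Defaults are desk-scale: 20 pairs, 200 taxa, sequencing depth one tenth
    of a typical 16S survey, and effect sizes chosen so the programmed
    contrasts are detectable at 40 pairs.
    """

    n_pairs: int = 20
    taxa_pool: int = 200
    gene_families: dict = field(
        default_factory=lambda: {"C": 90, "N": 48, "P": 48})
    n_specialist_guilds: int = 6
    generalist_fraction: float = 0.6
    specialist_gene_disjointness: float = 0.8
    specialist_genome_scale: float = 1.2
    genome_size_lognormal: tuple = (0.0, 0.15)   # repertoire-size multiplier
    copy_number_lambda: float = 0.5              # extra copies ~ Poisson

    response_shape: dict = field(default_factory=lambda: {
        "pH": "threshold", "CN_ratio": "threshold", "SOC": "threshold",
        "total_N": "flat", "LDMC_cwm": "linear", "MAT": "flat", "MAP": "flat",
    })
    threshold_stage: str = "forest"
    effect_sizes: dict = field(default_factory=lambda: {
        "pH": -1.7, "CN_ratio": 8.0, "SOC": 3.0, "total_N": 0.0,
        "LDMC_cwm": 0.08, "MAT": 0.0, "MAP": 0.0,
    })
    covariate_base: dict = field(default_factory=lambda: {
        "pH": 6.2, "CN_ratio": 12.0, "SOC": 3.0, "total_N": 0.25,
        "LDMC_cwm": 0.22, "MAT": 6.0, "MAP": 650.0,
    })
    covariate_noise_sd: dict = field(default_factory=lambda: {
        "pH": 0.3, "CN_ratio": 1.5, "SOC": 0.6, "total_N": 0.05,
        "LDMC_cwm": 0.02, "MAT": 1.0, "MAP": 80.0,
    })

    niche_width: float = 0.7
    niche_truncation: float = 1.8  # niche limit in units of width: fitness
                                   # is zero beyond this many widths from
                                   # the optimum (inf disables)
    generalist_pH_optimum: float = 6.4
    specialist_pH_optimum: float = 4.3
    optimum_sd: float = 0.2
    taxon_effect_sigma: float = 0.8       # generalists: even communities
    specialist_effect_sigma: float = 1.4  # specialists: dominance-prone
    core_coverage: float = 0.8            # fraction of the core pool a
                                          # typical repertoire spans
    sample_jitter_sigma: float = 0.7
    guild_jitter_sigma: float = 1.0   # per-sample dominance swings of whole
                                      # specialist guilds (microhabitat)

    depth_model: tuple = (4000, 10.0)            # (mean reads, NB dispersion)
    metagenome_noise: float = 1.0                # 0 -> exact linear product

    sir_coupling_beta: float = 1.0
    sir_basal: tuple = (1.0, 0.2)
    sir_alpha: float = 1.0
    sir_noise_sd: float = 0.1

    pair_distance_range: tuple = (0.1, 6.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        for name, val in (
            ("generalist_fraction", self.generalist_fraction),
            ("specialist_gene_disjointness", self.specialist_gene_disjointness),
        ):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for cov, shape in self.response_shape.items():
            if shape not in ("flat", "linear", "unimodal", "threshold"):
                raise ValueError(f"unknown response shape {shape!r} for {cov}")
        if self.threshold_stage not in STAGES:
            raise ValueError(f"unknown threshold stage {self.threshold_stage!r}")
        if self.niche_width <= 0 and not np.isinf(self.niche_width):
            raise ValueError("niche_width must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for key in ("genome_size_lognormal", "depth_model", "sir_basal",
                    "pair_distance_range"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg


@dataclass
class SimulatedDataset:
    sf: SampleFrame
    otu: FeatureTable
    genes: FeatureTable
    traits: TraitMatrix
    taxa_params: pd.DataFrame
    sir: pd.DataFrame
    truth: dict


def _stage_profile(cfg: SimulationConfig, shape: str) -> np.ndarray:
    if shape == "threshold":
        cut = STAGES.index(cfg.threshold_stage)
        return (np.arange(4) >= cut).astype(float)
    return _SHAPE_PROFILE[shape]


def stage_means(cfg: SimulationConfig) -> pd.DataFrame:
    """True covariate mean per stage implied by shapes and effect sizes."""
    rows = {}
    for cov in _COVARIATES:
        base = cfg.covariate_base[cov]
        eff = cfg.effect_sizes.get(cov, 0.0)
        prof = _stage_profile(cfg, cfg.response_shape.get(cov, "flat"))
        rows[cov] = base + eff * prof
    return pd.DataFrame(rows, index=list(STAGES))


def simulate_environment(cfg: SimulationConfig,
                         rng: np.random.Generator | None = None) -> SampleFrame:
    """Draw the paired design and per-sample covariates."""
    rng = rng or np.random.default_rng(cfg.seed)
    means = stage_means(cfg)
    rows = []
    parent_materials = np.array(["till", "glaciofluvial", "clay", "peat"])
    for i in range(cfg.n_pairs):
        g_stage = GRASSLAND_STAGES[i % len(GRASSLAND_STAGES)]
        pid = f"P{i:03d}"
        dist = rng.uniform(*cfg.pair_distance_range)
        pm = rng.choice(parent_materials)
        for stage, suffix in ((g_stage, "G"), ("forest", "F")):
            row = {"sample_id": f"{pid}{suffix}", "site_id": f"{pid}{suffix}",
                   "pair_id": pid, "stage": stage, "pair_distance_km": dist,
                   "parent_material": pm}
            for cov in _COVARIATES:
                row[cov] = means.loc[stage, cov] + rng.normal(
                    0.0, cfg.covariate_noise_sd[cov])
            if stage == "forest":
                row["stand_age"] = float(rng.integers(30, 120))
                row["stand_evenness"] = float(rng.uniform(0.3, 1.0))
            row["AGS"] = float(np.exp(rng.normal(np.log(4.5), 0.15)))
            rows.append(row)
    data = pd.DataFrame(rows).set_index("sample_id")
    return SampleFrame(data)


def _family_pools(cfg: SimulationConfig) -> dict:
    """Partition each cycle's families into a shared core + guild blocks."""
    pools = {}
    for cls, total in cfg.gene_families.items():
        names = [f"{cls}_{i:03d}" for i in range(total)]
        n_core = total // 3
        block = (total - n_core) // cfg.n_specialist_guilds
        if block < 1:
            raise ValueError(
                f"class {cls}: {total} families cannot host "
                f"{cfg.n_specialist_guilds} guild blocks beyond a core of {n_core}")
        core = names[:n_core]
        blocks = [names[n_core + g * block: n_core + (g + 1) * block]
                  for g in range(cfg.n_specialist_guilds)]
        pools[cls] = {"core": core, "blocks": blocks, "all": names}
    return pools


def simulate_taxa(cfg: SimulationConfig,
                  rng: np.random.Generator | None = None
                  ) -> tuple[TraitMatrix, pd.DataFrame]:
    """Draw gene repertoires and niche parameters for the taxa pool.

    Returns the taxa-by-family copy matrix plus a per-taxon parameter frame
    (guild, specialist guild index, pH optimum, lognormal abundance effect,
    repertoire size).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    pools = _family_pools(cfg)
    n_gen = round(cfg.generalist_fraction * cfg.taxa_pool)
    n_spec = cfg.taxa_pool - n_gen
    mu, sigma = cfg.genome_size_lognormal
    taxa, params = [], []
    all_families = [f for cls in sorted(pools) for f in pools[cls]["all"]]
    copies = np.zeros((cfg.taxa_pool, len(all_families)))
    col = {f: j for j, f in enumerate(all_families)}
    delta = cfg.specialist_gene_disjointness

    for t in range(cfg.taxa_pool):
        is_gen = t < n_gen
        guild = -1 if is_gen else (t - n_gen) % cfg.n_specialist_guilds
        size_mult = float(np.exp(rng.normal(mu, sigma)))
        opt = rng.normal(
            cfg.generalist_pH_optimum if is_gen else cfg.specialist_pH_optimum,
            cfg.optimum_sd)
        effect_sigma = (cfg.taxon_effect_sigma if is_gen
                        else cfg.specialist_effect_sigma)
        effect = float(np.exp(rng.normal(0.0, effect_sigma)))
        rep_total = 0
        for cls in sorted(pools):
            core = pools[cls]["core"]
            base = max(1, round(cfg.core_coverage * len(core)))
            if is_gen:
                r = max(1, round(base * size_mult))
                chosen = list(rng.choice(core, size=min(r, len(core)),
                                         replace=False))
            else:
                block = pools[cls]["blocks"][guild]
                r = max(1, round(base * cfg.specialist_genome_scale * size_mult))
                n_block = min(round(delta * r), len(block))
                n_core = min(round((1.0 - delta) * r), len(core))
                chosen = []
                if n_block:
                    chosen += list(rng.choice(block, size=n_block, replace=False))
                if n_core:
                    chosen += list(rng.choice(core, size=n_core, replace=False))
                if not chosen:  # delta rounding left an empty repertoire
                    chosen = [block[0]]
            for f in chosen:
                copies[t, col[f]] = 1.0 + rng.poisson(cfg.copy_number_lambda)
            rep_total += len(chosen)
        tid = f"T{t:04d}"
        taxa.append(tid)
        params.append({"taxon_id": tid,
                       "guild": "generalist" if is_gen else "specialist",
                       "specialist_guild": guild, "pH_optimum": float(opt),
                       "taxon_effect": effect, "repertoire_size": rep_total})
    family_class = {f: f.split("_")[0] for f in all_families}
    c_families = [f for f in all_families if family_class[f] == "C"]
    sub_classes = list(SUBSTRATE_CLASS_OF.values())
    substrate_class = {f: sub_classes[i % len(sub_classes)]
                       for i, f in enumerate(c_families)}
    tm = TraitMatrix(
        values=pd.DataFrame(copies, index=taxa, columns=all_families),
        family_class=family_class, substrate_class=substrate_class)
    return tm, pd.DataFrame(params).set_index("taxon_id")


def simulate_counts(cfg: SimulationConfig, env: SampleFrame,
                    taxa_params: pd.DataFrame,
                    rng: np.random.Generator | None = None) -> FeatureTable:
    """Multinomial read counts under Gaussian pH filtering.

    Expected relative abundance of taxon t in sample s is
    exp(-(pH_s - opt_t)^2 / 2w^2) * effect_t * jitter_ts; the per-sample
    depth is negative-binomial.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    opt = taxa_params["pH_optimum"].to_numpy(float)
    eff = taxa_params["taxon_effect"].to_numpy(float)
    w = cfg.niche_width
    mean_depth, disp = cfg.depth_model
    counts = np.zeros((len(taxa_params), len(env.sample_ids)), dtype=np.int64)
    for j, s in enumerate(env.sample_ids):
        ph = float(env.data.loc[s, "pH"])
        if np.isinf(w):
            fit = np.ones_like(opt)
        else:
            dev = np.abs(ph - opt)
            fit = np.exp(-(dev**2) / (2.0 * w * w))
            fit[dev > cfg.niche_truncation * w] = 0.0
        if fit.sum() == 0:  # pathological pH far outside every niche
            fit = np.ones_like(opt)
        jitter = np.exp(rng.normal(0.0, cfg.sample_jitter_sigma, size=opt.size))
        guild_factor = np.exp(rng.normal(0.0, cfg.guild_jitter_sigma,
                                         size=cfg.n_specialist_guilds))
        guild_idx = taxa_params["specialist_guild"].to_numpy(int)
        guild_mult = np.where(guild_idx >= 0,
                              guild_factor[np.clip(guild_idx, 0, None)], 1.0)
        weight = fit * eff * jitter * guild_mult
        rel = weight / weight.sum()
        depth = rng.negative_binomial(disp, disp / (disp + mean_depth))
        depth = max(int(depth), 100)
        counts[:, j] = rng.multinomial(depth, rel)
    values = pd.DataFrame(counts, index=list(taxa_params.index),
                          columns=env.sample_ids)
    return FeatureTable(values=values, kind="otu", marker="16S")


def simulate_metagenome(otu: FeatureTable, traits: TraitMatrix,
                        noise: float = 1.0,
                        rng: np.random.Generator | None = None) -> FeatureTable:
    """Gene-family table as the copy-weighted sum of taxon counts.

    gene g in sample s = sum_t count_ts * copies_tg; with ``noise`` > 0 the
    expectation is Poisson-resampled (annotation/mapping noise stand-in).
    """
    rng = rng or np.random.default_rng(0)
    if list(otu.feature_ids) != list(traits.taxa):
        raise ValueError("OTU table and trait matrix taxa are misaligned")
    expected = traits.values.to_numpy(float).T @ otu.values.to_numpy(float)
    out = rng.poisson(expected).astype(float) if noise > 0 else expected
    values = pd.DataFrame(out, index=traits.families, columns=otu.sample_ids)
    return FeatureTable(values=values, kind="gene", marker="metagenome")


def substrate_class_shannon(genes: FeatureTable, substrate_class: dict
                            ) -> pd.DataFrame:
    """Per-sample Shannon H' of the C genes of each substrate class.

    Columns are the substrate classes plus 'catabolic_sum', the sum over
    classes — the genetic aggregate mirroring how MSIR sums the substrate
    panel.
    """
    classes = sorted(set(substrate_class.values()))
    vals = genes.values
    out = {}
    for cls in classes:
        fams = [f for f in genes.feature_ids if substrate_class.get(f) == cls]
        sub = vals.loc[fams].to_numpy(float)
        tot = sub.sum(axis=0)
        h = np.zeros(sub.shape[1])
        for j in range(sub.shape[1]):
            if tot[j] > 0:
                p = sub[:, j] / tot[j]
                nz = p[p > 0]
                h[j] = float(-(nz * np.log(nz)).sum())
        out[cls] = h
    df = pd.DataFrame(out, index=genes.sample_ids)
    df["catabolic_sum"] = df[classes].sum(axis=1)
    return df


def simulate_sir(genes: FeatureTable, cfg: SimulationConfig,
                 substrate_class: dict,
                 rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Respiration rates coupled to substrate-class gene diversity.

    rate(substrate) = basal + alpha + beta * H'(C genes of that substrate's
    class) + Gaussian noise; basal is drawn per sample.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    h = substrate_class_shannon(genes, substrate_class)
    basal_mean, basal_sd = cfg.sir_basal
    rows = {}
    for s in genes.sample_ids:
        basal = rng.normal(basal_mean, basal_sd)
        row = {"basal": basal}
        for substrate in SIR_SUBSTRATES:
            cls = SUBSTRATE_CLASS_OF[substrate]
            row[substrate] = (basal + cfg.sir_alpha
                              + cfg.sir_coupling_beta * h.loc[s, cls]
                              + rng.normal(0.0, cfg.sir_noise_sd))
        rows[s] = row
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample_id")


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Run the full generator off one seeded stream and bundle ground truth."""
    rng = np.random.default_rng(cfg.seed)
    env = simulate_environment(cfg, rng)
    traits, taxa_params = simulate_taxa(cfg, rng)
    otu = simulate_counts(cfg, env, taxa_params, rng)
    genes = simulate_metagenome(otu, traits, cfg.metagenome_noise, rng)
    sir = simulate_sir(genes, cfg, traits.substrate_class, rng)
    truth = {
        "config": _jsonable(cfg.to_dict()),
        "stage_covariate_means": stage_means(cfg).to_dict(),
        "n_generalists": int((taxa_params["guild"] == "generalist").sum()),
        "n_specialists": int((taxa_params["guild"] == "specialist").sum()),
        "expected_orderings": {
            "shannon_grassland_gt_forest": cfg.generalist_fraction > 0.5,
            "rao_Q_forest_gt_grassland": cfg.specialist_gene_disjointness > 0.5,
            "redundancy_R_grassland_gt_forest":
                cfg.specialist_gene_disjointness > 0.5,
        },
        "sir_coupling_beta": cfg.sir_coupling_beta,
    }
    return SimulatedDataset(sf=env, otu=otu, genes=genes, traits=traits,
                            taxa_params=taxa_params, sir=sir, truth=truth)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_dataset(ds: SimulatedDataset, outdir) -> None:
    """Write otu/genes/traits/samples/sir TSVs plus truth.json."""
    from pathlib import Path

    from .tables_io import (write_feature_table, write_sample_frame,
                            write_trait_matrix)

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_feature_table(ds.otu, out / "otu.tsv")
    write_feature_table(ds.genes, out / "genes.tsv")
    write_trait_matrix(ds.traits, out / "traits.tsv",
                       class_path=out / "gene_classes.tsv")
    write_sample_frame(ds.sf, out / "samples.tsv")
    ds.sir.to_csv(out / "sir.tsv", sep="\t")
    ds.taxa_params.to_csv(out / "taxa_params.tsv", sep="\t")
    with open(out / "truth.json", "w") as fh:
        json.dump(_jsonable(ds.truth), fh, indent=2, sort_keys=True)


def null_config(seed: int = 0, n_pairs: int = 20, **overrides
                ) -> SimulationConfig:
    """A no-effect configuration: flat covariates, shared gene pools, no
    SIR-diversity coupling, guild-free niche optima."""
    cfg = SimulationConfig(
        n_pairs=n_pairs, seed=seed,
        response_shape={c: "flat" for c in _COVARIATES},
        effect_sizes={c: 0.0 for c in _COVARIATES},
        specialist_gene_disjointness=0.0,
        sir_coupling_beta=0.0,
        specialist_pH_optimum=6.4,  # same as generalists: no pH guild link
        **overrides,
    )
    return cfg


def effect_config(seed: int = 0, n_pairs: int = 40, **overrides
                  ) -> SimulationConfig:
    """The programmed-effect configuration used for recovery checks."""
    return SimulationConfig(n_pairs=n_pairs, seed=seed, **overrides)
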