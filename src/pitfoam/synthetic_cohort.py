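"""Synthetic deep-pit manure cohort generator with known ground truth.

Emulates the processed data of a longitudinal swine-farm survey: monthly
manure samples from many farms, each characterized by a surface texture
(no-foam / crust / foam), a bacterial 16S OTU table, a methanogen *mcrA*
OTU table, and per-sample diet and manure-chemistry covariates.

The generative model, chosen to reproduce the statistical structure the
downstream analyses assume:

* **Texture** per farm follows a first-order Markov chain over
  {no-foam, crust, foam}; textures are persistent (large self-transition
  probabilities) so pits tend to stay foaming once foaming.
* **Community composition** is logistic-normal: per-sample latent relative
  abundances are the softmax of ``base + farm effect + texture effect +
  accumulated drift`` on the log scale. Farm effects dominate texture
  effects, reproducing the farm-blocked variance hierarchy of real pits.
* **Temporal drift** is a Gaussian random walk on log abundances whose
  per-month step size depends on the current texture, so community
  dissimilarity grows with time lag at a texture-specific rate (non-foaming
  communities drift fastest by default — they are the least stable).
* **Counts** are multinomial draws at a negative-binomial sequencing depth,
  so some samples fall below QC thresholds. A large tail of very rare OTUs
  produces per-sample singletons (Good's coverage nontrivially < 1), and a
  set of ultra-rare "spurious" OTUs lands below the rare-OTU filter.
* **Diet / chemistry covariates** are Gaussian per texture with planted
  ordered group means (e.g. DDGS highest under foam, SBM highest under
  no-foam, methane production rate foam > crust > no-foam) and planted
  per-texture correlations (by default LCFA–SCFA coupling in foam only).

Every planted feature is recorded in :class:`GroundTruth` so recovery can
be checked end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .amplicon_qc import OtuTable

__all__ = [
    "TEXTURES",
    "CohortConfig",
    "GroundTruth",
    "generate_cohort",
    "write_cohort",
    "default_diet_means",
    "default_texture_transition",
]

TEXTURES = ("no-foam", "crust", "foam")

#: diet and manure variables carried in sample metadata
DIET_VARIABLES = ("SBM", "DDGS", "crude_protein", "NDF", "ADF", "crude_fiber")
MANURE_VARIABLES = (
    "MPR",
    "SCFA",
    "acetic_acid",
    "LCFA",
    "organic_N",
    "pH",
    "temperature",
    "depth",
)


def default_diet_means() -> dict[tuple[str, str], float]:
    """Per-(variable, texture) means with the orderings seen in field pits.

    Units: diet ingredients and fiber fractions in % of ration, fatty acids
    in mg/g manure, MPR in L CH4 / L manure / day, temperature in deg C,
    depth in m.
    """
    by_var = {
        # no-foam, crust, foam
        "SBM": (26.0, 21.0, 17.0),
        "DDGS": (18.0, 25.0, 30.0),
        "crude_protein": (14.5, 16.5, 15.5),
        "NDF": (9.5, 11.5, 13.0),
        "ADF": (3.8, 5.5, 4.7),
        "crude_fiber": (3.4, 4.6, 4.0),
        "MPR": (0.04, 0.08, 0.15),
        "SCFA": (12.4, 10.0, 7.3),
        "acetic_acid": (7.5, 5.8, 4.0),
        "LCFA": (2.0, 30.0, 1.4),
        "organic_N": (2.3, 2.0, 2.6),
        "pH": (8.2, 8.2, 8.2),
        "temperature": (15.0, 17.5, 16.5),
        "depth": (1.6, 2.2, 1.9),
    }
    return {
        (var, tex): mu for var, mus in by_var.items() for tex, mu in zip(TEXTURES, mus)
    }


#: coefficient of variation per variable (sd = cv * |texture mean|)
DEFAULT_DIET_CV = {"pH": 0.03, "MPR": 0.35, "LCFA": 0.40}
_FALLBACK_CV = 0.25


def default_texture_transition() -> np.ndarray:
    """Row-stochastic monthly transition matrix over (no-foam, crust, foam)."""
    return np.array(
        [
            [0.80, 0.10, 0.10],
            [0.08, 0.84, 0.08],
            [0.05, 0.05, 0.90],
        ]
    )


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort; defaults mirror the study design
    (46 farms sampled monthly for 13 months)."""

    n_farms: int = 46
    n_months: int = 13
    n_bacterial_otus: int = 600
    n_methanogen_otus: int = 120
    # rare tail: low-abundance OTUs supplying per-sample singletons
    n_tail_otus_16s: int = 1200
    n_tail_otus_mcra: int = 240
    # spurious OTUs: total count across the cohort typically < 5
    n_spurious_otus_16s: int = 400
    n_spurious_otus_mcra: int = 80
    tail_log_abundance: float = -4.0
    spurious_log_abundance: float = -8.5
    mean_depth_16s: int = 30_000
    mean_depth_mcra: int = 12_000
    depth_dispersion: float = 5.0  # negative-binomial shape
    base_log_sd: float = 1.5
    farm_effect_sd: float = 1.2
    texture_effect_sd: float = 0.35
    # idiosyncratic per-sample log-abundance noise (sampling/technical);
    # most within-farm variation comes from temporal drift instead
    sample_effect_sd: float = 0.50
    # methanogen communities are more strongly farm-blocked and more
    # texture-structured than bacterial ones; None = same as 16S
    farm_effect_sd_mcra: float | None = 2.4
    texture_effect_sd_mcra: float | None = 0.7
    sample_effect_sd_mcra: float | None = 0.3
    drift_rate: dict = field(
        default_factory=lambda: {"no-foam": 0.20, "crust": 0.10, "foam": 0.06}
    )
    texture_transition: np.ndarray = field(default_factory=default_texture_transition)
    initial_texture_probs: tuple = (0.55, 0.08, 0.37)
    diet_means: dict = field(default_factory=default_diet_means)
    diet_cv: dict = field(default_factory=lambda: dict(DEFAULT_DIET_CV))
    planted_correlations: list = field(
        default_factory=lambda: [("LCFA", "SCFA", "foam", 0.8, "monotonic")]
    )
    missingness_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_farms",
            "n_months",
            "n_bacterial_otus",
            "n_methanogen_otus",
            "mean_depth_16s",
            "mean_depth_mcra",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "farm_effect_sd",
            "texture_effect_sd",
            "sample_effect_sd",
            "base_log_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if set(self.drift_rate) != set(TEXTURES):
            raise ValueError("drift_rate must map every texture")
        if any(v < 0 for v in self.drift_rate.values()):
            raise ValueError("drift rates must be >= 0")
        T = np.asarray(self.texture_transition, dtype=float)
        if T.shape != (3, 3) or (T < 0).any():
            raise ValueError("texture_transition must be a non-negative 3x3 matrix")
        if not np.allclose(T.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("texture_transition rows must sum to 1")
        if not (0 <= self.missingness_rate < 1):
            raise ValueError("missingness_rate must be in [0, 1)")
        seen = set()
        for var_a, var_b, tex, rho, shape in self.planted_correlations:
            if tex not in TEXTURES:
                raise ValueError(f"unknown texture {tex!r}")
            if shape not in ("monotonic", "quadratic"):
                raise ValueError(f"unknown correlation shape {shape!r}")
            if not (-1 < rho < 1):
                raise ValueError("planted correlation must be in (-1, 1)")
            if (var_b, tex) in seen:
                raise ValueError(f"variable {var_b} targeted twice in {tex}")
            seen.add((var_b, tex))


@dataclass
class GroundTruth:
    """Everything planted by the generator, for downstream recovery checks."""

    latent_16s: pd.DataFrame  # OTUs x samples, columns sum to 1
    latent_mcra: pd.DataFrame
    texture_trajectories: pd.DataFrame  # farms x months
    planted_orderings: dict[str, tuple]  # variable -> textures sorted by mean, desc
    drift_rates: dict[str, float]
    planted_correlations: list


def _markov_textures(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    T = np.asarray(config.texture_transition, dtype=float)
    states = np.empty((config.n_farms, config.n_months), dtype=np.int64)
    init = np.asarray(config.initial_texture_probs, dtype=float)
    init = init / init.sum()
    for f in range(config.n_farms):
        states[f, 0] = rng.choice(3, p=init)
        for m in range(1, config.n_months):
            states[f, m] = rng.choice(3, p=T[states[f, m - 1]])
    return states


def _community_counts(
    config: CohortConfig,
    textures: np.ndarray,
    marker: str,
    rng: np.random.Generator,
):
    """Latent compositions and multinomial counts for one marker gene."""
    if marker == "16s":
        n_main = config.n_bacterial_otus
        n_tail = config.n_tail_otus_16s
        n_spur = config.n_spurious_otus_16s
        mean_depth = config.mean_depth_16s
        prefix = "OTU16S"
        farm_sd = config.farm_effect_sd
        tex_sd = config.texture_effect_sd
        samp_sd = config.sample_effect_sd
    else:
        n_main = config.n_methanogen_otus
        n_tail = config.n_tail_otus_mcra
        n_spur = config.n_spurious_otus_mcra
        mean_depth = config.mean_depth_mcra
        prefix = "OTUmcrA"
        farm_sd = (
            config.farm_effect_sd
            if config.farm_effect_sd_mcra is None
            else config.farm_effect_sd_mcra
        )
        tex_sd = (
            config.texture_effect_sd
            if config.texture_effect_sd_mcra is None
            else config.texture_effect_sd_mcra
        )
        samp_sd = (
            config.sample_effect_sd
            if config.sample_effect_sd_mcra is None
            else config.sample_effect_sd_mcra
        )
    n_otus = n_main + n_tail + n_spur
    n_farms, n_months = textures.shape

    base = np.concatenate(
        [
            rng.normal(0.0, config.base_log_sd, n_main),
            rng.normal(config.tail_log_abundance, 0.5, n_tail),
            rng.normal(config.spurious_log_abundance, 0.5, n_spur),
        ]
    )
    farm_eff = rng.normal(0.0, farm_sd, (n_farms, n_otus))
    tex_eff = rng.normal(0.0, tex_sd, (3, n_otus))
    drift_sd = np.array([config.drift_rate[t] for t in TEXTURES])

    latent = np.empty((n_otus, n_farms * n_months))
    counts = np.zeros((n_otus, n_farms * n_months), dtype=np.int64)
    depths = np.empty(n_farms * n_months, dtype=np.int64)
    p_nb = config.depth_dispersion / (config.depth_dispersion + mean_depth)
    col = 0
    for f in range(n_farms):
        walk = np.zeros(n_otus)
        for m in range(n_months):
            tex = textures[f, m]
            if m > 0:
                walk = walk + rng.normal(0.0, drift_sd[tex], n_otus)
            noise = rng.normal(0.0, samp_sd, n_otus) if samp_sd > 0 else 0.0
            logits = base + farm_eff[f] + tex_eff[tex] + walk + noise
            logits = logits - logits.max()
            p = np.exp(logits)
            p /= p.sum()
            latent[:, col] = p
            depth = max(int(rng.negative_binomial(config.depth_dispersion, p_nb)), 1)
            depths[col] = depth
            counts[:, col] = rng.multinomial(depth, p)
            col += 1

    otu_ids = (
        [f"{prefix}_{i:05d}" for i in range(n_main)]
        + [f"{prefix}_T{i:05d}" for i in range(n_tail)]
        + [f"{prefix}_S{i:05d}" for i in range(n_spur)]
    )
    return otu_ids, latent, counts, depths


# minimal plausible taxonomies for labeling synthetic OTUs -------------------

_BACT_LINEAGES = [
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae", "Prevotella"),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Bacteroidaceae", "Bacteroides"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Clostridiaceae", "Clostridium"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", "Sporobacter"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "Sporobacterium"),
    ("Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae", "Lactobacillus"),
    ("Firmicutes", "Erysipelotrichia", "Erysipelotrichales", "Erysipelotrichaceae", "Turicibacter"),
    ("Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae", "Escherichia"),
    ("Proteobacteria", "Deltaproteobacteria", "Desulfovibrionales", "Desulfovibrionaceae", "Desulfovibrio"),
    ("Spirochaetes", "Spirochaetia", "Spirochaetales", "Spirochaetaceae", "Treponema"),
    ("Actinobacteria", "Actinomycetia", "Actinomycetales", "Actinomycetaceae", "Actinomyces"),
]

_MCRA_LINEAGES = [
    ("Euryarchaeota", "Methanobacteria", "Methanobacteriales", "Methanobacteriaceae", "Methanobrevibacter"),
    ("Euryarchaeota", "Methanobacteria", "Methanobacteriales", "Methanobacteriaceae", "Methanosphaera"),
    ("Euryarchaeota", "Methanomicrobia", "Methanomicrobiales", "Methanocorpusculaceae", "Methanocorpusculum"),
    ("Euryarchaeota", "Methanomicrobia", "Methanomicrobiales", "Methanospirillaceae", "Methanospirillum"),
]


def _assign_taxonomy(
    otu_ids: list[str], marker: str, rng: np.random.Generator
) -> dict[str, str]:
    pool = _BACT_LINEAGES if marker == "16s" else _MCRA_LINEAGES
    kingdom = "Bacteria" if marker == "16s" else "Archaea"
    taxonomy = {}
    for otu in otu_ids:
        spurious = "_S" in otu
        tail = "_T" in otu
        if spurious or (tail and rng.random() < 0.6):
            # unresolvable rare sequence: kingdom only
            taxonomy[otu] = f"k__{kingdom};p__;c__;o__;f__;g__;s__"
            continue
        phy, cls, order, fam, genus = pool[rng.integers(len(pool))]
        g = genus if rng.random() < 0.75 else ""
        species = ""
        if g == "Methanosphaera" and rng.random() < 0.5:
            species = "Methanosphaera stadtmanae"
        elif g and rng.random() < 0.15:
            species = f"{g} sp"
        taxonomy[otu] = (
            f"k__{kingdom};p__{phy};c__{cls};o__{order};f__{fam};g__{g};s__{species}"
        )
    return taxonomy


def _diet_variables(
    config: CohortConfig, metadata: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw covariates per texture with planted correlations via a Gaussian
    structural construction on standardized scores."""
    variables = sorted({var for var, _ in config.diet_means})
    z = pd.DataFrame(
        rng.standard_normal((len(metadata), len(variables))),
        columns=variables,
        index=metadata.index,
    )
    for var_a, var_b, tex, rho, shape in config.planted_correlations:
        mask = (metadata["texture"] == tex).to_numpy()
        za = z.loc[mask, var_a].to_numpy()
        eps = rng.standard_normal(mask.sum())
        if shape == "monotonic":
            zb = rho * za + np.sqrt(1 - rho**2) * eps
        else:  # quadratic: zero linear correlation, strong dependence
            c = abs(rho)
            zb = np.sign(rho) * np.sqrt(c) * (za**2 - 1) / np.sqrt(2.0)
            zb = zb + np.sqrt(1 - c) * eps
        z.loc[mask, var_b] = zb
    values = pd.DataFrame(index=metadata.index, columns=variables, dtype=float)
    for var in variables:
        cv = config.diet_cv.get(var, _FALLBACK_CV)
        for tex in TEXTURES:
            mask = metadata["texture"] == tex
            mu = config.diet_means[(var, tex)]
            values.loc[mask, var] = mu + cv * abs(mu) * z.loc[mask, var]
    return values


def generate_cohort(
    config: CohortConfig,
) -> tuple[OtuTable, OtuTable, pd.DataFrame, GroundTruth]:
    """Generate (16S table, mcrA table, sample metadata, ground truth).

    One sample per (farm, month) before missingness; identical config and
    seed give bit-identical output.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    streams = [np.random.default_rng(child) for child in ss.spawn(6)]
    rng_tex, rng_16s, rng_mcra, rng_tax, rng_diet, rng_miss = streams

    textures = _markov_textures(config, rng_tex)
    sample_ids = [
        f"F{f + 1:02d}M{m + 1:02d}"
        for f in range(config.n_farms)
        for m in range(config.n_months)
    ]
    farms = [f"F{f + 1:02d}" for f in range(config.n_farms) for _ in range(config.n_months)]
    months = [m + 1 for _ in range(config.n_farms) for m in range(config.n_months)]
    tex_labels = [
        TEXTURES[textures[f, m]]
        for f in range(config.n_farms)
        for m in range(config.n_months)
    ]

    ids_16s, latent_16s, counts_16s, _ = _community_counts(
        config, textures, "16s", rng_16s
    )
    ids_mcra, latent_mcra, counts_mcra, _ = _community_counts(
        config, textures, "mcra", rng_mcra
    )

    metadata = pd.DataFrame(
        {"sample_id": sample_ids, "farm": farms, "month": months, "texture": tex_labels}
    ).set_index("sample_id")
    covars = _diet_variables(config, metadata, rng_diet)
    metadata = pd.concat([metadata, covars], axis=1)

    if config.missingness_rate > 0:
        keep = rng_miss.random(len(sample_ids)) >= config.missingness_rate
    else:
        keep = np.ones(len(sample_ids), dtype=bool)
    kept_ids = [s for s, k in zip(sample_ids, keep) if k]

    table_16s = OtuTable(
        pd.DataFrame(counts_16s[:, keep], index=ids_16s, columns=kept_ids),
        _assign_taxonomy(ids_16s, "16s", rng_tax),
    )
    table_mcra = OtuTable(
        pd.DataFrame(counts_mcra[:, keep], index=ids_mcra, columns=kept_ids),
        _assign_taxonomy(ids_mcra, "mcra", rng_tax),
    )
    metadata = metadata.loc[kept_ids]

    orderings = {}
    for var in sorted({v for v, _ in config.diet_means}):
        means = {tex: config.diet_means[(var, tex)] for tex in TEXTURES}
        orderings[var] = tuple(sorted(TEXTURES, key=lambda t: -means[t]))
    truth = GroundTruth(
        latent_16s=pd.DataFrame(latent_16s[:, keep], index=ids_16s, columns=kept_ids),
        latent_mcra=pd.DataFrame(
            latent_mcra[:, keep], index=ids_mcra, columns=kept_ids
        ),
        texture_trajectories=pd.DataFrame(
            [[TEXTURES[t] for t in row] for row in textures],
            index=[f"F{f + 1:02d}" for f in range(config.n_farms)],
            columns=[m + 1 for m in range(config.n_months)],
        ),
        planted_orderings=orderings,
        drift_rates=dict(config.drift_rate),
        planted_correlations=list(config.planted_correlations),
    )
    return table_16s, table_mcra, metadata, truth


def write_cohort(
    outdir,
    table_16s: OtuTable,
    table_mcra: OtuTable,
    metadata: pd.DataFrame,
) -> dict[str, Path]:
    """Write the cohort in the canonical TSV dialects; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts_16s": outdir / "otu_16s.tsv",
        "taxonomy_16s": outdir / "taxonomy_16s.tsv",
        "counts_mcra": outdir / "otu_mcra.tsv",
        "taxonomy_mcra": outdir / "taxonomy_mcra.tsv",
        "metadata": outdir / "metadata.tsv",
    }
    table_16s.to_tsv(paths["counts_16s"], paths["taxonomy_16s"])
    table_mcra.to_tsv(paths["counts_mcra"], paths["taxonomy_mcra"])
    metadata.to_csv(paths["metadata"], sep="\t", float_format="%.10g")
    return paths
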