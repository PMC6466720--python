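"""Synthetic family-tank experiment generator.

Emulates the design used for isotope-based feed-efficiency phenotyping in
salmon parr: full-sib families reared two tanks per family (default 23
families x 2 tanks x 50 fish), genotyped at SNPs segregating in the
founders, fed a diet enriched in 15N and 13C for 12 days, with tanks
sampled over 5 days, tank feed intake recorded as g dry matter, and
per-tissue isotope atom% measured at the end.

The generative model is deliberately minimal:

* five latent additive traits per fish -- growth potential, tissue
  turnover rate for muscle/liver/adipose, and an intake-per-gain
  deviation -- with breeding values built from per-SNP effects so that
  the realized genomic variance matches the configured ``genetic_cov``
  exactly (GRM-based REML then estimates an unbiased target);
* linear weight gain over the experimental window (only the endpoint
  weights are analysed downstream);
* single-compartment isotope mixing: the fraction of tissue nutrients
  that are new at the end of the window is
  ``f = clamp((WG + turnover * FW) / FW, 0, 1 - eps)`` and the recorded
  atom% is ``IA + f * (diet - IA)`` plus truncated measurement noise, so
  simulated values stay strictly between baseline and the diet level
  (equilibrium is never reached, by construction and by validation);
* individual feed intake decomposed as gain cost + turnover cost +
  genetic intake deviation, observable only as its sum per tank.

Every fish's true breeding values, tank effects and intake are returned
in a :class:`TruthRecord` so parameter recovery can be asserted.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .grm import GenotypeMatrix
from .isotopes import atom_percent_to_delta, IsotopeStandards

__all__ = ["SimulationConfig", "TruthRecord", "simulate_genotypes", "simulate_phenotypes"]

LATENTS = ("growth", "turn_muscle", "turn_liver", "turn_adipose", "intake_dev")
TISSUE_OF_TRAIT = {
    "amc": "muscle", "amn": "muscle", "alc": "liver", "aln": "liver", "aac": "adipose",
}
ISOTOPE_OF_TRAIT = {
    "amc": "c13", "amn": "n15", "alc": "c13", "aln": "n15", "aac": "c13",
}
_EPS_F = 1e-6  # clamp keeping APE strictly below diet enrichment


def _default_genetic_cov() -> np.ndarray:
    # Latent order: growth (g), turnover per tissue (fraction), intake (g).
    # Turnover and intake-deviation variances are kept small so that tank
    # feed conversion varies mainly through growth (fast-growing tanks
    # dilute the size-proportional turnover cost over more gain), giving
    # the strongly favourable FCR-growth relationship the design shows.
    sd = np.sqrt([5.82, 1e-4, 1e-4, 1e-4, 0.005])
    corr = np.array(
        [
            [1.0, 0.2, 0.2, 0.2, 0.3],
            [0.2, 1.0, 0.5, 0.5, 0.0],
            [0.2, 0.5, 1.0, 0.5, 0.0],
            [0.2, 0.5, 0.5, 1.0, 0.0],
            [0.3, 0.0, 0.0, 0.0, 1.0],
        ]
    )
    return corr * np.outer(sd, sd)


def _default_env_cov() -> np.ndarray:
    return np.diag([6.44, 4e-4, 4e-4, 4e-4, 0.05])


@dataclasses.dataclass
class SimulationConfig:
    """Configuration of the simulated experiment.

    Defaults reproduce the scale of the reference design: 23 families,
    two 50-fish tanks each, a 12-day enriched-feed window, diet atom%
    2.7 (15N) / 2.0 (13C), baselines 0.370 / ~1.08, initial weight about
    21.8 g and mean gain about 10.8 g.  ``genetic_cov`` and ``env_cov``
    are 5x5 over the latent traits (growth, muscle/liver/adipose
    turnover, intake deviation); ``tank_var`` holds between-tank
    environmental variances on the same axes.
    """

    n_families: int = 23
    n_tanks_per_family: int = 2
    n_fish_per_tank: int = 50
    n_snps: int = 51543
    maf_range: tuple[float, float] = (0.05, 0.5)
    days: int = 12
    diet_atom_n15: float = 2.7
    diet_atom_c13: float = 2.0
    baseline_atom: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {
            "amc": 1.087, "amn": 0.370, "alc": 1.086, "aln": 0.370, "aac": 1.082,
        }
    )
    genetic_cov: np.ndarray = dataclasses.field(default_factory=_default_genetic_cov)
    env_cov: np.ndarray = dataclasses.field(default_factory=_default_env_cov)
    tank_var: np.ndarray = dataclasses.field(
        default_factory=lambda: np.array([0.78, 0.0, 0.0, 0.0, 0.001])
    )
    sampling_day_effects: np.ndarray = dataclasses.field(
        default_factory=lambda: np.array([0.0, 0.25, 0.5, 0.75, 1.0])
    )
    seed: int = 0

    # Scale parameters of the growth / intake / turnover model.
    mean_iw: float = 21.8
    sd_iw: float = 6.0
    #: Correlation between initial weight and weight gain (bigger fish
    #: grow more); keeps relative gain inside the plausible range so the
    #: growth filters fire at realistic, error-like rates.
    iw_gain_corr: float = 0.8
    mean_gain: float = 10.8
    turnover_mean: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"muscle": 0.15, "liver": 0.21, "adipose": 0.02}
    )
    intake_per_gain: float = 0.45
    turnover_intake_cost: float = 0.53
    isotope_noise_sd: float = 0.01
    tank_fi_noise_sd: float = 0.0
    emit_delta: bool = False

    def __post_init__(self) -> None:
        self.genetic_cov = np.asarray(self.genetic_cov, dtype=float)
        self.env_cov = np.asarray(self.env_cov, dtype=float)
        self.tank_var = np.asarray(self.tank_var, dtype=float)
        self.sampling_day_effects = np.asarray(self.sampling_day_effects, dtype=float)
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5] with lo <= hi")
        for C, name in ((self.genetic_cov, "genetic_cov"), (self.env_cov, "env_cov")):
            if C.shape != (len(LATENTS), len(LATENTS)):
                raise ValueError(f"{name} must be {len(LATENTS)}x{len(LATENTS)}")
            if not np.allclose(C, C.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(C)[0] < -1e-8 * max(np.trace(C), 1.0):
                raise ValueError(f"{name} must be positive semi-definite")
        if self.tank_var.shape != (len(LATENTS),) or np.any(self.tank_var < 0):
            raise ValueError("tank_var must be 5 non-negative variances")
        if np.any(self.tank_var < 0):
            raise ValueError("tank_var entries must be non-negative")
        if self.sampling_day_effects.shape != (5,):
            raise ValueError("sampling_day_effects must have one entry per day 1..5")
        for trait, ia in self.baseline_atom.items():
            diet = self.diet_atom_for(trait)
            if not ia < diet:
                raise ValueError(
                    f"baseline atom% for {trait!r} ({ia}) must lie below the "
                    f"diet level ({diet})"
                )
        # Equilibrium guard: the deterministic mean new-nutrient fraction
        # must stay below 1 or the isotope signal saturates at the diet
        # level and carries no individual information.
        mean_rg = self.mean_gain / (self.mean_iw + self.mean_gain)
        worst = mean_rg + max(self.turnover_mean.values())
        if worst >= 1.0:
            raise ValueError(
                "configuration implies isotopic equilibrium (mean new-nutrient "
                f"fraction {worst:.2f} >= 1); shorten the window or reduce "
                "growth/turnover means"
            )

    def diet_atom_for(self, trait: str) -> float:
        return self.diet_atom_n15 if ISOTOPE_OF_TRAIT[trait] == "n15" else self.diet_atom_c13

    @property
    def n_tanks(self) -> int:
        return self.n_families * self.n_tanks_per_family

    @property
    def n_fish(self) -> int:
        return self.n_tanks * self.n_fish_per_tank

    def layout(self) -> pd.DataFrame:
        """Fish/family/tank/day labels; tanks get days 1..5 round-robin."""
        rows = []
        tank_counter = 0
        for f in range(self.n_families):
            fam = f"fam{f:02d}"
            for k in range(self.n_tanks_per_family):
                tank = f"{fam}_tank{k}"
                day = tank_counter % 5 + 1
                tank_counter += 1
                for i in range(self.n_fish_per_tank):
                    rows.append((f"{tank}_fish{i:02d}", fam, tank, day))
        return pd.DataFrame(rows, columns=["fish_id", "family", "tank", "day"])


@dataclasses.dataclass
class TruthRecord:
    """Ground truth of a simulation run, for parameter-recovery tests."""

    breeding_values: pd.DataFrame  # fish_id + bv_<latent> columns
    tank_effects: pd.DataFrame  # tank + te_<latent> columns
    intakes: pd.DataFrame  # fish_id, intake (g dry matter)


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Genotype full-sib families by Mendelian transmission.

    Allele frequencies are drawn uniformly from ``maf_range``; the two
    founders of each family are drawn in Hardy-Weinberg proportions and
    each offspring receives one uniformly chosen allele from each
    founder per locus (loci unlinked).  Full sibs then share an expected
    genomic relationship of about 0.5 on the base-frequency scale.
    """
    if config.n_families < 2:
        raise ValueError("at least two families are required")
    if config.n_snps < 10:
        raise ValueError("at least 10 SNPs are required")
    rng = np.random.default_rng([int(config.seed), 0])
    m = config.n_snps
    p = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    layout = config.layout()
    n_off = config.n_tanks_per_family * config.n_fish_per_tank

    dosages = np.empty((config.n_fish, m), dtype=float)
    row = 0
    for _ in range(config.n_families):
        sire = rng.random((2, m)) < p  # two haplotypes each
        dam = rng.random((2, m)) < p
        pick_s = rng.integers(0, 2, size=(n_off, m))
        pick_d = rng.integers(0, 2, size=(n_off, m))
        child = np.where(pick_s == 1, sire[1], sire[0]).astype(float)
        child += np.where(pick_d == 1, dam[1], dam[0])
        dosages[row:row + n_off] = child
        row += n_off
    return GenotypeMatrix(
        ids=list(layout["fish_id"]),
        dosages=dosages,
        snp_ids=[f"snp{j}" for j in range(m)],
        base_freqs=p,
    )


def _breeding_values(
    genotypes: GenotypeMatrix, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-SNP-effect breeding values, realized variance matched exactly.

    Effects are i.i.d. normal per latent with cross-trait correlation
    from ``genetic_cov``; after forming u = Z_c B the columns are
    centered and rescaled so the sample variance of each latent equals
    its configured genetic variance (correlations are matched in
    expectation only).
    """
    p = genotypes.base_freqs
    if p is None:
        raise ValueError("genotypes must carry base frequencies")
    Zc = genotypes.dosages - 2.0 * p[np.newaxis, :]
    target = config.genetic_cov
    var = np.diag(target).copy()
    sd = np.sqrt(var)
    corr = np.eye(len(LATENTS))
    pos = sd > 0
    corr[np.ix_(pos, pos)] = target[np.ix_(pos, pos)] / np.outer(sd[pos], sd[pos])
    L = np.linalg.cholesky(corr + 1e-10 * np.eye(len(LATENTS)))
    B = rng.standard_normal((genotypes.n_snps, len(LATENTS))) @ L.T
    u = Zc @ B
    u -= u.mean(axis=0)
    realized = u.var(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(realized > 0, np.sqrt(var / np.maximum(realized, 1e-300)), 0.0)
    return u * scale[np.newaxis, :]


def simulate_phenotypes(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Simulate weights, isotope atom% and tank feed intake.

    Returns the individual phenotype table (fish_id, family, tank, day,
    iw, fw, atom_* and optionally delta_* columns), the tank table
    (tank, day, fi, n_fish) and the :class:`TruthRecord`.  Tank feed
    intake equals the sum of its members' true intakes exactly unless
    ``tank_fi_noise_sd`` adds tank-level recording noise.
    """
    layout = config.layout()
    if list(genotypes.ids) != list(layout["fish_id"]):
        raise ValueError("genotypes do not cover the configured individuals")
    rng = np.random.default_rng([int(config.seed), 1])
    n = config.n_fish

    u = _breeding_values(genotypes, config, rng)
    # PSD square root (not Cholesky) so exactly-zero variances stay zero
    evals, evecs = np.linalg.eigh(config.env_cov)
    Le = evecs * np.sqrt(np.clip(evals, 0.0, None))
    e = rng.standard_normal((n, len(LATENTS))) @ Le.T
    tank_ids = list(dict.fromkeys(layout["tank"]))
    te = rng.standard_normal((len(tank_ids), len(LATENTS))) * np.sqrt(config.tank_var)
    tank_index = {t: k for k, t in enumerate(tank_ids)}
    te_fish = te[[tank_index[t] for t in layout["tank"]]]

    day_effect = config.sampling_day_effects[layout["day"].to_numpy() - 1]

    gidx = {name: k for k, name in enumerate(LATENTS)}
    wg = (
        config.mean_gain + day_effect
        + u[:, gidx["growth"]] + te_fish[:, gidx["growth"]] + e[:, gidx["growth"]]
    )
    # Initial weight correlated with gain (Gaussian copula on the
    # standardized gain): bigger fish grow more, so relative gain stays
    # in a plausible range without altering the gain distribution.
    rho = float(config.iw_gain_corr)
    wg_sd = wg.std()
    z_wg = (wg - wg.mean()) / wg_sd if wg_sd > 0 else np.zeros(n)
    z_iw = rho * z_wg + np.sqrt(max(1.0 - rho**2, 0.0)) * rng.standard_normal(n)
    iw = np.maximum(config.mean_iw + config.sd_iw * z_iw, 2.0)
    fw = iw + wg
    low = fw < 0.5  # physically implausible shrinkage; keep FW positive
    fw[low] = 0.5
    wg = fw - iw

    turnover = {}
    for tissue in ("muscle", "liver", "adipose"):
        k = gidx[f"turn_{tissue}"]
        turnover[tissue] = np.maximum(
            config.turnover_mean[tissue] + u[:, k] + te_fish[:, k] + e[:, k], 0.0
        )

    ind = layout.copy()
    ind["iw"], ind["fw"] = iw, fw
    standards = IsotopeStandards()
    for trait, tissue in TISSUE_OF_TRAIT.items():
        ia = config.baseline_atom[trait]
        diet = config.diet_atom_for(trait)
        f = np.clip((wg + turnover[tissue] * fw) / fw, 0.0, 1.0 - _EPS_F)
        noise = config.isotope_noise_sd * np.clip(
            rng.standard_normal(n), -3.0, 3.0
        )
        atom = ia + f * (diet - ia) + noise
        atom = np.minimum(atom, diet - 1e-9)
        ind[f"atom_{trait}"] = atom
        if config.emit_delta:
            ind[f"delta_{trait}"] = atom_percent_to_delta(
                atom, standards.ratio_for(ISOTOPE_OF_TRAIT[trait])
            )

    intake = np.maximum(
        config.intake_per_gain * wg
        + config.turnover_intake_cost * turnover["muscle"] * fw
        + u[:, gidx["intake_dev"]] + te_fish[:, gidx["intake_dev"]]
        + e[:, gidx["intake_dev"]],
        0.0,
    )

    fi = pd.Series(intake, index=layout["tank"].to_numpy()).groupby(level=0).sum()
    fi = fi.reindex(tank_ids)
    if config.tank_fi_noise_sd > 0:
        fi = fi + rng.normal(0.0, config.tank_fi_noise_sd, size=len(fi))
    tank_day = layout.drop_duplicates("tank").set_index("tank")["day"]
    tanks = pd.DataFrame(
        {
            "tank": tank_ids,
            "day": tank_day.reindex(tank_ids).to_numpy(),
            "fi": fi.to_numpy(),
            "n_fish": layout.groupby("tank").size().reindex(tank_ids).to_numpy(),
        }
    )

    truth = TruthRecord(
        breeding_values=pd.DataFrame(
            {"fish_id": layout["fish_id"], **{f"bv_{n_}": u[:, k] for k, n_ in enumerate(LATENTS)}}
        ),
        tank_effects=pd.DataFrame(
            {"tank": tank_ids, **{f"te_{n_}": te[:, k] for k, n_ in enumerate(LATENTS)}}
        ),
        intakes=pd.DataFrame({"fish_id": layout["fish_id"], "intake": intake}),
    )
    return ind, tanks, truth
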