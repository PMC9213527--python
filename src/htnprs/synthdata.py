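"""Synthetic multi-ancestry cohort generator.

Generates every input the pipeline reads, with the statistical structure the
method assumes:

* ancestry-differentiated allele frequencies via the Balding-Nichols model
  (group frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F) around an ancestral p);
* LD blocks from a latent-Gaussian haplotype model: within a block the
  latent variables follow an AR(1) correlation, thresholded at the
  quantile of each sample's admixture-weighted allele frequency, so the
  dosage r² target is analytically controllable;
* sparse relatedness: a configurable fraction of samples are siblings who
  draw haplotypes from shared simulated parents (kinship 0.25 edges);
* correlated SBP/DBP/HTN genetic effects: causal variants carry an effect
  triple from a multivariate normal; a hypertension-specific component is
  folded into both BP traits, so the three discovery GWAS share signal while
  each also contributes its own;
* two-visit (or longer) BP measurements with a progression drift, absorbing
  antihypertensive treatment, and covariates; hypertension status is always
  derived through the phenotyping rules (single source of truth);
* discovery GWAS summary statistics with the standard error implied by the
  discovery sample size and allele frequency.

All randomness flows from the mandatory seed; each operation uses its own
stream derived from (seed, operation tag), so outputs are reproducible and
insertion of new steps never shifts existing streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, ndtri

from .genodata import GenotypeDataset, KinshipGraph
from .sumstats import SumStats, SumStatsRecord, VariantKey

TRAITS = ("SBP", "DBP", "HTN")

# stable stream tags per operation
_TAG_FREQ, _TAG_GENO, _TAG_PHENO, _TAG_SUMSTATS, _TAG_OUTCOME = 1, 2, 3, 4, 5

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"), ("A", "C"), ("G", "T")]


@dataclass
class SimConfig:
    """Generator settings; the defaults are the study conditions emulated."""

    seed: int
    n_samples: dict[str, int] = field(default_factory=lambda: {"groupA": 1000, "groupB": 1000})
    n_variants: int = 1000
    ld_block_size: int = 10
    # latent-scale AR(1) correlation between adjacent variants; dichotomizing
    # haplotypes attenuates it, so 0.9 here yields adjacent dosage r2 ~ 0.4
    ld_rho: float = 0.9
    freq_range: tuple[float, float] = (0.05, 0.5)
    fst: float = 0.1
    admixture_concentration: float = 20.0
    family_fraction: float = 0.1
    sibship_size: int = 2
    causal_fraction: float = 0.01
    effect_sd: dict[str, float] = field(
        default_factory=lambda: {"SBP": 0.6, "DBP": 0.4, "HTN": 0.5}
    )
    trait_corr: tuple = ((1.0, 0.5, 0.4), (0.5, 1.0, 0.4), (0.4, 0.4, 1.0))
    htn_liability_weight: float = 0.5
    effect_z_range: tuple[float, float] = (7.0, 15.0)  # discovery |z| of causal variants
    resid_sd: dict[str, float] = field(default_factory=lambda: {"SBP": 12.0, "DBP": 8.0})
    person_sd: float = 6.0  # person-level BP intercept shared across visits
    mean_sbp: float = 118.0
    mean_dbp: float = 74.0
    ancestry_shift_sbp: float = 4.0  # mmHg shift per unit first-ancestry proportion
    treatment_prob: float = 0.4
    discovery_n: dict[str, int] = field(
        default_factory=lambda: {"SBP": 40_000, "DBP": 40_000, "HTN": 60_000}
    )
    htn_case_fraction: float = 0.35
    n_visits: int = 2
    visit_spacing_years: float = 5.0
    progression_drift: float = 3.0  # mmHg SBP per visit (DBP scaled by 0.5)
    age_range: tuple[float, float] = (30.0, 70.0)
    n_sites: int = 2
    pos_spacing_bp: int = 20_000

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name, val in (("family_fraction", self.family_fraction), ("causal_fraction", self.causal_fraction), ("treatment_prob", self.treatment_prob)):
            if not 0 <= val <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        c = np.asarray(self.trait_corr)
        if np.any(np.linalg.eigvalsh(c) < -1e-10):
            raise ValueError("trait_corr must be positive semi-definite")
        if not 0 <= self.fst < 0.5:
            raise ValueError("fst must be in [0, 0.5)")

    @property
    def groups(self) -> list[str]:
        return list(self.n_samples)

    @property
    def total_n(self) -> int:
        return sum(self.n_samples.values())

    def rng(self, tag: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, tag])


@dataclass
class GroundTruth:
    """Everything needed to compute oracle quantities for a simulation."""

    variants: list[VariantKey]
    causal: np.ndarray  # bool per variant
    beta_true: dict[str, np.ndarray]  # trait -> per-variant true effect
    admixture: pd.DataFrame  # per-sample ancestry proportions
    families: list[list[str]]
    pooled_freqs: np.ndarray

    def oracle_weights(self, trait: str) -> dict[VariantKey, float]:
        b = self.beta_true[trait]
        return {v: float(b[i]) for i, v in enumerate(self.variants) if self.causal[i]}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chrom": [v.chrom for v in self.variants],
                "pos": [v.pos for v in self.variants],
                "effect_allele": [v.effect_allele for v in self.variants],
                "other_allele": [v.other_allele for v in self.variants],
                "causal": self.causal.astype(int),
                "pooled_freq": self.pooled_freqs,
            }
        )
        for t in TRAITS:
            df[f"beta_{t}"] = self.beta_true[t]
        return df


def _variant_keys(cfg: SimConfig) -> list[VariantKey]:
    keys = []
    for i in range(cfg.n_variants):
        ea, oa = _ALLELE_PAIRS[i % len(_ALLELE_PAIRS)]
        keys.append(VariantKey("1", (i + 1) * cfg.pos_spacing_bp, ea, oa))
    return keys


def simulate_frequencies(cfg: SimConfig) -> pd.DataFrame:
    """Balding-Nichols per-group allele frequencies (variants x groups)."""
    rng = cfg.rng(_TAG_FREQ)
    lo, hi = cfg.freq_range
    p = rng.uniform(lo, hi, size=cfg.n_variants)
    out = {}
    for g in cfg.groups:
        if cfg.fst == 0:
            fg = p.copy()
        else:
            a = p * (1 - cfg.fst) / cfg.fst
            b = (1 - p) * (1 - cfg.fst) / cfg.fst
            fg = rng.beta(a, b)
        out[g] = np.clip(fg, 0.005, 0.995)
    df = pd.DataFrame(out)
    df.insert(0, "ancestral", p)
    return df


def simulate_genotypes(
    cfg: SimConfig, freqs: pd.DataFrame
) -> tuple[GenotypeDataset, KinshipGraph, pd.DataFrame, list[list[str]]]:
    """Latent-Gaussian LD genotypes with admixture and sibships."""
    rng = cfg.rng(_TAG_GENO)
    m = cfg.n_variants
    groups = cfg.groups
    k_anc = len(groups)
    fg = freqs[groups].to_numpy()  # m x k

    sample_ids: list[str] = []
    sample_group: list[str] = []
    for g in groups:
        for i in range(cfg.n_samples[g]):
            sample_ids.append(f"{g}_{i:05d}")
            sample_group.append(g)
    n = len(sample_ids)

    # per-sample admixture: Dirichlet concentrated on own ancestry
    alpha0 = np.ones(k_anc)
    admix = np.empty((n, k_anc))
    row = 0
    for gi, g in enumerate(groups):
        a = alpha0.copy()
        a[gi] = cfg.admixture_concentration
        cnt = cfg.n_samples[g]
        admix[row : row + cnt] = rng.dirichlet(a, size=cnt)
        row += cnt

    # sibships: pairs (or larger) drawn within group, sharing parents
    families: list[list[str]] = []
    n_fam_samples = int(cfg.family_fraction * n)
    fam_members: list[list[int]] = []
    if n_fam_samples >= cfg.sibship_size and cfg.sibship_size >= 2:
        pool = []
        row = 0
        for g in groups:
            cnt = cfg.n_samples[g]
            take = int(cfg.family_fraction * cnt)
            pool.extend(range(row, row + take))
            row += cnt
        for start in range(0, len(pool) - cfg.sibship_size + 1, cfg.sibship_size):
            fam_members.append(list(pool[start : start + cfg.sibship_size]))
    for fam in fam_members:
        # siblings share admixture (their parents')
        admix[fam[1:]] = admix[fam[0]]
        families.append([sample_ids[i] for i in fam])

    # individual allele frequency = admixture-weighted group frequency
    f_ind = admix @ fg.T  # n x m
    thresh = ndtri(np.clip(f_ind, 1e-6, 1 - 1e-6))

    # block AR(1) Cholesky shared by all blocks
    def block_chol(size: int) -> np.ndarray:
        idx = np.arange(size)
        corr = cfg.ld_rho ** np.abs(idx[:, None] - idx[None, :])
        return np.linalg.cholesky(corr)

    bs = cfg.ld_block_size
    n_blocks = (m + bs - 1) // bs
    chols = {}

    def draw_latent(rows: int) -> np.ndarray:
        z = np.empty((rows, m))
        for b in range(n_blocks):
            s, e = b * bs, min((b + 1) * bs, m)
            size = e - s
            if size not in chols:
                chols[size] = block_chol(size)
            z[:, s:e] = rng.standard_normal((rows, size)) @ chols[size].T
        return z

    # unrelated samples: two haplotypes each from their own frequencies
    hap1 = (draw_latent(n) < thresh).astype(np.int8)
    hap2 = (draw_latent(n) < thresh).astype(np.int8)

    # siblings redraw from 4 shared parental haplotypes
    kin_edges: list[tuple[str, str, float]] = []
    for fam in fam_members:
        f_fam = np.clip(admix[fam[0]] @ fg.T, 1e-6, 1 - 1e-6)
        t_fam = ndtri(f_fam)
        parents = (draw_latent(4) < t_fam).astype(np.int8)  # 4 parental haplotypes
        for i in fam:
            hap1[i] = parents[rng.integers(0, 2)]
            hap2[i] = parents[2 + rng.integers(0, 2)]
        for a in range(len(fam)):
            for b in range(a + 1, len(fam)):
                kin_edges.append((sample_ids[fam[a]], sample_ids[fam[b]], 0.25))

    dosages = (hap1 + hap2).astype(float)
    g = GenotypeDataset(sample_ids, _variant_keys(cfg), dosages)
    kinship = KinshipGraph.from_pairs(kin_edges, sample_ids)
    admix_df = pd.DataFrame(admix, index=sample_ids, columns=[f"anc_{gr}" for gr in groups])
    admix_df.insert(0, "group", sample_group)
    return g, kinship, admix_df, families


def draw_effects(cfg: SimConfig, pooled_freqs: np.ndarray) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Causal set and per-trait true effects.

    Causal variants carry a correlated (SBP, DBP, HTN-specific) effect
    triple; the HTN-specific part is folded into both BP traits with weight
    ``htn_liability_weight``.  The HTN discovery GWAS effect (log-OR) is a
    stylized liability mapping of the total BP effects; its magnitude is
    re-scaled so causal discovery |z| falls in ``effect_z_range``.
    """
    rng = cfg.rng(_TAG_FREQ + 10)
    m = cfg.n_variants
    n_causal = max(1, int(round(cfg.causal_fraction * m)))
    causal_idx = rng.choice(m, size=n_causal, replace=False)
    causal = np.zeros(m, dtype=bool)
    causal[causal_idx] = True

    sds = np.array([cfg.effect_sd[t] for t in TRAITS])
    corr = np.asarray(cfg.trait_corr)
    cov = corr * np.outer(sds, sds)
    raw = rng.multivariate_normal(np.zeros(3), cov, size=n_causal)
    lam = cfg.htn_liability_weight
    t_sbp = np.zeros(m)
    t_dbp = np.zeros(m)
    t_sbp[causal_idx] = raw[:, 0] + lam * raw[:, 2]
    t_dbp[causal_idx] = raw[:, 1] + lam * raw[:, 2]

    # stylized liability-scale log-OR for the binary hypertension trait
    t_htn = 0.85 * (t_sbp / cfg.resid_sd["SBP"] + t_dbp / cfg.resid_sd["DBP"])

    # rescale each trait's causal effects so discovery |z| covers the target range
    zlo, zhi = cfg.effect_z_range
    z_target = rng.uniform(zlo, zhi, size=n_causal) * rng.choice([-1.0, 1.0], size=n_causal)
    betas = {"SBP": t_sbp, "DBP": t_dbp, "HTN": t_htn}
    out = {}
    for trait in TRAITS:
        se = _discovery_se(cfg, trait, pooled_freqs[causal_idx])
        b = betas[trait].copy()
        cur = b[causal_idx]
        scale = np.abs(z_target * se) / np.maximum(np.abs(cur), 1e-12)
        # preserve the correlated sign structure, match |z| to the target
        b[causal_idx] = cur * scale
        out[trait] = b
    return causal, out


def _discovery_se(cfg: SimConfig, trait: str, f: np.ndarray) -> np.ndarray:
    n = cfg.discovery_n[trait]
    info = 2.0 * n * f * (1.0 - f)
    if trait == "HTN":
        phi = cfg.htn_case_fraction
        info = info * phi * (1.0 - phi)
        return 1.0 / np.sqrt(info)
    return cfg.resid_sd[trait] / np.sqrt(info)


def simulate_truth(
    cfg: SimConfig,
    g: GenotypeDataset,
    admix: pd.DataFrame,
    families: list[list[str]] | None = None,
) -> GroundTruth:
    pooled = g.dosages.mean(axis=0) / 2.0
    causal, betas = draw_effects(cfg, pooled)
    families = families or []
    return GroundTruth(
        variants=list(g.variants),
        causal=causal,
        beta_true=betas,
        admixture=admix,
        families=families,
        pooled_freqs=pooled,
    )


def simulate_phenotypes(
    cfg: SimConfig, g: GenotypeDataset, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Visit-level BP table and per-sample covariate table.

    SBP/DBP are linear in the causal dosages plus covariate and ancestry
    effects, a person-level intercept shared across visits, and visit noise;
    later visits add a progression drift.  Treatment is absorbing: once a
    sample meets the hypertension criteria at a visit it starts treatment
    with the configured probability, which lowers subsequent measured BP by
    10/5 mmHg.  Hypertension status is derived only through the phenotyping
    rules.
    """
    rng = cfg.rng(_TAG_PHENO)
    n = g.n_samples
    ids = g.sample_ids

    G = g.dosages
    gs = G @ truth.beta_true["SBP"]
    gd = G @ truth.beta_true["DBP"]

    sex = rng.integers(0, 2, size=n)  # 1 = female
    age0 = rng.uniform(*cfg.age_range, size=n)
    bmi = rng.normal(28.0, 4.0, size=n)
    smoking = (rng.random(n) < 0.2).astype(int)
    site = rng.integers(0, cfg.n_sites, size=n)
    anc1 = truth.admixture.iloc[:, 1].to_numpy()  # first ancestry proportion
    person = rng.normal(0.0, cfg.person_sd, size=n)

    base_sbp = (
        cfg.mean_sbp
        + gs
        - 3.0 * sex
        + 0.25 * (age0 - 50.0)
        + 0.4 * (bmi - 28.0)
        + 2.0 * smoking
        + cfg.ancestry_shift_sbp * anc1
        + person
    )
    base_dbp = (
        cfg.mean_dbp
        + gd
        - 2.0 * sex
        + 0.10 * (age0 - 50.0)
        + 0.25 * (bmi - 28.0)
        + 1.0 * smoking
        + 0.5 * cfg.ancestry_shift_sbp * anc1
        + 0.5 * person
    )

    treated = np.zeros(n, dtype=bool)
    rows = []
    for v in range(cfg.n_visits):
        t = v * cfg.visit_spacing_years
        sbp = base_sbp + v * cfg.progression_drift + rng.normal(0, cfg.resid_sd["SBP"], n)
        dbp = base_dbp + v * 0.5 * cfg.progression_drift + rng.normal(0, cfg.resid_sd["DBP"], n)
        sbp = sbp - 10.0 * treated
        dbp = dbp - 5.0 * treated
        dbp = np.minimum(dbp, sbp - 5.0)  # physiologic: pulse pressure > 0
        dbp = np.maximum(dbp, 30.0)
        sbp = np.maximum(sbp, dbp + 5.0)
        meets = (sbp >= 130) | (dbp >= 80) | treated
        newly = (~treated) & meets & (rng.random(n) < cfg.treatment_prob)
        for i in range(n):
            rows.append(
                {
                    "sample_id": ids[i],
                    "visit": v + 1,
                    "sbp": float(sbp[i]),
                    "dbp": float(dbp[i]),
                    "treated": bool(treated[i]),
                    "self_report_htn": bool(treated[i]),
                    "age": float(age0[i] + t),
                    "time": float(t),
                }
            )
        treated = treated | newly

    visits = pd.DataFrame(rows)
    covars = pd.DataFrame(
        {
            "sample_id": ids,
            "sex": sex,
            "age": age0,
            "age2": age0**2,
            "bmi": bmi,
            "smoking": smoking,
            "site": [f"site{j}" for j in site],
            "background": truth.admixture["group"].to_numpy(),
        }
    )
    # ancestry proportions stand in for genetic PCs (centered, last dropped)
    anc = truth.admixture.drop(columns="group").to_numpy()
    for j in range(anc.shape[1] - 1):
        covars[f"pc{j + 1}"] = anc[:, j] - anc[:, j].mean()
    return visits, covars


def simulate_sumstats(cfg: SimConfig, truth: GroundTruth, trait: str) -> SumStats:
    """Discovery-GWAS summary statistics: beta_hat ~ N(beta_true, se²)."""
    rng = cfg.rng(_TAG_SUMSTATS * 100 + TRAITS.index(trait))
    f = np.clip(truth.pooled_freqs, 0.01, 0.99)
    se = _discovery_se(cfg, trait, f)
    beta_true = truth.beta_true[trait]
    beta_hat = rng.normal(beta_true, se)
    z = beta_hat / se
    pvals = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    records = [
        SumStatsRecord(
            key=v,
            beta=float(beta_hat[i]),
            se=float(se[i]),
            pvalue=float(pvals[i]),
            eaf=float(f[i]),
            n=float(cfg.discovery_n[trait]),
        )
        for i, v in enumerate(truth.variants)
    ]
    return SumStats(trait=trait, records=records)


def simulate_binary_outcome(
    prs_std: np.ndarray,
    log_or_per_sd: float,
    prevalence: float,
    seed: int,
) -> np.ndarray:
    """Binary outcome from a logistic model in the standardized score.

    Used for effect-size calibration studies where the generating per-SD
    log-OR must be exactly known.
    """
    rng = np.random.default_rng([seed, _TAG_OUTCOME])
    z = np.asarray(prs_std, dtype=float)
    intercept = float(np.log(prevalence / (1 - prevalence)))
    p = expit(intercept + log_or_per_sd * z)
    return (rng.random(len(z)) < p).astype(int)


def simulate_cohort(cfg: SimConfig):
    """One-call generator: genotypes, kinship, truth, visits, covariates."""
    freqs = simulate_frequencies(cfg)
    g, kinship, admix, families = simulate_genotypes(cfg, freqs)
    truth = simulate_truth(cfg, g, admix, families)
    visits, covars = simulate_phenotypes(cfg, g, truth)
    return g, kinship, truth, visits, covars
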