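"""Liability-threshold synthetic cohorts with LD structure and paired GWAS.

The generator emulates the data a case/control PRS benchmark consumes when
the real cohorts are access-restricted:

* an LD-structured variant panel — haplotype alleles are produced by
  thresholding a latent AR(1) Gaussian at each variant's allele-frequency
  quantile, so adjacent variants within a block show tunably decaying r^2
  while distinct blocks are independent;
* a dedicated APOE-like block on its own chromosome, with two designated
  epsilon-defining sites (rs429358/rs7412 roles) drawn from a three-haplotype
  (e2/e3/e4) frequency model plus tag variants in LD with the e4 haplotype;
* case/control status from a liability-threshold model (latent Gaussian
  liability = polygenic + APOE + environment; case iff liability exceeds the
  prevalence quantile), with rejection-sampling ascertainment to target
  case/control counts;
* two discovery GWAS (traits A and B) whose marginal effect-size vectors have
  a configurable genetic correlation ``rg``, with sampling noise matching the
  stated discovery sample sizes through the standardized-trait SE
  approximation SE = 1/sqrt(2 p (1-p) n);
* a microglia-like annotation: contiguous regions covering a few percent of
  variants, including a sub-interval of the APOE block that excludes the two
  epsilon-defining sites.

Full ground truth (causal effects, LD-convolved marginal effects, liabilities)
is retained for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .apoe import APOE_REGION_END, APOE_REGION_START
from .geno_io import GenotypeMatrix, RegionSet, SummaryStats, VariantRecord

_ASCERTAINMENT_CAP = 10_000_000  # max population draws during ascertainment
_N_LD_REFERENCE = 4000  # reference sample used to estimate population block LD


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults are the benchmark's conditions.

    ``n_variants`` counts the polygenic (main-chromosome) panel; the APOE-like
    block adds two epsilon-defining sites plus ``n_apoe_tags`` tag variants on
    chromosome 19. Discovery sample sizes default to the clinical-AD-scale
    (~64k) and proxy-ADRD-scale (~488k) studies the benchmark emulates; the
    ascertained target cohort defaults to 223 cases / 345 controls.
    """

    n_variants: int = 2000
    n_blocks: int = 100
    block_rho: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    pi_causal: float = 0.1
    h2: float = 0.2
    prevalence: float = 0.05
    n_cases: int = 223
    n_controls: int = 345
    apoe_beta_e4: float = 0.7
    apoe_beta_e2: float = -0.3
    rg: float = 0.8
    n_gwas_a: float = 63_926
    n_gwas_b: float = 487_511
    microglia_fraction: float = 0.03
    seed: int = 0
    # APOE-like locus layout
    apoe_freq_e2: float = 0.08
    apoe_freq_e4: float = 0.20
    apoe_tag_prob: float = 0.6
    n_apoe_tags: int = 18
    # covariate generation
    age_mean: float = 74.0
    age_sd: float = 7.0
    age_case_shift: float = 2.5
    sex_female_prob: float = 0.55

    def __post_init__(self):
        checks = {
            "n_variants >= 1": self.n_variants >= 1,
            "1 <= n_blocks <= n_variants": 1 <= self.n_blocks <= self.n_variants,
            "block_rho in [0,1)": 0.0 <= self.block_rho < 1.0,
            "maf_range in (0,0.5]": 0.0 < self.maf_range[0] <= self.maf_range[1] <= 0.5,
            "pi_causal in (0,1]": 0.0 < self.pi_causal <= 1.0,
            "pi_causal*n_variants >= 1": self.pi_causal * self.n_variants >= 1.0,
            "h2 in [0,1)": 0.0 <= self.h2 < 1.0,
            "prevalence in (0,1)": 0.0 < self.prevalence < 1.0,
            "cohort sizes positive": self.n_cases >= 1 and self.n_controls >= 1,
            "rg in [-1,1]": -1.0 <= self.rg <= 1.0,
            "gwas sizes positive": self.n_gwas_a > 0 and self.n_gwas_b > 0,
            "microglia_fraction in (0,1)": 0.0 < self.microglia_fraction < 1.0,
            "apoe hap freqs valid": 0.0 < self.apoe_freq_e2
            and 0.0 < self.apoe_freq_e4
            and self.apoe_freq_e2 + self.apoe_freq_e4 < 1.0,
        }
        finite = all(
            np.isfinite(v)
            for v in (
                self.block_rho, self.pi_causal, self.h2, self.prevalence,
                self.apoe_beta_e4, self.apoe_beta_e2, self.rg,
                self.microglia_fraction, *self.maf_range,
            )
        )
        checks["all fields finite"] = finite
        bad = [name for name, ok in checks.items() if not ok]
        if bad:
            raise ValueError(f"invalid SimulationConfig: {'; '.join(bad)}")


@dataclass
class VariantPanel:
    """Fixed characteristics of the simulated variant panel (seed-derived)."""

    variants: list[VariantRecord]
    freq: np.ndarray  # population alt-allele frequency per variant
    blocks: list[np.ndarray]  # column-index arrays; APOE block is last
    idx_e4: int
    idx_e2: int
    apoe_tag_idx: np.ndarray
    tag_maf: np.ndarray  # baseline Bernoulli freq of the tag variants

    @property
    def n_total(self) -> int:
        return len(self.variants)

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(2.0 * self.freq * (1.0 - self.freq))


@dataclass
class TruthRecord:
    """Ground truth retained for recovery tests.

    Effects are on the standardized-genotype liability scale; ``beta_marginal``
    is the LD-convolved (block-correlation times causal) marginal effect that
    an infinite-sample GWAS of trait A would estimate. ``beta_marginal_b`` is
    the trait-B analogue, correlated with trait A at ``rg``.
    """

    beta_true: np.ndarray
    causal_mask: np.ndarray
    beta_marginal: np.ndarray
    beta_marginal_b: np.ndarray
    env_sd: float
    liability: np.ndarray | None = None

    def __post_init__(self):
        if np.any(self.beta_true[~self.causal_mask] != 0.0):
            raise ValueError("beta_true must be zero where causal_mask is false")


def _child_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def build_panel(config: SimulationConfig) -> VariantPanel:
    """Deterministically derive the variant panel from the config seed."""
    rng = _child_rng(config.seed, 0)
    m = config.n_variants
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    # main chromosome: evenly spaced positions, blocks of near-equal size
    pos = 1_000_000 + 5_000 * np.arange(m)
    bounds = np.linspace(0, m, config.n_blocks + 1).astype(int)
    blocks = [np.arange(bounds[i], bounds[i + 1]) for i in range(config.n_blocks)]
    blocks = [b for b in blocks if b.size]
    variants = [
        VariantRecord(chrom="1", pos=int(pos[j]), id=f"snp{j}", ref="A", alt="G")
        for j in range(m)
    ]
    # APOE-like block on chromosome 19
    n_tags = config.n_apoe_tags
    half = n_tags // 2
    tag_pos_low = np.linspace(43_950_000, 44_880_000, max(half, 1)).astype(int)
    tag_pos_high = np.linspace(44_950_000, 45_900_000, max(n_tags - half, 1)).astype(int)
    tag_pos = np.concatenate([tag_pos_low[:half], tag_pos_high[: n_tags - half]])
    pos_e4, pos_e2 = 44_908_684, 44_908_822
    apoe_records, apoe_freqs = [], []
    tag_maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=n_tags)
    entries = [(int(p), "tag", i) for i, p in enumerate(tag_pos)]
    entries += [(pos_e4, "e4", -1), (pos_e2, "e2", -1)]
    entries.sort()
    idx_e4 = idx_e2 = -1
    tag_idx = []
    for k, (p, kind, i) in enumerate(entries):
        col = m + k
        if kind == "e4":
            idx_e4 = col
            apoe_records.append(
                VariantRecord(chrom="19", pos=p, id="rs429358_like", ref="T", alt="C")
            )
            apoe_freqs.append(config.apoe_freq_e4)
        elif kind == "e2":
            idx_e2 = col
            apoe_records.append(
                VariantRecord(chrom="19", pos=p, id="rs7412_like", ref="C", alt="T")
            )
            apoe_freqs.append(config.apoe_freq_e2)
        else:
            apoe_records.append(
                VariantRecord(chrom="19", pos=p, id=f"apoe_tag{i}", ref="A", alt="G")
            )
            # tag allele copies the e4 haplotype indicator with prob tag_prob
            f = config.apoe_tag_prob * config.apoe_freq_e4 + (1 - config.apoe_tag_prob) * tag_maf[i]
            apoe_freqs.append(f)
            tag_idx.append(col)
    blocks.append(np.arange(m, m + len(entries)))
    return VariantPanel(
        variants=variants + apoe_records,
        freq=np.concatenate([mafs, np.array(apoe_freqs)]),
        blocks=blocks,
        idx_e4=idx_e4,
        idx_e2=idx_e2,
        apoe_tag_idx=np.array(tag_idx, dtype=int),
        tag_maf=tag_maf,
    )


def _draw_dosages(panel: VariantPanel, config: SimulationConfig, n: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Draw n samples (2n haplotypes) of dosages for the full panel."""
    n_hap = 2 * n
    m_total = panel.n_total
    hap = np.empty((n_hap, m_total), dtype=np.int8)
    rho = config.block_rho
    # main-chromosome blocks: latent AR(1) Gaussian thresholded per MAF
    for block in panel.blocks[:-1]:
        z = np.empty((n_hap, block.size))
        z[:, 0] = rng.standard_normal(n_hap)
        if block.size > 1:
            eps = rng.standard_normal((n_hap, block.size - 1))
            c = np.sqrt(1.0 - rho**2)
            for t in range(1, block.size):
                z[:, t] = rho * z[:, t - 1] + c * eps[:, t - 1]
        thresh = norm.ppf(panel.freq[block])
        hap[:, block] = (z < thresh[None, :]).astype(np.int8)
    # APOE-like block: three-haplotype model + tag copying
    p2, p4 = config.apoe_freq_e2, config.apoe_freq_e4
    u = rng.random(n_hap)
    is_e4 = u < p4
    is_e2 = (u >= p4) & (u < p4 + p2)
    hap[:, panel.idx_e4] = is_e4.astype(np.int8)
    hap[:, panel.idx_e2] = is_e2.astype(np.int8)
    for i, col in enumerate(panel.apoe_tag_idx):
        copy = rng.random(n_hap) < config.apoe_tag_prob
        base = rng.random(n_hap) < panel.tag_maf[i]
        hap[:, col] = np.where(copy, is_e4, base).astype(np.int8)
    return (hap[0::2] + hap[1::2]).astype(float)


def simulate_genotypes(
    config: SimulationConfig,
    n_samples: int | None = None,
    panel: VariantPanel | None = None,
    rng: np.random.Generator | None = None,
    sample_prefix: str = "S",
) -> GenotypeMatrix:
    """Simulate an LD-structured dosage matrix for the configured panel.

    Dosages are sums of two independent haplotypes; same config (and seed)
    gives bit-identical output.
    """
    panel = panel or build_panel(config)
    if n_samples is None:
        n_samples = config.n_cases + config.n_controls
    rng = rng or _child_rng(config.seed, 1)
    dosage = _draw_dosages(panel, config, n_samples, rng)
    return GenotypeMatrix(
        samples=[f"{sample_prefix}{i}" for i in range(n_samples)],
        variants=list(panel.variants),
        dosage=dosage,
    )


def _block_ld(panel: VariantPanel, config: SimulationConfig) -> list[np.ndarray]:
    """Population dosage-correlation matrix per block, estimated on an
    independent unascertained reference sample (deterministic child seed)."""
    rng = _child_rng(config.seed, 2)
    dos = _draw_dosages(panel, config, _N_LD_REFERENCE, rng)
    mats = []
    for block in panel.blocks:
        X = dos[:, block]
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        R = np.corrcoef(X, rowvar=False)
        if block.size == 1:
            R = np.array([[1.0]])
        R = np.nan_to_num(R, nan=0.0)
        np.fill_diagonal(R, 1.0)
        mats.append(R)
    return mats


def _apoe_std_effects(panel: VariantPanel, config: SimulationConfig) -> tuple[float, float]:
    """Epsilon-site effects converted to the standardized-genotype scale."""
    sd4 = np.sqrt(2 * config.apoe_freq_e4 * (1 - config.apoe_freq_e4))
    sd2 = np.sqrt(2 * config.apoe_freq_e2 * (1 - config.apoe_freq_e2))
    return config.apoe_beta_e4 * sd4, config.apoe_beta_e2 * sd2


def apoe_liability_variance(config: SimulationConfig) -> float:
    """Liability variance contributed by the two epsilon sites (incl. their
    negative covariance: the two defining alleles never share a haplotype)."""
    p2, p4 = config.apoe_freq_e2, config.apoe_freq_e4
    b4, b2 = config.apoe_beta_e4, config.apoe_beta_e2
    var4 = 2 * p4 * (1 - p4)
    var2 = 2 * p2 * (1 - p2)
    cov = -2 * p2 * p4
    return b4**2 * var4 + b2**2 * var2 + 2 * b4 * b2 * cov


def assign_effects(config: SimulationConfig, panel: VariantPanel | None = None) -> TruthRecord:
    """Draw causal effects and compute LD-convolved marginal effects.

    The causal mask is Bernoulli(pi_causal) over non-epsilon variants (the two
    epsilon-defining sites are always causal with the configured per-allele
    effects); polygenic effects are i.i.d. Normal(0, h2/m_causal) on the
    standardized scale. Trait B's marginal vector is
    rg * beta_marginal_A + sqrt(1-rg^2) * (an independent same-law draw).
    """
    panel = panel or build_panel(config)
    rng = _child_rng(config.seed, 3)
    m_total = panel.n_total
    eps_idx = {panel.idx_e4, panel.idx_e2}
    ld = _block_ld(panel, config)

    def draw_effect_vector(include_apoe: bool) -> tuple[np.ndarray, np.ndarray]:
        mask = rng.random(m_total) < config.pi_causal
        for i in eps_idx:
            mask[i] = True
        m_causal = int(mask.sum()) - 2
        if m_causal <= 0 and config.h2 > 0:
            raise ValueError("no polygenic causal variants drawn (m_causal = 0)")
        beta = np.zeros(m_total)
        poly = mask.copy()
        for i in eps_idx:
            poly[i] = False
        if m_causal > 0:
            sd = np.sqrt(config.h2 / m_causal) if config.h2 > 0 else 0.0
            beta[poly] = rng.normal(0.0, sd, size=int(poly.sum())) if sd > 0 else 0.0
        if include_apoe:
            b4, b2 = _apoe_std_effects(panel, config)
            beta[panel.idx_e4] = b4
            beta[panel.idx_e2] = b2
        return beta, mask

    beta_true, causal_mask = draw_effect_vector(include_apoe=True)
    # the trait-B mixing component is a fresh polygenic draw WITHOUT the fixed
    # epsilon-site effects: those are deterministic config values, so a
    # "re-draw" would be perfectly shared and inflate the cross-trait
    # correlation above rg. Trait B's APOE signal therefore scales with rg
    # (an attenuated major locus, as seen in proxy-phenotype GWAS).
    beta_ind, _ = draw_effect_vector(include_apoe=False)

    def convolve(beta: np.ndarray) -> np.ndarray:
        marg = np.zeros_like(beta)
        for block, R in zip(panel.blocks, ld):
            marg[block] = R @ beta[block]
        return marg

    beta_marginal = convolve(beta_true)
    bm_ind = convolve(beta_ind)
    rg = config.rg
    beta_marginal_b = rg * beta_marginal + np.sqrt(1.0 - rg**2) * bm_ind

    var_apoe = apoe_liability_variance(config)
    env_var = 1.0 - config.h2 - var_apoe
    if env_var <= 0:
        raise ValueError(
            f"h2 ({config.h2}) + APOE variance ({var_apoe:.3f}) leave no "
            "environmental variance on the liability scale"
        )
    return TruthRecord(
        beta_true=beta_true,
        causal_mask=causal_mask,
        beta_marginal=beta_marginal,
        beta_marginal_b=beta_marginal_b,
        env_sd=float(np.sqrt(env_var)),
    )


def genetic_liability(dosage: np.ndarray, panel: VariantPanel, truth: TruthRecord) -> np.ndarray:
    """Genetic component of liability for a dosage matrix (standardized scale)."""
    Z = (dosage - 2.0 * panel.freq[None, :]) / panel.sd[None, :]
    return Z @ truth.beta_true


def simulate_phenotype(
    genotypes: GenotypeMatrix,
    truth: TruthRecord,
    config: SimulationConfig,
    panel: VariantPanel | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Liability-threshold phenotype plus covariates for an existing matrix.

    No ascertainment: every sample keeps its drawn status, so the case
    fraction approaches the configured prevalence. Use
    :func:`simulate_cohort` for an ascertained case/control cohort.
    """
    panel = panel or build_panel(config)
    if genotypes.n_variants != panel.n_total:
        raise ValueError("genotypes do not match the configured panel")
    rng = rng or _child_rng(config.seed, 4)
    g = genetic_liability(genotypes.dosage, panel, truth)
    liab = g + rng.normal(0.0, truth.env_sd, size=len(g))
    case = (liab > norm.ppf(1.0 - config.prevalence)).astype(int)
    return _with_covariates(genotypes.samples, case, liab, config, rng)


def _with_covariates(samples, case, liability, config, rng) -> pd.DataFrame:
    n = len(samples)
    age = rng.normal(config.age_mean, config.age_sd, size=n) + config.age_case_shift * case
    sex = (rng.random(n) < config.sex_female_prob).astype(int)  # 1 = female
    return pd.DataFrame(
        {
            "sample_id": list(samples),
            "case": case,
            "age": age,
            "sex": sex,
            "liability": liability,
        }
    )


@dataclass
class Cohort:
    """An ascertained case/control cohort with its full generating truth."""

    config: SimulationConfig
    panel: VariantPanel
    truth: TruthRecord
    genotypes: GenotypeMatrix
    phenotype: pd.DataFrame
    microglia: RegionSet
    sumstats_a: SummaryStats
    sumstats_b: SummaryStats


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """End-to-end generation: panel, effects, ascertained cohort, annotation
    and both discovery GWAS, all deterministic in ``config.seed``."""
    panel = build_panel(config)
    truth = assign_effects(config, panel)
    rng = _child_rng(config.seed, 4)
    thresh = norm.ppf(1.0 - config.prevalence)

    need_case, need_ctrl = config.n_cases, config.n_controls
    batch = max(500, int((need_case / config.prevalence) * 0.25))
    kept_dos, kept_case, kept_liab = [], [], []
    n_case = n_ctrl = n_drawn = 0
    while n_case < need_case or n_ctrl < need_ctrl:
        if n_drawn >= _ASCERTAINMENT_CAP:
            raise RuntimeError(
                f"ascertainment cap reached ({_ASCERTAINMENT_CAP} draws) with "
                f"{n_case}/{need_case} cases, {n_ctrl}/{need_ctrl} controls"
            )
        dos = _draw_dosages(panel, config, batch, rng)
        g = genetic_liability(dos, panel, truth)
        liab = g + rng.normal(0.0, truth.env_sd, size=batch)
        case = liab > thresh
        n_drawn += batch
        take = np.zeros(batch, dtype=bool)
        idx_case = np.flatnonzero(case)[: max(0, need_case - n_case)]
        idx_ctrl = np.flatnonzero(~case)[: max(0, need_ctrl - n_ctrl)]
        take[idx_case] = True
        take[idx_ctrl] = True
        kept_dos.append(dos[take])
        kept_case.append(case[take].astype(int))
        kept_liab.append(liab[take])
        n_case += len(idx_case)
        n_ctrl += len(idx_ctrl)
    dosage = np.vstack(kept_dos)
    case = np.concatenate(kept_case)
    liab = np.concatenate(kept_liab)
    samples = [f"S{i}" for i in range(len(case))]
    genotypes = GenotypeMatrix(samples=samples, variants=list(panel.variants), dosage=dosage)
    pheno = _with_covariates(samples, case, liab, config, rng)
    truth.liability = liab
    micro = annotate_microglia(panel, config)
    ss_a = simulate_gwas(truth, config, "A", panel)
    ss_b = simulate_gwas(truth, config, "B", panel)
    return Cohort(
        config=config,
        panel=panel,
        truth=truth,
        genotypes=genotypes,
        phenotype=pheno,
        microglia=micro,
        sumstats_a=ss_a,
        sumstats_b=ss_b,
    )


def simulate_gwas(
    truth: TruthRecord,
    config: SimulationConfig,
    trait: str,
    panel: VariantPanel | None = None,
) -> SummaryStats:
    """Discovery summary statistics for trait ``A`` or ``B``.

    The per-allele marginal truth is the standardized marginal effect divided
    by the genotype SD; reported beta-hat adds Normal(0, SE^2) noise with
    SE = 1/sqrt(2 p (1-p) n_gwas) (standardized-trait approximation). An
    infinite ``n_gwas`` is the noiseless limit. P-values are two-sided Wald.
    """
    panel = panel or build_panel(config)
    if trait not in ("A", "B"):
        raise ValueError(f"trait must be 'A' or 'B', got {trait!r}")
    marg_std = truth.beta_marginal if trait == "A" else truth.beta_marginal_b
    n_gwas = config.n_gwas_a if trait == "A" else config.n_gwas_b
    rng = _child_rng(config.seed, 5 if trait == "A" else 6)
    p = panel.freq
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("allele frequency outside (0,1): SE formula undefined")
    sd = panel.sd
    beta_allele = marg_std / sd
    if np.isinf(n_gwas):
        se = np.full_like(beta_allele, 1e-12)
        beta_hat = beta_allele.copy()
    else:
        se = 1.0 / np.sqrt(2.0 * p * (1.0 - p) * n_gwas)
        beta_hat = beta_allele + rng.normal(0.0, se)
    z = beta_hat / se
    pval = np.clip(2.0 * norm.sf(np.abs(z)), np.nextafter(0, 1), 1.0)
    table = pd.DataFrame(
        {
            "chrom": [v.chrom for v in panel.variants],
            "pos": [v.pos for v in panel.variants],
            "id": [v.id for v in panel.variants],
            "effect_allele": [v.alt for v in panel.variants],
            "other_allele": [v.ref for v in panel.variants],
            "beta": beta_hat,
            "se": se,
            "p": pval,
            "freq": p,
            "n": float(n_gwas) if not np.isinf(n_gwas) else np.nan,
        }
    )
    return SummaryStats(table=table, gwas_id=f"gwas_{trait}")


def annotate_microglia(panel: VariantPanel, config: SimulationConfig) -> RegionSet:
    """Contiguous regions covering ~microglia_fraction of the panel.

    Includes a sub-interval of the APOE-like block that contains tag variants
    but never the two epsilon-defining sites.
    """
    frac = config.microglia_fraction
    if not (0.0 < frac < 1.0):
        raise ValueError(f"microglia_fraction {frac} outside (0,1)")
    rng = _child_rng(config.seed, 7)
    m = config.n_variants
    pos = np.array([v.pos for v in panel.variants[:m]])
    # APOE sub-interval: the tag variants below the epsilon sites
    apoe_sub = ("19", 43_950_000, 44_880_000)
    n_apoe_covered = int(
        sum(
            1
            for j in panel.apoe_tag_idx
            if apoe_sub[1] <= panel.variants[j].pos <= apoe_sub[2]
        )
    )
    target = int(round(frac * panel.n_total)) - n_apoe_covered
    target = max(target, 0)
    run_len = max(4, min(12, target))
    regions = [apoe_sub]
    chosen = np.zeros(m, dtype=bool)
    covered = 0
    attempts = 0
    while covered < target and attempts < 10_000:
        attempts += 1
        length = min(run_len, target - covered) or 1
        start = int(rng.integers(0, m - length))
        if chosen[start : start + length].any():
            continue
        chosen[start : start + length] = True
        regions.append(("1", int(pos[start]), int(pos[start + length - 1])))
        covered += length
    return RegionSet(regions=regions)
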