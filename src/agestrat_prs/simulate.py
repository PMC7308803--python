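"""Synthetic cohort generator.

Produces genotype panels, discovery summary statistics, case-control and
parental-proxy phenotypes, and APOE-linked parental survival with the
statistical structure the downstream analysis assumes:

* LD-blocked biallelic genotypes from a latent-Gaussian (copula) threshold
  model with AR(1) correlation within contiguous blocks and independence
  across blocks;
* the two APOE coding SNPs rs429358/rs7412 attached as phase-consistent
  ε2/ε3/ε4 haplotype draws (worldwide frequencies 8.4% / 77.9% / 13.7%);
* a liability-threshold disease model whose per-ε4-allele effect switches
  at an age cutoff (default 80 years) from ``beta_e4_young`` to
  ``beta_e4_old``, plus an additive polygenic background explaining
  ``h2_poly`` of liability variance;
* Mendelian-consistent parental genotypes (parent-child dosage correlation
  ~0.5) with parental disease status from the same liability model and a
  configurable ε4-dose shift of parental age at death.

All operations are deterministic functions of ``SimulationConfig`` —
identical configs (including seed) give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from agestrat_prs.datatypes import GenotypePanel, SUMSTATS_COLUMNS

# rs429358 (T>C; C on the ε4 haplotype) then rs7412 (C>T; T on the ε2
# haplotype).  GRCh38 coordinates; the build is a config label only.
APOE_SNP_IDS = ("rs429358", "rs7412")
APOE_POSITIONS_GRCH38 = (44_908_684, 44_908_822)
APOE_HAPLOTYPE_FREQS = (0.084, 0.779, 0.137)  # (ε2, ε3, ε4)

# Fixed stream tags so each operation draws from its own substream of the
# config seed, independent of call order.
_TAG_GENO_TARGET = 11
_TAG_GENO_DISCOVERY = 12
_TAG_APOE_TARGET = 21
_TAG_APOE_DISCOVERY = 22
_TAG_ARCH = 31
_TAG_VARIANTS = 32
_TAG_PHENO_TARGET = 41
_TAG_PHENO_DISCOVERY = 42
_TAG_PARENTS = 51


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Liability-scale effects are per allele in residual-SD units.  The
    defaults encode a realistic late-onset dementia setting: lifetime
    prevalence 0.10, a strong ε4 effect below the 80-year cutoff that
    weakens above it, a mildly protective ε2, a polygenic background
    explaining 30% of liability variance, and a one-year earlier parental
    age at death per ε4 allele.
    """

    seed: int = 0
    n_variants: int = 400
    n_blocks: int = 40
    within_block_r: float = 0.7
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_discovery: int = 20_000
    n_target: int = 10_000
    prevalence: float = 0.10
    beta_e4_young: float = 0.5
    beta_e4_old: float = 0.2
    beta_e2: float = -0.15
    n_causal: int = 100
    h2_poly: float = 0.3
    age_distribution: tuple[float, float] = (75.0, 8.0)
    age_cutoff: float = 80.0
    survival_shift_e4: float = -1.0
    proxy: bool = False
    # plumbing / secondary knobs
    apoe_freqs: tuple[float, float, float] = APOE_HAPLOTYPE_FREQS
    apoe_positions: tuple[int, int] = APOE_POSITIONS_GRCH38
    genome_build: str = "GRCh38"
    variant_spacing_bp: int = 5_000
    parent_age_distribution: tuple[float, float] = (78.0, 8.0)
    parent_death_prob: float = 0.6
    sex_effect: float = 0.0
    n_pcs: int = 4

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not 0 <= self.within_block_r < 1:
            raise ValueError("within_block_r must lie in [0, 1)")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.n_causal > self.n_variants:
            raise ValueError("n_causal exceeds n_variants")
        if self.n_variants < self.n_blocks:
            raise ValueError("n_variants must be >= n_blocks")
        if not 0 <= self.h2_poly < 1:
            raise ValueError("h2_poly must lie in [0, 1)")
        f2, f3, f4 = self.apoe_freqs
        if abs(f2 + f3 + f4 - 1) > 1e-9:
            raise ValueError("APOE haplotype frequencies must sum to 1")
        beta_e4 = max(abs(self.beta_e4_young), abs(self.beta_e4_old))
        apoe_var = beta_e4**2 * 2 * f4 * (1 - f4) + self.beta_e2**2 * 2 * f2 * (1 - f2)
        if self.h2_poly + apoe_var >= 1:
            raise ValueError("h2_poly plus APOE liability variance must be < 1")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


def _rng(config: SimulationConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed) % (2**31), tag]))


def _block_ids(n_variants: int, n_blocks: int) -> np.ndarray:
    """Contiguous near-equal blocks, e.g. 10 variants / 3 blocks -> 4,3,3."""
    sizes = np.full(n_blocks, n_variants // n_blocks)
    sizes[: n_variants % n_blocks] += 1
    return np.repeat(np.arange(n_blocks), sizes)


def _phi_correlation(rho: np.ndarray, a: np.ndarray, b: np.ndarray,
                     pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    """Correlation of the threshold indicators 1{Z1<a}, 1{Z2<b} under a
    bivariate normal with latent correlation rho (vectorized quadrature)."""
    rho = np.clip(rho, -0.99999, 0.99999)
    nodes, weights = np.polynomial.legendre.leggauss(80)
    lo = -8.5
    z = lo + (a[:, None] - lo) * (nodes[None, :] + 1) / 2  # (m, nodes) on (-inf, a]
    scale = (a - lo)[:, None] / 2
    inner = stats.norm.cdf((b[:, None] - rho[:, None] * z) / np.sqrt(1 - rho**2)[:, None])
    p11 = np.sum(weights[None, :] * stats.norm.pdf(z) * inner * scale, axis=1)
    return (p11 - pa * pb) / np.sqrt(pa * (1 - pa) * pb * (1 - pb))


def _calibrate_latent_rho(target_r: float, pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    """Latent correlations giving indicator (phi) correlation ~target_r.

    The thresholding attenuates correlation, so the latent value must
    exceed the target; pairs whose margins cannot reach the target even at
    latent correlation ~1 are clamped.  Solved by bisection on the
    monotone map rho -> phi(rho).
    """
    if target_r <= 0:
        return np.zeros(len(pa))
    a, b = stats.norm.ppf(pa), stats.norm.ppf(pb)
    lo = np.zeros(len(pa))
    hi = np.full(len(pa), 0.99995)
    reachable = _phi_correlation(hi, a, b, pa, pb) >= target_r
    for _ in range(35):
        mid = (lo + hi) / 2
        too_low = _phi_correlation(mid, a, b, pa, pb) < target_r
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    mid = (lo + hi) / 2
    return np.where(reachable, mid, 0.99995)


def _adjacent_latent_rho(mafs: np.ndarray, blocks: np.ndarray, r: float) -> np.ndarray:
    """Per-variant latent AR(1) coefficient linking variant j-1 to j
    (0 at block starts), calibrated so genotype correlation ~r."""
    m = len(mafs)
    rho = np.zeros(m)
    if m < 2 or r <= 0:
        return rho
    within = np.flatnonzero((np.arange(m) > 0) & (blocks == np.roll(blocks, 1)))
    if len(within):
        rho[within] = _calibrate_latent_rho(r, mafs[within - 1], mafs[within])
    return rho


def _draw_latent_haplotypes(
    rng: np.random.Generator, n_hap: int, mafs: np.ndarray, blocks: np.ndarray, r: float
) -> np.ndarray:
    """Binary haplotypes from an AR(1) latent Gaussian within each block.

    The per-step latent correlation is calibrated (tetrachoric inversion)
    so that the realized adjacent-variant genotype correlation, not the
    latent one, approximates ``r``.
    """
    m = len(mafs)
    rho = _adjacent_latent_rho(mafs, blocks, r)
    e = rng.standard_normal((n_hap, m))
    z = np.empty((n_hap, m))
    z[:, 0] = e[:, 0]
    for j in range(1, m):
        z[:, j] = rho[j] * z[:, j - 1] + np.sqrt(1 - rho[j] ** 2) * e[:, j]
    thresh = stats.norm.ppf(mafs)
    return (z < thresh[None, :]).astype(np.uint8)


def simulate_genotypes(config: SimulationConfig, *, n_samples: int | None = None,
                       _tag: int = _TAG_GENO_TARGET, _id_prefix: str = "S") -> GenotypePanel:
    """Simulate an LD-blocked biallelic genotype panel.

    Variants sit on chromosome 1 at ``variant_spacing_bp`` intervals,
    partitioned into ``n_blocks`` contiguous blocks.  Within a block the
    latent Gaussian is AR(1) with coefficient ``within_block_r``; blocks are
    independent.  Per-variant allele frequencies are uniform on
    ``maf_range``.  Haplotypes are retained on the panel for Mendelian
    parent simulation.
    """
    n = config.n_target if n_samples is None else n_samples
    # the variant map (frequencies, allele labels) is a function of the seed
    # only, so target and discovery cohorts share it exactly
    rng_map = _rng(config, _TAG_VARIANTS)
    m = config.n_variants
    mafs = rng_map.uniform(config.maf_range[0], config.maf_range[1], m)
    alleles = np.array([["A", "G"], ["C", "T"], ["T", "G"], ["A", "C"]])
    pair = alleles[rng_map.integers(0, len(alleles), m)]
    blocks = _block_ids(m, config.n_blocks)
    # sort frequencies within each block: tightly linked variants have
    # similar frequencies, which keeps the target correlation attainable
    # after thresholding
    for b in range(config.n_blocks):
        sel = blocks == b
        mafs[sel] = np.sort(mafs[sel])
    rng = _rng(config, _tag)
    haps = _draw_latent_haplotypes(rng, 2 * n, mafs, blocks, config.within_block_r)
    haps = haps.reshape(n, 2, m)
    dosages = haps.sum(axis=1).astype(float)
    variants = pd.DataFrame(
        {
            "id": [f"snp{j + 1:05d}" for j in range(m)],
            "chrom": "1",
            "pos": 1 + np.arange(m) * config.variant_spacing_bp,
            "effect_allele": pair[:, 0],
            "other_allele": pair[:, 1],
            "info": 1.0,
        }
    )
    return GenotypePanel(
        sample_ids=np.array([f"{_id_prefix}{i + 1:06d}" for i in range(n)]),
        variants=variants,
        dosages=dosages,
        haplotypes=haps,
        sim_info={
            "maf": mafs,
            "block": blocks,
            "latent_r": config.within_block_r,
        },
    )


def _draw_apoe_haplotypes(rng: np.random.Generator, n_hap: int,
                          freqs: tuple[float, float, float]) -> np.ndarray:
    """(n_hap, 2) allele matrix for (rs429358, rs7412); 1 = effect allele.

    Effect alleles are rs429358-C (ε4-defining) and rs7412-T (ε2-defining):
    ε2 = (T, T) -> (0, 1); ε3 = (T, C) -> (0, 0); ε4 = (C, C) -> (1, 0).
    """
    eps = rng.choice(3, size=n_hap, p=list(freqs))  # 0=ε2, 1=ε3, 2=ε4
    out = np.zeros((n_hap, 2), dtype=np.uint8)
    out[eps == 2, 0] = 1  # rs429358-C on ε4
    out[eps == 0, 1] = 1  # rs7412-T on ε2
    return out


def attach_apoe(panel: GenotypePanel, config: SimulationConfig,
                *, _tag: int = _TAG_APOE_TARGET) -> GenotypePanel:
    """Append rs429358 and rs7412 as phase-consistent ε-haplotype draws."""
    existing = set(panel.variants["id"])
    if existing & set(APOE_SNP_IDS):
        raise ValueError("panel already carries APOE variants")
    rng = _rng(config, _tag)
    n = panel.n_samples
    hap_alleles = _draw_apoe_haplotypes(rng, 2 * n, config.apoe_freqs)
    hap_alleles = hap_alleles.reshape(n, 2, 2)  # (sample, haplotype, snp)
    new_vars = pd.DataFrame(
        {
            "id": list(APOE_SNP_IDS),
            "chrom": "19",
            "pos": list(config.apoe_positions),
            "effect_allele": ["C", "T"],
            "other_allele": ["T", "C"],
            "info": 1.0,
        }
    )
    variants = pd.concat([panel.variants, new_vars], ignore_index=True)
    dosages = np.hstack([panel.dosages, hap_alleles.sum(axis=1).astype(float)])
    haplotypes = None
    if panel.haplotypes is not None:
        haplotypes = np.concatenate([panel.haplotypes, hap_alleles], axis=2)
    missing = panel.missing
    if missing is not None:
        missing = np.hstack([missing, np.zeros((n, 2), dtype=bool)])
    sim_info = dict(panel.sim_info)
    m0 = panel.n_variants
    sim_info["apoe_cols"] = (m0, m0 + 1)
    sim_info["apoe_freqs"] = tuple(config.apoe_freqs)
    # extend per-variant bookkeeping over the two new columns (effect-allele
    # frequencies ε4 and ε2; their own LD block — phase comes from the
    # ε-haplotype draw, not the copula)
    if "maf" in sim_info:
        f2, _, f4 = config.apoe_freqs
        sim_info["maf"] = np.concatenate([np.asarray(sim_info["maf"]), [f4, f2]])
    if "block" in sim_info:
        blocks = np.asarray(sim_info["block"])
        nxt = blocks.max() + 1 if blocks.size else 0
        sim_info["block"] = np.concatenate([blocks, [nxt, nxt]])
    return GenotypePanel(
        sample_ids=panel.sample_ids,
        variants=variants,
        dosages=dosages,
        missing=missing,
        haplotypes=haplotypes,
        sim_info=sim_info,
    )


def draw_architecture(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Causal variant indices (among the simulated, non-APOE variants) and
    their liability-scale effects.  Shared by target and discovery cohorts
    so that discovery weights are informative for the target phenotype."""
    rng = _rng(config, _TAG_ARCH)
    causal = np.sort(rng.choice(config.n_variants, size=config.n_causal, replace=False))
    betas = rng.standard_normal(config.n_causal)
    return causal, betas


def _apoe_doses_from_panel(panel: GenotypePanel) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample ε4 and ε2 allele doses from the two APOE SNP hard calls."""
    cols = panel.sim_info.get("apoe_cols")
    if cols is None:
        idx = panel.variants.set_index("id")
        try:
            cols = (idx.index.get_loc(APOE_SNP_IDS[0]), idx.index.get_loc(APOE_SNP_IDS[1]))
        except KeyError as exc:
            raise ValueError("panel lacks APOE variants rs429358/rs7412") from exc
    g429358 = np.rint(panel.dosages[:, cols[0]])  # count of C (ε4-defining)
    g7412 = np.rint(panel.dosages[:, cols[1]])  # count of T (ε2-defining)
    return g429358, g7412


def simulate_phenotype(panel: GenotypePanel, config: SimulationConfig,
                       *, ages: np.ndarray | None = None,
                       _tag: int = _TAG_PHENO_TARGET) -> pd.DataFrame:
    """Liability-threshold disease status with an age-dependent APOE effect.

    Liability is ``sqrt(h2_poly) * P + b_e4(age) * dose_e4 + b_e2 * dose_e2
    + eps`` where ``P`` is the standardized weighted sum of causal
    standardized dosages, ``eps ~ N(0, 1 - h2_poly)``, and ``b_e4(age)``
    steps from ``beta_e4_young`` to ``beta_e4_old`` at ``age_cutoff``.
    Status is 1 where liability exceeds the empirical (1 - prevalence)
    quantile, so the realized case fraction matches the configured
    prevalence up to rounding.
    """
    rng = _rng(config, _tag)
    n = panel.n_samples
    e4_dose, e2_dose = _apoe_doses_from_panel(panel)

    causal, betas = draw_architecture(config)
    G = panel.dosages[:, causal]
    freq = G.mean(axis=0) / 2.0
    sd = np.sqrt(np.maximum(2 * freq * (1 - freq), 1e-12))
    poly = (G - 2 * freq) / sd @ betas
    poly_sd = poly.std()
    if poly_sd > 0 and config.h2_poly > 0:
        poly = poly / poly_sd * np.sqrt(config.h2_poly)
    else:
        poly = np.zeros(n)

    if ages is None:
        ages = rng.normal(config.age_distribution[0], config.age_distribution[1], n)
    else:
        ages = np.asarray(ages, dtype=float)
        rng.normal(size=n)  # keep the stream aligned whether or not ages are supplied
    b_e4 = np.where(ages < config.age_cutoff, config.beta_e4_young, config.beta_e4_old)
    sex = rng.integers(0, 2, n)
    eps = rng.normal(0.0, np.sqrt(1 - config.h2_poly), n)
    liability = poly + b_e4 * e4_dose + config.beta_e2 * e2_dose + config.sex_effect * sex + eps
    threshold = np.quantile(liability, 1 - config.prevalence)
    status = (liability > threshold).astype(int)

    table = pd.DataFrame(
        {
            "sample_id": panel.sample_ids,
            "status": status,
            "age": ages,
            "sex": sex,
            "liability": liability,
        }
    )
    for k in range(config.n_pcs):
        table[f"pc{k + 1}"] = rng.standard_normal(n)
    return table


def simulate_discovery_sumstats(config: SimulationConfig) -> pd.DataFrame:
    """Marginal per-variant association in an independent discovery cohort.

    A discovery panel of ``n_discovery`` samples is simulated with the same
    variant map and genetic architecture as the target cohort (but
    independent sample draws), the liability phenotype is generated, and
    each variant gets a one-step logistic score test against the
    intercept-only null: ``beta = U/V``, ``se = 1/sqrt(V)``, ``p`` from the
    normal approximation of ``U/sqrt(V)``.  APOE-region variants are
    included.
    """
    if config.n_discovery < 100:
        raise ValueError("n_discovery < 100 gives unstable marginal fits")
    panel = simulate_genotypes(config, n_samples=config.n_discovery,
                               _tag=_TAG_GENO_DISCOVERY, _id_prefix="D")
    panel = attach_apoe(panel, config, _tag=_TAG_APOE_DISCOVERY)
    table = simulate_phenotype(panel, config, _tag=_TAG_PHENO_DISCOVERY)
    y = table["status"].to_numpy(dtype=float)
    ybar = y.mean()
    G = panel.dosages
    Gc = G - G.mean(axis=0)
    U = Gc.T @ (y - ybar)
    V = ybar * (1 - ybar) * (Gc**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(V > 0, U / V, 0.0)
        se = np.where(V > 0, 1 / np.sqrt(V), np.inf)
        z = np.where(V > 0, U / np.sqrt(V), 0.0)
    p = np.clip(2 * stats.norm.sf(np.abs(z)), np.nextafter(0, 1), 1.0)
    out = panel.variants[["id", "chrom", "pos", "effect_allele", "other_allele"]].copy()
    out["beta"] = beta
    out["se"] = se
    out["p"] = p
    return out[SUMSTATS_COLUMNS]


def simulate_parents(panel: GenotypePanel, config: SimulationConfig
                     ) -> tuple[GenotypePanel, GenotypePanel, pd.DataFrame]:
    """Mendelian-consistent parents with proxy phenotypes and survival.

    Each child haplotype is treated as the transmitted haplotype of one
    parent (haplotype 0 paternal, 1 maternal); the non-transmitted parental
    haplotype is drawn fresh from the population copula (ε-haplotype draw
    at the APOE SNPs), giving parent-child dosage correlation ~0.5 per
    variant.  Parental status comes from the same liability model at
    parental ages; parental age at death is the recorded age shifted by
    ``survival_shift_e4`` years per parental ε4 allele.

    Returns (father_panel, mother_panel, child_table) where the child table
    carries ``father_status / mother_status / parent_count`` (0/1/2),
    per-parent recorded ages and is-death-age flags, alongside the child's
    own phenotype columns.
    """
    if not config.proxy:
        raise ValueError("simulate_parents requires config.proxy=True")
    if panel.haplotypes is None or "apoe_cols" not in panel.sim_info:
        raise ValueError("panel must carry haplotypes and APOE variants "
                         "(simulate_genotypes + attach_apoe)")
    rng = _rng(config, _TAG_PARENTS)
    n = panel.n_samples
    info = panel.sim_info
    mafs = np.asarray(info["maf"])
    blocks = np.asarray(info["block"])
    r = info["latent_r"]
    apoe_cols = info["apoe_cols"]

    child_table = simulate_phenotype(panel, config)

    panels = []
    parent_cols = {}
    for which, hap_idx, prefix in (("father", 0, "F"), ("mother", 1, "M")):
        transmitted = panel.haplotypes[:, hap_idx, :]
        fresh = _draw_latent_haplotypes(rng, n, mafs, blocks, r)
        fresh[:, list(apoe_cols)] = _draw_apoe_haplotypes(rng, n, config.apoe_freqs)
        haps = np.stack([transmitted, fresh], axis=1)
        parent_panel = GenotypePanel(
            sample_ids=np.array([f"{prefix}{i + 1:06d}" for i in range(n)]),
            variants=panel.variants.copy(),
            dosages=haps.sum(axis=1).astype(float),
            haplotypes=haps,
            sim_info=dict(info),
        )
        mean_age, sd_age = config.parent_age_distribution
        base_age = np.clip(rng.normal(mean_age, sd_age, n), 60.0, None)
        e4_dose, _ = _apoe_doses_from_panel(parent_panel)
        dead = rng.random(n) < config.parent_death_prob
        recorded_age = np.where(dead, base_age + config.survival_shift_e4 * e4_dose, base_age)
        ptab = simulate_phenotype(parent_panel, config, ages=recorded_age,
                                  _tag=_TAG_PARENTS + 100 + hap_idx)
        parent_cols[f"{which}_status"] = ptab["status"].to_numpy()
        parent_cols[f"{which}_age"] = recorded_age
        parent_cols[f"{which}_is_death_age"] = dead
        parent_cols[f"{which}_e4_dose"] = e4_dose
        panels.append(parent_panel)

    for k, v in parent_cols.items():
        child_table[k] = v
    child_table["parent_count"] = child_table["father_status"] + child_table["mother_status"]
    return panels[0], panels[1], child_table
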