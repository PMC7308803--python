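"""Polygenic scoring, APOE diplotype calling and pathway restriction.

The polygenic score of sample *s* is the weighted sum of effect-allele
dosages, ``score_s = sum_j beta_j * dose_s(effect_allele_j)``, over variants
passing the discovery p-value threshold (default p_T <= 0.5) and surviving
region exclusion (by default the APOE region chr19:44.4-46.5 Mb for the
genome-wide score).  Scores are then residualized on covariates (age, sex,
principal components) and standardized to mean 0 / SD 1 over the cohort.

APOE ε2/ε3/ε4 diplotypes are called from the unphased genotypes of
rs429358 (T>C) and rs7412 (C>T): ε2 = (T, T), ε3 = (T, C), ε4 = (C, C).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from agestrat_prs.datatypes import GenotypePanel, validate_sumstats


@dataclass(frozen=True)
class RegionSpec:
    """A genomic interval, 1-based and inclusive at both ends."""

    chrom: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"region start {self.start_bp} > end {self.end_bp}")

    @classmethod
    def parse(cls, text: str) -> "RegionSpec":
        """Parse ``chrom:start-end``, e.g. ``19:44400000-46500000``."""
        chrom, _, span = text.partition(":")
        start, _, end = span.partition("-")
        return cls(chrom.lstrip("chr") or chrom, int(start), int(end))

    def contains(self, chrom, pos) -> np.ndarray:
        chrom = np.asarray(chrom).astype(str)
        pos = np.asarray(pos)
        return (chrom == self.chrom) & (pos >= self.start_bp) & (pos <= self.end_bp)


#: The APOE region used for PRS exclusion (chr19 44.4-46.5 Mb).
APOE_REGION = RegionSpec("19", 44_400_000, 46_500_000)


@dataclass(frozen=True)
class ScoreConfig:
    p_threshold: float = 0.5
    exclude_regions: tuple[RegionSpec, ...] = (APOE_REGION,)
    include_regions: tuple[RegionSpec, ...] | None = None
    missing_policy: str = "mean"  # or "omit" (per-sample renormalization)

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must lie in (0, 1]")
        if self.missing_policy not in ("mean", "omit"):
            raise ValueError("missing_policy must be 'mean' or 'omit'")


# ---------------------------------------------------------------------------
# APOE diplotype calling
# ---------------------------------------------------------------------------

_DIPLOTYPE_TABLE = {
    # (count of rs429358-C, count of rs7412-T) -> (diplotype, e2, e4, ambiguous)
    (0, 0): ("e3/e3", 0, 0, False),
    (1, 0): ("e3/e4", 0, 1, False),
    (2, 0): ("e4/e4", 0, 2, False),
    (0, 1): ("e2/e3", 1, 0, False),
    (0, 2): ("e2/e2", 2, 0, False),
    # ε2ε4 and ε1ε3 are the same unphased genotype; ε1 is vanishingly rare
    (1, 1): ("e2/e4", 1, 1, True),
}

_EXPECTED_ALLELES = {"rs429358": ("T", "C"), "rs7412": ("C", "T")}


@dataclass(frozen=True)
class ApoeCall:
    """An APOE diplotype with ε2/ε4 allele doses.

    ``diplotype`` is one of e2/e2 ... e4/e4, "ambiguous" for genotype
    combinations not representable with ε2/ε3/ε4 haplotypes alone (they
    imply the vanishingly rare ε1), or None for a missing call.
    ``ambiguous`` is also set for the phase-ambiguous ε2ε4 genotype.
    """

    diplotype: str | None
    e2_dose: int | None
    e4_dose: int | None
    ambiguous: bool = False


def _allele_count(genotype, snp: str) -> int | None:
    """Count of the ε-defining allele (rs429358-C / rs7412-T)."""
    if genotype is None or (isinstance(genotype, float) and np.isnan(genotype)):
        return None
    if isinstance(genotype, (int, np.integer)) or (
        isinstance(genotype, float) and float(genotype).is_integer()
    ):
        g = int(genotype)
        if g not in (0, 1, 2):
            raise ValueError(f"{snp}: allele count {g} outside 0..2")
        return g
    ref, alt = _EXPECTED_ALLELES[snp]
    alleles = [a for a in str(genotype).upper() if a.isalpha()]
    if len(alleles) != 2 or any(a not in (ref, alt) for a in alleles):
        raise ValueError(f"{snp}: genotype {genotype!r} not on alleles {ref}/{alt}")
    return sum(a == alt for a in alleles)


def call_apoe(g_rs429358, g_rs7412) -> ApoeCall:
    """Map the unphased rs429358/rs7412 genotype pair to an APOE diplotype.

    Genotypes may be allele-count dosages (0/1/2 copies of rs429358-C and
    rs7412-T respectively) or two-letter strings such as ``"CT"``.  The
    (C/T, C/T) double heterozygote is returned as ε2/ε4 with the ambiguity
    flag set (the alternative ε1ε3 phase is vanishingly rare).  Any missing
    genotype yields a missing call.
    """
    a = _allele_count(g_rs429358, "rs429358")
    b = _allele_count(g_rs7412, "rs7412")
    if a is None or b is None:
        return ApoeCall(None, None, None)
    entry = _DIPLOTYPE_TABLE.get((a, b))
    if entry is None:
        # e.g. rs429358 CC with rs7412 CT: needs an ε1 = (C, T) haplotype
        return ApoeCall("ambiguous", b, a, True)
    diplotype, e2, e4, amb = entry
    return ApoeCall(diplotype, e2, e4, amb)


def call_apoe_panel(panel: GenotypePanel) -> pd.DataFrame:
    """Per-sample APOE calls from a panel carrying rs429358 and rs7412."""
    idx = panel.variant_index(["rs429358", "rs7412"])
    for col, snp in zip(idx, ("rs429358", "rs7412")):
        row = panel.variants.iloc[col]
        ref, alt = _EXPECTED_ALLELES[snp]
        if {row["effect_allele"], row["other_allele"]} != {ref, alt}:
            raise ValueError(
                f"{snp}: panel alleles {row['effect_allele']}/{row['other_allele']}"
                f" do not match expected {ref}/{alt}"
            )
    g = panel.hard_calls()[:, idx]
    # panel dosages count the effect allele; reorient to the ε-defining allele
    for k, (col, snp) in enumerate(zip(idx, ("rs429358", "rs7412"))):
        if panel.variants.iloc[col]["effect_allele"] != _EXPECTED_ALLELES[snp][1]:
            g[:, k] = 2 - g[:, k]
    calls = [call_apoe(a if not np.isnan(a) else None, b if not np.isnan(b) else None)
             for a, b in g]
    return pd.DataFrame(
        {
            "sample_id": panel.sample_ids,
            "diplotype": [c.diplotype for c in calls],
            "e2_dose": [c.e2_dose for c in calls],
            "e4_dose": [c.e4_dose for c in calls],
            "ambiguous": [c.ambiguous for c in calls],
        }
    )


# ---------------------------------------------------------------------------
# Polygenic scores
# ---------------------------------------------------------------------------

def compute_prs(panel: GenotypePanel, sumstats: pd.DataFrame, retained,
                config: ScoreConfig | None = None) -> pd.DataFrame:
    """Raw polygenic scores over the retained variants.

    Applies the p-value threshold and region include/exclude filters,
    reconciles allele orientation (a panel counting the discovery "other"
    allele contributes ``2 - dose``), and handles missing dosages by
    cohort-mean substitution (default) or per-sample renormalization.
    Variants whose alleles match neither discovery allele pair are dropped
    with a warning and counted in ``result.attrs['n_dropped_mismatch']``.
    """
    config = config or ScoreConfig()
    validate_sumstats(sumstats)
    retained = list(retained)
    panel_ids = set(panel.variants["id"])
    ss_ids = set(sumstats["id"])
    unknown = [v for v in retained if v not in panel_ids or v not in ss_ids]
    if unknown:
        raise ValueError(f"retained variants absent from panel or sumstats: {unknown[:5]}")

    ss = sumstats.set_index("id").loc[retained]
    keep = ss["p"].to_numpy() <= config.p_threshold
    cols = panel.variant_index(retained)
    chrom = panel.variants["chrom"].to_numpy()[cols]
    pos = panel.variants["pos"].to_numpy()[cols]
    for region in config.exclude_regions:
        keep &= ~region.contains(chrom, pos)
    if config.include_regions is not None:
        inside = np.zeros(len(cols), dtype=bool)
        for region in config.include_regions:
            inside |= region.contains(chrom, pos)
        keep &= inside

    n_dropped = 0
    use_cols, betas, flip = [], [], []
    pv = panel.variants
    for k in np.flatnonzero(keep):
        col = cols[k]
        ea_p, oa_p = pv["effect_allele"].iloc[col], pv["other_allele"].iloc[col]
        ea_s, oa_s = ss["effect_allele"].iloc[k], ss["other_allele"].iloc[k]
        if (ea_p, oa_p) == (ea_s, oa_s):
            flip.append(False)
        elif (ea_p, oa_p) == (oa_s, ea_s):
            flip.append(True)
        else:
            n_dropped += 1
            continue
        use_cols.append(col)
        betas.append(ss["beta"].iloc[k])
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} variants with unresolvable allele mismatch",
                      stacklevel=2)

    n = panel.n_samples
    if not use_cols:
        result = pd.DataFrame({"sample_id": panel.sample_ids,
                               "raw_score": np.zeros(n), "n_variants_used": 0})
    else:
        D = panel.dosages[:, use_cols].copy()
        miss = None
        if panel.missing is not None:
            miss = panel.missing[:, use_cols]
            D[miss] = np.nan
        D[:, np.array(flip)] = 2 - D[:, np.array(flip)]
        betas = np.asarray(betas, dtype=float)
        if miss is not None and miss.any():
            if config.missing_policy == "mean":
                col_mean = np.nanmean(D, axis=0)
                inds = np.where(np.isnan(D))
                D[inds] = np.take(col_mean, inds[1])
                raw = D @ betas
            else:  # omit: renormalize each sample by its non-missing count
                m_used = (~np.isnan(D)).sum(axis=1)
                raw = np.nansum(D * betas, axis=1)
                scale = np.where(m_used > 0, len(use_cols) / np.maximum(m_used, 1), 0.0)
                raw = raw * scale
        else:
            raw = D @ betas
        result = pd.DataFrame({"sample_id": panel.sample_ids, "raw_score": raw,
                               "n_variants_used": len(use_cols)})
    result.attrs.update(
        p_threshold=config.p_threshold,
        exclude_regions=[f"{r.chrom}:{r.start_bp}-{r.end_bp}" for r in config.exclude_regions],
        missing_policy=config.missing_policy,
        n_dropped_mismatch=n_dropped,
    )
    return result


def adjust_and_standardize(raw_scores: pd.DataFrame, covariates: pd.DataFrame,
                           covariate_cols: list[str] | None = None) -> pd.DataFrame:
    """Residualize raw scores on covariates (OLS with intercept), then
    standardize the residuals to mean 0 / SD 1 over the cohort.

    With an empty covariate list this reduces to the z-score of the raw
    score.  Rank-deficient designs raise an error naming the collinear
    columns; a (near-)zero residual SD — the score is an exact linear
    function of the covariates — is flagged via a warning and
    ``result.attrs['degenerate_sd']``.
    """
    covariate_cols = list(covariate_cols or [])
    merged = raw_scores.merge(covariates, on="sample_id", how="inner", validate="1:1")
    if len(merged) != len(raw_scores):
        raise ValueError("covariate table does not cover all scored samples")
    y = merged["raw_score"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(merged))]
                        + [merged[c].to_numpy(dtype=float) for c in covariate_cols])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = []
        base = X[:, :1]
        for k, name in enumerate(covariate_cols):
            cand = np.column_stack([base, X[:, k + 1]])
            if np.linalg.matrix_rank(cand) == base.shape[1]:
                bad.append(name)
            else:
                base = cand
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    adjusted = y - X @ coef
    sd = adjusted.std()
    degenerate = sd < 1e-10
    if degenerate:
        warnings.warn("residual SD below tolerance; standardized scores set to 0",
                      stacklevel=2)
        standardized = np.zeros_like(adjusted)
    else:
        standardized = (adjusted - adjusted.mean()) / sd
    out = pd.DataFrame(
        {
            "sample_id": merged["sample_id"],
            "raw_score": y,
            "adjusted_score": adjusted,
            "standardized_score": standardized,
            "n_variants_used": merged["n_variants_used"],
        }
    )
    out.attrs.update(raw_scores.attrs)
    out.attrs["covariates"] = covariate_cols
    out.attrs["degenerate_sd"] = bool(degenerate)
    return out


# ---------------------------------------------------------------------------
# Pathway (gene-set) restriction
# ---------------------------------------------------------------------------

@dataclass
class GeneSet:
    """A named gene set resolved to genomic intervals (1-based inclusive)."""

    name: str
    genes: list[str]
    intervals: list[tuple[str, int, int]]
    unresolved: list[str] = field(default_factory=list)

    def include_regions(self) -> tuple[RegionSpec, ...]:
        return tuple(RegionSpec(c, s, e) for c, s, e in self.intervals)


def resolve_gene_set(name: str, genes, gene_intervals: pd.DataFrame) -> GeneSet:
    """Resolve gene symbols to intervals from a gene-interval table.

    ``gene_intervals`` must have columns ``chrom, start, end, gene`` with
    1-based inclusive coordinates (see :func:`agestrat_prs.io.read_bed`).
    Genes missing from the table are reported in ``unresolved``, not
    silently dropped; duplicate gene rows contribute the union of their
    intervals.
    """
    genes = list(genes)
    required = {"chrom", "start", "end", "gene"}
    if not required.issubset(gene_intervals.columns):
        raise ValueError(f"gene interval table must have columns {sorted(required)}")
    by_gene = gene_intervals.groupby("gene")
    intervals, unresolved = [], []
    for g in genes:
        if g in by_gene.groups:
            for _, row in by_gene.get_group(g).iterrows():
                intervals.append((str(row["chrom"]), int(row["start"]), int(row["end"])))
        else:
            unresolved.append(g)
    if not intervals:
        raise ValueError(f"gene set {name!r}: no genes resolved to intervals")
    return GeneSet(name=name, genes=genes, intervals=intervals, unresolved=unresolved)


def pathway_variants(gene_set: GeneSet, panel: GenotypePanel) -> list[str]:
    """Variant ids falling inside any of the gene set's intervals
    (1-based, inclusive at both boundaries)."""
    chrom = panel.variants["chrom"].to_numpy().astype(str)
    pos = panel.variants["pos"].to_numpy()
    inside = np.zeros(panel.n_variants, dtype=bool)
    for c, s, e in gene_set.intervals:
        inside |= (chrom == c) & (pos >= s) & (pos <= e)
    return panel.variants["id"].to_numpy()[inside].tolist()
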