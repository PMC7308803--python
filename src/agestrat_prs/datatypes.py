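"""Core in-memory containers.

Tabular objects (summary statistics, sample tables, score results) are plain
pandas DataFrames with documented column contracts — the convention of
statsmodels/scanpy-style analysis packages.  The genotype panel carries a
dense dosage matrix plus variant metadata and therefore gets a dataclass.

Column contracts
----------------
SummaryStats (DataFrame): ``id, chrom, pos, effect_allele, other_allele,
    beta, se, p``.  ``p`` in (0, 1], ``se`` > 0, ids unique.
SampleTable (DataFrame): ``sample_id, age, sex`` plus either ``status``
    (0/1 case-control) or the proxy block ``father_status, mother_status,
    parent_count, father_age, mother_age, father_is_death_age,
    mother_is_death_age`` and any number of numeric covariate columns
    (``pc1`` ... by convention).
ScoreResult (DataFrame): ``sample_id, raw_score, adjusted_score,
    standardized_score, n_variants_used``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SUMSTATS_COLUMNS = ["id", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "p"]
VARIANT_COLUMNS = ["id", "chrom", "pos", "effect_allele", "other_allele"]


@dataclass
class GenotypePanel:
    """Samples x biallelic variants, dosage-valued.

    Parameters
    ----------
    sample_ids
        Length-``n`` array of unique sample identifiers.
    variants
        DataFrame with columns ``id, chrom, pos, effect_allele,
        other_allele`` and optionally ``info`` (imputation quality in
        [0, 1]; defaults to 1.0 for simulated / hard-called data).
        Positions are 1-based and strictly increasing within a chromosome.
    dosages
        ``(n_samples, n_variants)`` float array of effect-allele dosages in
        [0, 2] where not missing.
    missing
        Optional boolean mask of the same shape; True marks a missing call.
    haplotypes
        Optional ``(n_samples, 2, n_variants)`` uint8 phased allele matrix
        (1 = effect allele).  Populated by the simulator; required for
        Mendelian parent simulation, ignored by all analysis code.
    sim_info
        Simulator bookkeeping (per-variant allele frequency, LD block ids,
        APOE column indices) used only by :mod:`agestrat_prs.simulate`.
    """

    sample_ids: np.ndarray
    variants: pd.DataFrame
    dosages: np.ndarray
    missing: np.ndarray | None = None
    haplotypes: np.ndarray | None = None
    sim_info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        if "info" not in self.variants.columns:
            self.variants = self.variants.assign(info=1.0)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        v = self.variants
        missing_cols = [c for c in VARIANT_COLUMNS if c not in v.columns]
        if missing_cols:
            raise ValueError(f"variant table missing columns: {missing_cols}")
        if v["id"].duplicated().any():
            dups = v.loc[v["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate variant ids: {dups[:5]}")
        if (v["effect_allele"] == v["other_allele"]).any():
            raise ValueError("variant with identical effect/other allele")
        for chrom, grp in v.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on chrom {chrom}")
        obs = self.dosages if self.missing is None else self.dosages[~self.missing]
        if obs.size and (np.nanmin(obs) < -1e-9 or np.nanmax(obs) > 2 + 1e-9):
            raise ValueError("non-missing dosages outside [0, 2]")

    # -- conveniences -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, ids) -> np.ndarray:
        """Column indices of the given variant ids (order preserved)."""
        lookup = pd.Series(np.arange(self.n_variants), index=self.variants["id"])
        ids = pd.Index(ids)
        unknown = ids.difference(lookup.index)
        if len(unknown):
            raise KeyError(f"unknown variant ids: {list(unknown[:5])}")
        return lookup[ids].to_numpy()

    def subset_variants(self, mask_or_ids) -> "GenotypePanel":
        """New panel restricted to a boolean variant mask or an id list."""
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            idx = self.variant_index(mask_or_ids)
        variants = self.variants.iloc[idx].reset_index(drop=True)
        sim_info = dict(self.sim_info)
        for key in ("maf", "block"):
            if key in sim_info:
                sim_info[key] = np.asarray(sim_info[key])[idx]
        if "apoe_cols" in sim_info:
            old = list(sim_info["apoe_cols"])
            new = [int(np.flatnonzero(idx == c)[0]) if c in idx else None for c in old]
            sim_info["apoe_cols"] = tuple(new) if None not in new else None
            if sim_info["apoe_cols"] is None:
                del sim_info["apoe_cols"]
        return GenotypePanel(
            sample_ids=self.sample_ids,
            variants=variants,
            dosages=self.dosages[:, idx],
            missing=None if self.missing is None else self.missing[:, idx],
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, :, idx],
            sim_info=sim_info,
        )

    def hard_calls(self) -> np.ndarray:
        """Dosages rounded to the nearest genotype; missing as NaN."""
        g = np.rint(self.dosages)
        if self.missing is not None:
            g = np.where(self.missing, np.nan, g)
        return g

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GenotypePanel({self.n_samples} samples x {self.n_variants} variants)"


def validate_sumstats(df: pd.DataFrame) -> pd.DataFrame:
    """Check the SummaryStats column contract and value domains."""
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary statistics missing columns: {missing}")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate variant ids in summary statistics: {dups[:5]}")
    if ((df["p"] <= 0) | (df["p"] > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if (df["se"] <= 0).any():
        raise ValueError("standard errors must be positive")
    return df
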