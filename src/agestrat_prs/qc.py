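"""Variant-level quality control.

Filters and threshold senses follow the conventions of array/imputed GWAS
QC: minor-allele frequency *less than* the minimum fails, missingness
*greater than* the maximum fails, Hardy-Weinberg exact p *at or below* the
minimum fails, and (imputed profile only) INFO *at or below* the minimum
fails.  Dosages are converted to hard calls first; a dosage too far from an
integer genotype (implied posterior at or below ``hardcall_posterior_min``)
becomes a missing call.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from agestrat_prs.datatypes import GenotypePanel

# above this many diploid samples the exact-integer HWE path switches to
# log-gamma floating arithmetic (the integer path is exact but O(n) big-int)
_HWE_EXACT_MAX_N = 5_000


@dataclass(frozen=True)
class QCConfig:
    """Thresholds for variant QC.

    ``missing_max`` differs by dataset profile: 0.02 for directly genotyped
    ("array") data, 0.05 for imputed data; the INFO and hard-call posterior
    filters apply only to the imputed profile.
    """

    maf_min: float = 0.01
    missing_max: float = 0.02
    hwe_p_min: float = 1e-6
    info_min: float | None = None
    hardcall_posterior_min: float | None = None
    hwe_controls_only: bool = False

    @classmethod
    def array(cls, **kwargs) -> "QCConfig":
        return cls(missing_max=kwargs.pop("missing_max", 0.02), **kwargs)

    @classmethod
    def imputed(cls, **kwargs) -> "QCConfig":
        kwargs.setdefault("missing_max", 0.05)
        kwargs.setdefault("info_min", 0.4)
        kwargs.setdefault("hardcall_posterior_min", 0.4)
        return cls(**kwargs)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact test of Hardy-Weinberg proportions.

    Conditional on the observed allele counts, sums the probabilities of
    every heterozygote count whose probability does not exceed that of the
    observed count (the standard exact HWE test, no mid-p correction).
    Monomorphic tables return 1.

    For tables up to ``_HWE_EXACT_MAX_N`` diploids the distribution is
    computed in exact integer arithmetic (the returned float is the
    correctly rounded rational); larger tables use log-gamma floating
    arithmetic with a relative tie tolerance.
    """
    counts = (n_AA, n_Aa, n_aa)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative genotype count in {counts}")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("empty genotype table")
    n_a = n_Aa + 2 * n_aa  # 'a' allele count
    n_minor = min(n_a, 2 * n - n_a)
    if n_minor == 0:
        return 1.0
    if n <= _HWE_EXACT_MAX_N:
        return _hwe_exact_integer(n, n_minor, n_Aa)
    return _hwe_exact_float(n, n_minor, n_Aa)


def _hwe_het_support(n: int, n_minor: int) -> range:
    start = n_minor % 2
    return range(start, min(n_minor, 2 * n - n_minor) + 1, 2)


def hwe_exact_pvalues(n: int, n_minor: int) -> dict[int, float]:
    """Exact two-sided HWE p-values for every possible heterozygote count.

    For ``n`` diploids carrying ``n_minor`` copies of the minor allele,
    returns ``{het_count: p}`` for all counts of the correct parity.
    Computed in exact integer arithmetic — weight(k) proportional to
    ``comb(n, k) * comb(n - k, hom_minor) * 2**k`` — so each returned float
    is the correctly rounded exact rational.
    """
    if n_minor == 0:
        return {0: 1.0}
    ks = list(_hwe_het_support(n, n_minor))
    weights = []
    for k in ks:
        hom_minor = (n_minor - k) // 2
        weights.append(math.comb(n, k) * math.comb(n - k, hom_minor) * pow(2, k))
    total = sum(weights)
    order = sorted(range(len(ks)), key=weights.__getitem__)
    out: dict[int, float] = {}
    cum = 0
    i = 0
    while i < len(order):
        j = i
        tied = 0
        while j < len(order) and weights[order[j]] == weights[order[i]]:
            tied += weights[order[j]]
            j += 1
        cum += tied
        for idx in order[i:j]:
            out[ks[idx]] = min(cum / total, 1.0)
        i = j
    return out


def _hwe_exact_integer(n: int, n_minor: int, het_obs: int) -> float:
    pvals = hwe_exact_pvalues(n, n_minor)
    if het_obs not in pvals:
        raise ValueError(
            f"heterozygote count {het_obs} impossible with {n_minor} minor alleles in {n} diploids"
        )
    return pvals[het_obs]


def _hwe_exact_float(n: int, n_minor: int, het_obs: int) -> float:
    ks = np.array(list(_hwe_het_support(n, n_minor)))
    if het_obs not in set(ks.tolist()):
        raise ValueError(
            f"heterozygote count {het_obs} impossible with {n_minor} minor alleles in {n} diploids"
        )
    hom_minor = (n_minor - ks) // 2
    hom_major = n - ks - hom_minor
    logw = ks * math.log(2) - gammaln(hom_minor + 1) - gammaln(ks + 1) - gammaln(hom_major + 1)
    logw -= logsumexp(logw)
    probs = np.exp(logw)
    p_obs = probs[ks == het_obs][0]
    return float(min(probs[probs <= p_obs * (1 + 1e-12)].sum(), 1.0))


def _effective_calls(panel: GenotypePanel, config: QCConfig) -> np.ndarray:
    """Hard calls with the posterior rule applied; missing as NaN.

    For dosage data without genotype probabilities the implied posterior of
    the nearest integer genotype is taken as ``1 - 2|d - round(d)|`` (1 at
    an integer dosage, 0 at d = x.5); calls with posterior at or below
    ``hardcall_posterior_min`` are set missing.
    """
    g = np.rint(panel.dosages)
    calls = g.copy()
    if panel.missing is not None:
        calls[panel.missing] = np.nan
    if config.hardcall_posterior_min is not None:
        posterior = 1 - 2 * np.abs(panel.dosages - g)
        calls[posterior <= config.hardcall_posterior_min] = np.nan
    return calls


def compute_metrics(panel: GenotypePanel, config: QCConfig | None = None,
                    status: np.ndarray | None = None) -> pd.DataFrame:
    """Per-variant QC metrics: MAF, missingness, HWE exact p, INFO.

    MAF and HWE are computed from hard calls over non-missing samples; HWE
    uses controls only when ``config.hwe_controls_only`` and a status
    vector are provided.  A variant with all calls missing gets NaN MAF and
    is flagged ``all_missing``.
    """
    if panel.n_variants == 0:
        raise ValueError("empty panel")
    config = config or QCConfig()
    calls = _effective_calls(panel, config)
    hwe_calls = calls
    if config.hwe_controls_only and status is not None:
        hwe_calls = calls[np.asarray(status) == 0]

    n = calls.shape[0]
    n_obs = np.sum(~np.isnan(calls), axis=0)
    missingness = 1 - n_obs / n
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        freq = np.nanmean(calls, axis=0) / 2.0
    maf = np.where(n_obs > 0, np.minimum(freq, 1 - freq), np.nan)

    hwe_p = np.ones(panel.n_variants)
    for j in range(panel.n_variants):
        col = hwe_calls[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            hwe_p[j] = np.nan
            continue
        n_aa = int(np.sum(col == 2))
        n_Aa = int(np.sum(col == 1))
        n_AA = int(np.sum(col == 0))
        hwe_p[j] = hwe_exact_test(n_AA, n_Aa, n_aa)

    return pd.DataFrame(
        {
            "variant_id": panel.variants["id"].to_numpy(),
            "maf": maf,
            "missingness": missingness,
            "hwe_p": hwe_p,
            "info": panel.variants["info"].to_numpy(),
            "all_missing": n_obs == 0,
        }
    )


def apply_filters(panel: GenotypePanel, metrics: pd.DataFrame, config: QCConfig
                  ) -> tuple[GenotypePanel, pd.DataFrame]:
    """Remove variants failing any threshold; report per-filter attrition.

    Threshold senses: MAF strictly below ``maf_min`` fails; missingness
    strictly above ``missing_max`` fails; HWE p at or below ``hwe_p_min``
    fails; INFO at or below ``info_min`` fails.  A variant failing several
    filters is counted under each; the report's ``unique_removed`` row
    gives the deduplicated total.
    """
    if len(metrics) != panel.n_variants or not np.array_equal(
        metrics["variant_id"].to_numpy(), panel.variants["id"].to_numpy()
    ):
        raise ValueError("metrics are not aligned to the panel's variants")

    fails = {
        "all_missing": metrics["all_missing"].to_numpy(dtype=bool),
        "maf": (metrics["maf"] < config.maf_min).to_numpy() & ~metrics["maf"].isna().to_numpy(),
        "missingness": (metrics["missingness"] > config.missing_max).to_numpy(),
        "hwe": (metrics["hwe_p"] <= config.hwe_p_min).to_numpy()
        & ~metrics["hwe_p"].isna().to_numpy(),
    }
    thresholds = {
        "all_missing": np.nan,
        "maf": config.maf_min,
        "missingness": config.missing_max,
        "hwe": config.hwe_p_min,
    }
    if config.info_min is not None:
        fails["info"] = (metrics["info"] <= config.info_min).to_numpy()
        thresholds["info"] = config.info_min

    any_fail = np.logical_or.reduce(list(fails.values()))
    rows = [
        {"filter": name, "threshold": thresholds[name], "n_failed": int(mask.sum())}
        for name, mask in fails.items()
    ]
    rows.append({"filter": "unique_removed", "threshold": np.nan, "n_failed": int(any_fail.sum())})
    report = pd.DataFrame(rows)
    return panel.subset_variants(~any_fail), report
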