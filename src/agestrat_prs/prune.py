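"""LD pruning (clumping by smallest discovery p-value).

Variants are visited in ascending discovery-p order; a candidate is kept iff
its dosage r-squared with every already-kept variant on the same chromosome
within the physical window does not exceed ``r2_max``.  This reproduces the
"retain the variant with the smallest p-value from each LD block" behaviour
of distance-window clumping (r² > 0.1, 1000-kb window by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from agestrat_prs.datatypes import GenotypePanel, validate_sumstats


@dataclass(frozen=True)
class PruneConfig:
    """r² threshold, physical window (± bp between positions) and the
    deterministic tie-break for equal p-values (chrom, pos, id order)."""

    r2_max: float = 0.1
    window_bp: int = 1_000_000
    ref_n: int | None = None  # r² from a seeded subsample of this many samples
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.r2_max <= 1:
            raise ValueError("r2_max must lie in (0, 1]")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")


def genotype_r2(panel: GenotypePanel, i: int, j: int) -> float:
    """Squared Pearson correlation of two dosage columns.

    Computed over jointly non-missing samples.  A zero-variance column
    (monomorphic — such variants should not survive QC) yields r² = 0 with
    a warning rather than NaN.
    """
    x = panel.dosages[:, i]
    y = panel.dosages[:, j]
    if panel.missing is not None:
        ok = ~(panel.missing[:, i] | panel.missing[:, j])
        x, y = x[ok], y[ok]
    if len(x) < 2:
        raise ValueError("fewer than 2 jointly non-missing samples")
    vx, vy = x.var(), y.var()
    if vx == 0 or vy == 0:
        warnings.warn("zero-variance dosage column; treating r² as 0", stacklevel=2)
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _normalized_dosages(panel: GenotypePanel, config: PruneConfig) -> np.ndarray:
    """Mean-imputed, centred, unit-norm dosage columns for fast pairwise r²."""
    X = panel.dosages.copy()
    if panel.missing is not None:
        X[panel.missing] = np.nan
    if config.ref_n is not None and config.ref_n < panel.n_samples:
        rng = np.random.default_rng(config.seed)
        rows = rng.choice(panel.n_samples, size=config.ref_n, replace=False)
        X = X[rows]
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    X -= X.mean(axis=0)
    norms = np.linalg.norm(X, axis=0)
    zero = norms == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance dosage columns; treating their r² as 0",
            stacklevel=2,
        )
        norms[zero] = 1.0
    return X / norms


def prune(panel: GenotypePanel, sumstats: pd.DataFrame, config: PruneConfig | None = None
          ) -> list[str]:
    """Greedy-by-p pruning; returns retained variant ids in genomic order.

    Variants absent from the summary statistics are dropped before
    pruning.  Deterministic: p-value ties are broken by (chrom, pos, id).
    """
    config = config or PruneConfig()
    validate_sumstats(sumstats)
    ss = sumstats.set_index("id")
    have = panel.variants["id"].isin(ss.index).to_numpy()
    if not have.any():
        raise ValueError("no overlap between panel variants and summary statistics")
    sub = panel.subset_variants(have)

    X = _normalized_dosages(sub, config)
    v = sub.variants
    p = ss.loc[v["id"], "p"].to_numpy()
    order = np.lexsort((v["id"].to_numpy(), v["pos"].to_numpy(),
                        v["chrom"].to_numpy(), p))

    kept: list[int] = []
    kept_by_chrom: dict[str, list[int]] = {}
    chroms = v["chrom"].to_numpy()
    positions = v["pos"].to_numpy()
    for idx in order:
        ok = True
        for k in kept_by_chrom.get(chroms[idx], []):
            if abs(positions[idx] - positions[k]) <= config.window_bp:
                r = X[:, idx] @ X[:, k]
                if r * r > config.r2_max:
                    ok = False
                    break
        if ok:
            kept.append(idx)
            kept_by_chrom.setdefault(chroms[idx], []).append(idx)

    kept_sorted = sorted(kept)  # panel order is genomic order
    return v["id"].iloc[kept_sorted].tolist()
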