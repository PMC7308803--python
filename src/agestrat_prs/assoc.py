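"""Association models and age-stratified summary tables.

Fits logistic (case-control, per-parent proxy) and Poisson (0/1/2 parental
count) GLMs of disease on APOE allele doses and the standardized polygenic
score, compares nested models with likelihood-ratio tests, computes AUC as
Mann-Whitney concordance of the linear predictor, and emits the
age-stratified (<cutoff / >=cutoff / all) coefficient tables plus the
APOE-homozygote parental-survival descriptive tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

_OUTCOME_COLUMNS = {
    "status": "status",
    "parental_count": "parent_count",
    "maternal": "mother_status",
    "paternal": "father_status",
}

_COUNT_OUTCOMES = {"parental_count"}

_MAX_ABS_BETA = 30.0  # beyond this the fit is treated as separated


@dataclass(frozen=True)
class ModelSpec:
    """Outcome, predictors and GLM family for one association model.

    ``outcome`` is one of ``status`` (child case-control),
    ``parental_count`` (0/1/2 affected parents), ``maternal`` or
    ``paternal`` (per-parent 0/1).  Counts must use the Poisson family,
    binary outcomes the binomial-logit family.
    """

    outcome: str = "status"
    predictors: tuple[str, ...] = ("e4_dose", "e2_dose", "prs")
    family: str = "binomial"  # "binomial" (logit) or "poisson" (log)
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.outcome not in _OUTCOME_COLUMNS:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.family not in ("binomial", "poisson"):
            raise ValueError(f"unknown family {self.family!r}")
        if (self.outcome in _COUNT_OUTCOMES) != (self.family == "poisson"):
            raise ValueError(
                f"family {self.family!r} does not match outcome {self.outcome!r}: "
                "counts need poisson, binary outcomes need binomial"
            )

    @property
    def outcome_column(self) -> str:
        return _OUTCOME_COLUMNS[self.outcome]


@dataclass(frozen=True)
class StratumSpec:
    """Age stratification: which age variable, the cutoff, and labels.

    Age exactly at the cutoff goes to the upper (">=") stratum.
    """

    age_variable: str = "participant_age"  # or "parental_age"
    cutoff_years: float = 80.0
    labels: tuple[str, str, str] = ("all", "<80", ">=80")

    def __post_init__(self) -> None:
        if self.cutoff_years <= 0:
            raise ValueError("cutoff_years must be positive")
        if self.age_variable not in ("participant_age", "parental_age"):
            raise ValueError(f"unknown age variable {self.age_variable!r}")

    @property
    def age_column(self) -> str:
        return "age" if self.age_variable == "participant_age" else "parental_age"


@dataclass
class AssociationResult:
    """One fitted GLM: per-predictor coefficients, fit quality and counts.

    ``coefficients`` has columns ``term, beta, se, p`` (Wald two-sided,
    intercept included).  ``auc`` is Mann-Whitney concordance of the linear
    predictor against the binarized outcome (counts binarized as >=1
    affected parent vs none).
    """

    coefficients: pd.DataFrame
    llf: float
    auc: float
    n_by_outcome: dict = field(default_factory=dict)
    n_dropped: int = 0
    n_params: int = 0
    n_obs: int = 0
    spec: ModelSpec | None = None

    def beta(self, term: str) -> float:
        row = self.coefficients.set_index("term")
        return float(row.loc[term, "beta"])

    def se(self, term: str) -> float:
        row = self.coefficients.set_index("term")
        return float(row.loc[term, "se"])

    def p(self, term: str) -> float:
        row = self.coefficients.set_index("term")
        return float(row.loc[term, "p"])


def mann_whitney_auc(score: np.ndarray, y: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney U of score against binary y."""
    score = np.asarray(score, dtype=float)
    y = np.asarray(y).astype(int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        return np.nan
    ranks = stats.rankdata(score)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def build_analysis_frame(samples: pd.DataFrame, scores: pd.DataFrame | None = None,
                         apoe: pd.DataFrame | None = None) -> pd.DataFrame:
    """Merge the sample table with scores and APOE calls on sample_id.

    The standardized score becomes the ``prs`` column; APOE calls add
    ``e2_dose``/``e4_dose``.  A ``parental_age`` column (mean of available
    parental recorded ages) is derived when parental ages are present.
    """
    frame = samples.copy()
    if scores is not None:
        cols = scores[["sample_id", "standardized_score"]].rename(
            columns={"standardized_score": "prs"}
        )
        frame = frame.merge(cols, on="sample_id", how="inner")
    if apoe is not None:
        frame = frame.merge(
            apoe[["sample_id", "e2_dose", "e4_dose"]], on="sample_id", how="inner"
        )
    if "parental_age" not in frame.columns:
        parent_ages = [c for c in ("father_age", "mother_age") if c in frame.columns]
        if parent_ages:
            frame["parental_age"] = frame[parent_ages].mean(axis=1)
    return frame


def fit_glm(frame: pd.DataFrame, spec: ModelSpec) -> AssociationResult:
    """Maximum-likelihood GLM fit (IRLS) for the given model spec.

    Rows with missing values in modelled columns are dropped and counted.
    Separation (diverging coefficients) and non-convergence raise with
    diagnostics, as does a rank-deficient design or a degenerate outcome
    (no events / no non-events).
    """
    ycol = spec.outcome_column
    cols = [ycol, *spec.predictors, *spec.covariates]
    missing_cols = [c for c in cols if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"analysis frame lacks columns: {missing_cols}")
    data = frame[cols].apply(pd.to_numeric, errors="coerce")
    complete = data.dropna()
    n_dropped = len(data) - len(complete)

    y = complete[ycol].to_numpy(dtype=float)
    if spec.family == "binomial":
        if len(np.unique(y)) < 2:
            raise ValueError(f"degenerate outcome {ycol!r}: all values identical")
    elif y.sum() == 0:
        raise ValueError(f"degenerate count outcome {ycol!r}: zero events")

    xcols = [*spec.predictors, *spec.covariates]
    X = sm.add_constant(complete[xcols].to_numpy(dtype=float), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient design over columns {xcols}")

    family = sm.families.Binomial() if spec.family == "binomial" else sm.families.Poisson()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=family).fit(maxiter=100, tol=1e-8)
    if not res.converged:
        raise RuntimeError(f"GLM did not converge for outcome {ycol!r}")
    if np.any(np.abs(res.params) > _MAX_ABS_BETA):
        raise RuntimeError(
            f"separation suspected for outcome {ycol!r}: |beta| > {_MAX_ABS_BETA}"
        )

    terms = ["const", *xcols]
    coeffs = pd.DataFrame(
        {"term": terms, "beta": res.params, "se": res.bse, "p": res.pvalues}
    )
    linpred = X @ res.params
    y_bin = (y >= 1).astype(int) if spec.family == "poisson" else y.astype(int)
    auc = mann_whitney_auc(linpred, y_bin)
    n_by_outcome = {int(k): int(v) for k, v in zip(*np.unique(y, return_counts=True))}
    return AssociationResult(
        coefficients=coeffs,
        llf=float(res.llf),
        auc=auc,
        n_by_outcome=n_by_outcome,
        n_dropped=n_dropped,
        n_params=X.shape[1],
        n_obs=len(complete),
        spec=spec,
    )


def likelihood_ratio_test(full: AssociationResult, reduced: AssociationResult
                          ) -> tuple[float, int, float]:
    """LRT of nested GLMs: (statistic, df, chi-squared upper-tail p)."""
    if full.spec is not None and reduced.spec is not None:
        full_terms = set(full.spec.predictors) | set(full.spec.covariates)
        red_terms = set(reduced.spec.predictors) | set(reduced.spec.covariates)
        if not red_terms.issubset(full_terms):
            raise ValueError("reduced model's predictors are not a subset of the full model's")
    if full.n_obs != reduced.n_obs:
        raise ValueError("full and reduced models were fit on different rows")
    df = full.n_params - reduced.n_params
    stat = 2 * (full.llf - reduced.llf)
    if stat < -1e-8:
        raise ValueError(
            f"full-model log-likelihood {full.llf:.6g} below reduced {reduced.llf:.6g}: "
            "fit failure"
        )
    stat = max(stat, 0.0)
    if df == 0:
        return stat, 0, 1.0
    return stat, df, float(stats.chi2.sf(stat, df))


_STRATUM_MODELS = {
    "apoe": ("e4_dose", "e2_dose"),
    "prs": ("prs",),
    "joint": ("e4_dose", "e2_dose", "prs"),
}


def _stratum_masks(frame: pd.DataFrame, strata: StratumSpec):
    age = frame[strata.age_column].to_numpy(dtype=float)
    yield strata.labels[0], np.ones(len(frame), dtype=bool)
    yield strata.labels[1], age < strata.cutoff_years
    yield strata.labels[2], age >= strata.cutoff_years


def stratified_table(frame: pd.DataFrame, spec: ModelSpec,
                     strata: StratumSpec | None = None,
                     min_events: int = 10
                     ) -> tuple[pd.DataFrame, dict]:
    """Age-stratified association table (all / <cutoff / >=cutoff).

    Within each stratum three models are fit: APOE doses only, PRS only,
    and joint, plus the LRT of joint vs APOE-only.  Strata with fewer than
    ``min_events`` outcome events are skipped with a warning.  Returns the
    tidy machine-readable table and the underlying fits keyed by
    (stratum, model).
    """
    strata = strata or StratumSpec()
    if strata.age_column not in frame.columns:
        raise ValueError(f"analysis frame lacks age column {strata.age_column!r}")
    rows = []
    fits: dict[tuple[str, str], AssociationResult] = {}
    for label, mask in _stratum_masks(frame, strata):
        sub = frame[mask]
        ycol = spec.outcome_column
        events = int((pd.to_numeric(sub[ycol], errors="coerce") >= 1).sum()) if len(sub) else 0
        if events < min_events:
            warnings.warn(f"stratum {label!r}: {events} events < {min_events}; skipped",
                          stacklevel=2)
            continue
        stratum_fits = {}
        for model_name, predictors in _STRATUM_MODELS.items():
            mspec = ModelSpec(outcome=spec.outcome, predictors=predictors,
                              family=spec.family, covariates=spec.covariates)
            stratum_fits[model_name] = fit_glm(sub, mspec)
        lrt_stat, lrt_df, lrt_p = likelihood_ratio_test(
            stratum_fits["joint"], stratum_fits["apoe"]
        )
        for model_name, fit in stratum_fits.items():
            fits[(label, model_name)] = fit
            for term in _STRATUM_MODELS[model_name]:
                rows.append(
                    {
                        "stratum": label,
                        "model": model_name,
                        "term": term,
                        "beta": fit.beta(term),
                        "se": fit.se(term),
                        "p": fit.p(term),
                        "auc": fit.auc,
                        "llf": fit.llf,
                        "n_obs": fit.n_obs,
                        "n_by_outcome": "/".join(
                            f"{k}:{v}" for k, v in sorted(fit.n_by_outcome.items())
                        ),
                        "lrt_p_joint_vs_apoe": lrt_p,
                        "lrt_stat": lrt_stat,
                        "lrt_df": lrt_df,
                    }
                )
    return pd.DataFrame(rows), fits


def parental_models(frame: pd.DataFrame, covariates: tuple[str, ...] = ()
                    ) -> dict[str, AssociationResult]:
    """The three proxy-phenotype fits: Poisson on the 0/1/2 parental count
    and logistic on maternal and paternal status separately, each using
    the relevant parental age as the age covariate when present."""
    fits = {}
    count_cov = tuple(covariates)
    if "parental_age" in frame.columns and "parental_age" not in count_cov:
        count_cov = count_cov + ("parental_age",)
    fits["parental_count"] = fit_glm(
        frame,
        ModelSpec(outcome="parental_count", predictors=("e4_dose", "e2_dose", "prs"),
                  family="poisson", covariates=count_cov),
    )
    for outcome, age_col in (("maternal", "mother_age"), ("paternal", "father_age")):
        cov = tuple(covariates)
        if age_col in frame.columns and age_col not in cov:
            cov = cov + (age_col,)
        fits[outcome] = fit_glm(
            frame,
            ModelSpec(outcome=outcome, predictors=("e4_dose", "e2_dose", "prs"),
                      family="binomial", covariates=cov),
        )
    return fits


_HOMOZYGOTES = ("e4/e4", "e3/e3", "e2/e2")


def apoe_survival_tables(frame: pd.DataFrame, apoe: pd.DataFrame,
                         cutoff_years: float = 80.0) -> dict[str, pd.DataFrame]:
    """Descriptive parental-age tables for APOE-homozygous participants.

    Restricting to ε4ε4/ε3ε3/ε2ε2 children guarantees each parent carries
    at least one copy of the corresponding allele.  Returns:

    ``ages`` — per homozygote stratum: N children, mean (SD) of mothers'
    and fathers' last recorded age and of age at death (death ages only).

    ``proportions`` — per parent and per age group (<cutoff / >=cutoff of
    that parent's recorded age): the proportion of parents in each
    homozygote stratum (columns sum to 1).
    """
    needed = {"father_age", "mother_age", "father_is_death_age", "mother_is_death_age"}
    missing = needed - set(frame.columns)
    if missing:
        raise ValueError(f"sample table lacks parental-age columns: {sorted(missing)}")
    merged = frame.merge(apoe[["sample_id", "diplotype"]], on="sample_id", how="inner")
    homo = merged[merged["diplotype"].isin(_HOMOZYGOTES)]
    if homo.empty:
        raise ValueError("no APOE-homozygous participants")

    age_rows = []
    for diplo in _HOMOZYGOTES:
        sub = homo[homo["diplotype"] == diplo]
        if sub.empty:
            continue
        row = {"apoe_genotype": diplo, "n": len(sub)}
        for parent, label in (("mother", "mothers"), ("father", "fathers")):
            ages = sub[f"{parent}_age"]
            dead = sub[f"{parent}_is_death_age"].astype(bool)
            row[f"{label}_last_age_mean"] = ages.mean()
            row[f"{label}_last_age_sd"] = ages.std()
            row[f"{label}_death_age_mean"] = ages[dead].mean() if dead.any() else np.nan
            row[f"{label}_death_age_sd"] = ages[dead].std() if dead.any() else np.nan
        age_rows.append(row)
    ages_table = pd.DataFrame(age_rows)

    prop_rows = []
    for diplo in _HOMOZYGOTES:
        sub_mask = homo["diplotype"] == diplo
        row = {"apoe_genotype": diplo}
        for parent in ("father", "mother"):
            age = homo[f"{parent}_age"]
            for group, gmask in (("lt", age < cutoff_years), ("ge", age >= cutoff_years)):
                denom = int(gmask.sum())
                row[f"{parent}_{group}{int(cutoff_years)}"] = (
                    float((sub_mask & gmask).sum() / denom) if denom else np.nan
                )
        prop_rows.append(row)
    proportions = pd.DataFrame(prop_rows)
    return {"ages": ages_table, "proportions": proportions}
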