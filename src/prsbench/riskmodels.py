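"""Case/control risk models over polygenic scores and APOE allele counts.

Five logistic models are benchmarked:

* M1: status ~ APOE epsilon2 count + epsilon4 count
* M2: status ~ PRS restricted to the APOE region
* M3: status ~ whole-genome PRS
* M4: status ~ PRS excluding the APOE region
* M5: status ~ PRS excluding the APOE region + APOE epsilon2/epsilon4 counts

Every predictor (scores and allele counts alike) is first residualized on
age, sex and genotype PCs by ordinary least squares, then z-scored; models
are fit by maximum likelihood with Wald per-coefficient p-values, and
accuracy is summarized as the AUC of the fitted linear predictor (which for a
single-predictor model equals the AUC of the predictor itself).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

MODEL_PREDICTORS = {
    "M1": ["APOE_e2_count", "APOE_e4_count"],
    "M2": ["PRS_APOEonly"],
    "M3": ["PRS_full"],
    "M4": ["PRS_noAPOE"],
    "M5": ["PRS_noAPOE", "APOE_e2_count", "APOE_e4_count"],
}


@dataclass(frozen=True)
class TestGrid:
    """Multiple-testing bookkeeping for the full benchmark grid."""

    __test__ = False  # not a test class, despite the name

    n_models_main: int = 5
    n_sumstats: int = 2
    n_approaches: int = 4
    n_models_e33: int = 1
    n_models_microglia: int = 4
    alpha: float = 0.05

    @property
    def total(self) -> int:
        per = self.n_sumstats * self.n_approaches
        return (self.n_models_main + self.n_models_e33 + self.n_models_microglia) * per


@dataclass
class ModelResult:
    model_id: str
    predictors: list[str]
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    auc: float
    n_cases: int
    n_controls: int
    linear_predictor: np.ndarray | None = None
    significant: bool | None = None
    provenance: dict = field(default_factory=dict)

    def to_rows(self) -> list[dict]:
        rows = []
        for name, b, s, pv in zip(self.predictors, self.beta, self.se, self.p):
            rows.append(
                {
                    "model": self.model_id,
                    "predictor": name,
                    "beta": b,
                    "se": s,
                    "p": pv,
                    "auc": self.auc,
                    "n_cases": self.n_cases,
                    "n_controls": self.n_controls,
                    "significant": self.significant,
                    **self.provenance,
                }
            )
        return rows


class PerfectSeparationError(RuntimeError):
    """The logistic likelihood is unbounded: a predictor separates the classes."""


def adjust_standardize(values: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """OLS-residualize ``values`` on [1, covariates], then z-score (ddof=1)."""
    y = np.asarray(values, dtype=float)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if np.isnan(y).any() or np.isnan(C).any():
        raise ValueError("missing values among predictor or covariates")
    X = np.column_stack([np.ones(len(y)), C])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sd = resid.std(ddof=1)
    if sd <= 1e-12:
        raise ValueError("zero residual variance after covariate adjustment")
    return (resid - resid.mean()) / sd


def logistic_fit(y: np.ndarray, X: np.ndarray, add_intercept: bool = True):
    """Maximum-likelihood logistic regression.

    Returns (beta, se, p) for the non-intercept columns (intercept first in
    the internal fit). Raises PerfectSeparationError when the MLE diverges and
    ValueError on rank deficiency or single-class y.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    design = sm.add_constant(X, has_constant="add") if add_intercept else X
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design matrix")
    with warnings.catch_warnings():
        warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            fit = sm.Logit(y, design).fit(disp=False, maxiter=100, tol=1e-10)
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning) as err:
            raise PerfectSeparationError(str(err)) from err
    if np.abs(fit.params).max() > 1e3:
        raise PerfectSeparationError("|beta| diverged: classes are separable")
    sl = slice(1, None) if add_intercept else slice(None)
    return fit.params[sl], fit.bse[sl], fit.pvalues[sl], fit


def auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Probability a random case outranks a random control (ties count 1/2).

    Computed as the Mann-Whitney rank statistic U / (n1 * n0) with midranks.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required for AUC")
    ranks = rankdata(scores)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def run_models(
    scores: dict,
    apoe_counts: pd.DataFrame | None,
    phenotype: pd.DataFrame,
    covariates: np.ndarray,
    which=("M1", "M2", "M3", "M4", "M5"),
    bonferroni_alpha: float | None = None,
    provenance: dict | None = None,
) -> list[ModelResult]:
    """Fit the requested models on adjusted, standardized predictors.

    ``scores`` maps predictor names (PRS_full, PRS_noAPOE, PRS_APOEonly) to
    per-sample arrays; ``apoe_counts`` must carry APOE_e2_count and
    APOE_e4_count columns when M1/M5 are requested. AUC is computed on the
    fitted linear predictor.
    """
    y = phenotype["case"].to_numpy()
    pool = dict(scores)
    if apoe_counts is not None:
        pool["APOE_e2_count"] = apoe_counts["APOE_e2_count"].to_numpy()
        pool["APOE_e4_count"] = apoe_counts["APOE_e4_count"].to_numpy()
    results = []
    adjusted = {}
    for model_id in which:
        preds = MODEL_PREDICTORS[model_id]
        missing = [p for p in preds if p not in pool]
        if missing:
            raise ValueError(f"{model_id} requires predictor(s) {missing}")
        for p in preds:
            if p not in adjusted:
                adjusted[p] = adjust_standardize(pool[p], covariates)
        X = np.column_stack([adjusted[p] for p in preds])
        beta, se, pvals, fit = logistic_fit(y, X)
        lp = fit.fittedvalues  # linear predictor (X @ beta incl. intercept)
        res = ModelResult(
            model_id=model_id,
            predictors=list(preds),
            beta=np.asarray(beta),
            se=np.asarray(se),
            p=np.asarray(pvals),
            auc=auc(lp, y),
            n_cases=int((y == 1).sum()),
            n_controls=int((y == 0).sum()),
            linear_predictor=np.asarray(lp),
            provenance=dict(provenance or {}),
        )
        if bonferroni_alpha is not None:
            res.significant = bool(np.min(res.p) <= bonferroni_alpha)
        results.append(res)
    return results


def select_pt(results_by_pt: dict, criterion_model: str = "M5") -> float:
    """Pick the pT whose criterion-model AUC is maximal (ties: smallest pT).

    ``results_by_pt`` maps pT -> list[ModelResult] (or a single ModelResult).
    """
    if not results_by_pt:
        raise ValueError("no thresholds evaluated")
    best_pt, best_auc = None, -np.inf
    for pt in sorted(results_by_pt):
        rs = results_by_pt[pt]
        rs = rs if isinstance(rs, (list, tuple)) else [rs]
        cand = [r for r in rs if r.model_id == criterion_model]
        if not cand:
            raise ValueError(f"criterion model {criterion_model} absent at pT={pt}")
        a = cand[0].auc
        if a > best_auc:
            best_pt, best_auc = pt, a
    return best_pt


def bonferroni_threshold(grid: TestGrid) -> float:
    """Per-test alpha = alpha / (total tests enumerated from the grid)."""
    total = grid.total
    if total <= 0:
        raise ValueError("zero tests in grid")
    return grid.alpha / total


def e33_subgroup(
    score_full: np.ndarray,
    calls,
    phenotype: pd.DataFrame,
    covariates: np.ndarray,
    provenance: dict | None = None,
) -> ModelResult:
    """M3 restricted to epsilon3/epsilon3 carriers, with adjustment re-fit
    within the subgroup."""
    from .apoe import e33_mask

    mask = e33_mask(calls)
    sub_pheno = phenotype.loc[mask].reset_index(drop=True)
    y = sub_pheno["case"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("epsilon3/epsilon3 subgroup contains a single class")
    res = run_models(
        scores={"PRS_full": np.asarray(score_full)[mask]},
        apoe_counts=None,
        phenotype=sub_pheno,
        covariates=np.asarray(covariates)[mask],
        which=("M3",),
        provenance=provenance,
    )[0]
    res.provenance["subgroup"] = "e3e3"
    return res


def _pct(numer: int, denom: int) -> float:
    """Percent to one decimal, round-half-up (reproduces printed table cells)."""
    from decimal import ROUND_HALF_UP, Decimal

    return float(
        (Decimal(100 * numer) / Decimal(denom)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


def cohort_table(
    phenotype: pd.DataFrame,
    continuous: dict | None = None,
    categorical: dict | None = None,
    continuous_test: str = "ttest",
) -> pd.DataFrame:
    """Case-vs-control descriptive table.

    Continuous fields: per-group mean (SD) with a two-sample test p (t-test or
    Mann-Whitney U). Categorical fields (boolean arrays): N (%) per group with
    a chi-squared p (no continuity correction); percentages to one decimal,
    rounded half-up.
    """
    y = phenotype["case"].to_numpy().astype(int)
    case, ctrl = y == 1, y == 0
    if case.sum() == 0 or ctrl.sum() == 0:
        raise ValueError("both groups must be non-empty")
    rows = []
    for name, vals in (continuous or {}).items():
        vals = np.asarray(vals, dtype=float)
        if continuous_test == "mannwhitney":
            p = stats.mannwhitneyu(vals[case], vals[ctrl], alternative="two-sided").pvalue
        else:
            p = stats.ttest_ind(vals[case], vals[ctrl], equal_var=False).pvalue
        rows.append(
            {
                "characteristic": name,
                "cases": f"{vals[case].mean():.1f} ({vals[case].std(ddof=1):.1f})",
                "controls": f"{vals[ctrl].mean():.1f} ({vals[ctrl].std(ddof=1):.1f})",
                "p": float(p),
            }
        )
    for name, flags in (categorical or {}).items():
        flags = np.asarray(flags).astype(bool)
        a, b = int(flags[case].sum()), int(flags[ctrl].sum())
        table = np.array(
            [[a, case.sum() - a], [b, ctrl.sum() - b]]
        )
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            p = 1.0
        else:
            p = stats.chi2_contingency(table, correction=False).pvalue
        rows.append(
            {
                "characteristic": name,
                "cases": f"{a} ({_pct(a, int(case.sum()))})",
                "controls": f"{b} ({_pct(b, int(ctrl.sum()))})",
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


def format_percent(numer: int, denom: int) -> float:
    """Public helper: percentage to one decimal, round-half-up."""
    return _pct(numer, denom)
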