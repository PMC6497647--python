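"""Statistical validation: group t-tests, mixed-effects models, LRT comparisons.

Neural scores are validated by (a) Welch two-sample t-tests between expert
and novice groups and (b) linear mixed-effects models predicting concept-
knowledge accuracy (long format over the FBD/SCI/FCI tests) from the run-1
neural score, with crossed random intercepts for subject and test type.
Models are fit by REML for reported estimates and by ML inside likelihood-
ratio comparisons.  Slope p-values use the Wald normal approximation
(approximate for small n; flagged below 30 subjects).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "MixedModelResult",
    "ModelComparisonResult",
    "welch_t",
    "fit_score_model",
    "lrt_compare",
    "scores_to_long",
]


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float, float]:
    """Welch unequal-variance t-test: returns (t, Welch-Satterthwaite df, two-sided p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


@dataclass
class MixedModelResult:
    """Mixed-model slope of a neural score predicting concept knowledge."""

    beta: float
    beta_se: float
    beta_std: float
    p: float
    loglik: float
    n_obs: int
    var_subject: float
    var_test_type: float
    converged: bool
    flags: list[str] = field(default_factory=list)


@dataclass
class ModelComparisonResult:
    chi2: float
    p: float
    df_diff: int


def _check_long(data: pd.DataFrame, predictors: Sequence[str]) -> pd.DataFrame:
    required = {"subject_id", "test_type", "accuracy", *predictors}
    if not required <= set(data.columns):
        raise ValueError(f"long table needs columns {sorted(required)}")
    df = data.dropna(subset=["accuracy", *predictors]).copy()
    if ((df["accuracy"] < 0) | (df["accuracy"] > 1)).any():
        raise ValueError("accuracy values must lie in [0, 1]")
    return df


def _fit_mixed(df: pd.DataFrame, predictors: Sequence[str], reml: bool,
               methods: Sequence[str] = ("lbfgs", "bfgs")):
    """Fit the crossed-random-intercepts model, keeping the best of several
    optimizer runs (guards against spurious local optima in LRT chains)."""
    rhs = " + ".join(predictors) if predictors else "1"
    md = sm.MixedLM.from_formula(
        f"accuracy ~ {rhs}",
        data=df,
        groups=np.ones(len(df)),
        re_formula="0",
        vc_formula={
            "subject": "0 + C(subject_id)",
            "test_type": "0 + C(test_type)",
        },
    )
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        for method in methods:
            try:
                fit = md.fit(reml=reml, method=method, maxiter=1000)
            except Exception:  # singular step in one optimizer is survivable
                continue
            if best is None or fit.llf > best.llf:
                best = fit
    if best is None:
        raise ValueError("mixed-model fit failed under all optimizers")
    return best


def fit_score_model(
    data: pd.DataFrame, score_column: str = "score", reml: bool = True
) -> MixedModelResult:
    """Fit accuracy ~ score with crossed random intercepts (subject, test type).

    ``data`` is long format: one row per (subject, test type) with columns
    ``subject_id``, ``test_type``, ``accuracy`` and the score column; missing
    SCI/FCI rows are simply absent (no imputation).  ``beta_std`` rescales
    the raw slope by sd(score)/sd(accuracy).
    """
    df = _check_long(data, [score_column])
    score_sd = df[score_column].std(ddof=1)
    if not np.isfinite(score_sd) or score_sd == 0:
        raise ValueError("score is constant across subjects; slope inestimable")
    acc_sd = df["accuracy"].std(ddof=1)

    fit = _fit_mixed(df, [score_column], reml=reml)
    beta = float(fit.params[score_column])
    beta_se = float(fit.bse[score_column])
    p = float(fit.pvalues[score_column])
    flags = []
    if not fit.converged:
        flags.append("non_converged")
    if df["subject_id"].nunique() <= 30:
        flags.append("normal_approx_small_n")
    vcomp = dict(zip(fit.model.exog_vc.names, np.asarray(fit.vcomp, dtype=float)))
    return MixedModelResult(
        beta=beta,
        beta_se=beta_se,
        beta_std=float(beta * score_sd / acc_sd) if acc_sd > 0 else float("nan"),
        p=p,
        loglik=float(fit.llf),
        n_obs=int(len(df)),
        var_subject=float(vcomp.get("subject", np.nan)),
        var_test_type=float(vcomp.get("test_type", np.nan)),
        converged=bool(fit.converged),
        flags=flags,
    )


def lrt_compare(
    base_predictors: Sequence[str],
    composite_predictors: Sequence[str],
    data: pd.DataFrame,
) -> ModelComparisonResult:
    """Likelihood-ratio test of a composite mixed model over a nested base.

    Both models are refit by maximum likelihood; the composite adds the
    base's predictors plus (normally) one score column.  Identical specs are
    allowed and return chi2 = 0, p = 1.
    """
    base = list(base_predictors)
    comp = list(composite_predictors)
    if not set(base) <= set(comp):
        raise ValueError("base predictors must be nested in composite")
    df_diff = len(set(comp)) - len(set(base))
    df = _check_long(data, comp)
    if df_diff == 0:
        return ModelComparisonResult(chi2=0.0, p=1.0, df_diff=0)

    fit_base = _fit_mixed(df, base, reml=False)
    fit_comp = _fit_mixed(df, comp, reml=False)
    chi2 = 2.0 * (float(fit_comp.llf) - float(fit_base.llf))
    if chi2 < 0:
        # the composite likelihood dominates the base pointwise (fixed
        # effects are profiled), so a negative statistic is an optimizer
        # artifact: retry the composite with a wider optimizer set
        retry = ("cg", "powell", "nm")
        fit_comp2 = _fit_mixed(df, comp, reml=False, methods=retry)
        if fit_comp2.llf > fit_comp.llf:
            fit_comp = fit_comp2
        chi2 = 2.0 * (float(fit_comp.llf) - float(fit_base.llf))
    if chi2 < -1e-6:
        raise ValueError(f"negative LRT statistic {chi2}; fits inconsistent")
    chi2 = max(chi2, 0.0)
    return ModelComparisonResult(
        chi2=float(chi2),
        p=float(stats.chi2.sf(chi2, df_diff)),
        df_diff=df_diff,
    )


def scores_to_long(
    scores: pd.DataFrame, behavior: pd.DataFrame, run: int = 1
) -> pd.DataFrame:
    """Join run-level scores with behavior into the long validation format.

    ``scores`` has columns subject_id, run_id, method, score (tidy; one row
    per subject-run-method); ``behavior`` is the wide cohort table with
    fbd_acc_run<r>, sci_acc, fci_acc.  Output: one row per (subject,
    test_type, method) with columns subject_id, test_type, accuracy, method,
    score.  Missing inventories and invalid scores yield absent rows.
    """
    fbd_col = f"fbd_acc_run{run}"
    long = behavior.melt(
        id_vars=["subject_id"],
        value_vars=[c for c in (fbd_col, "sci_acc", "fci_acc") if c in behavior],
        var_name="test_type", value_name="accuracy",
    ).dropna(subset=["accuracy"])
    long["test_type"] = long["test_type"].str.replace(fbd_col, "fbd").str.replace("_acc", "")
    run_scores = scores[(scores["run_id"] == run) & np.isfinite(scores["score"])]
    return long.merge(
        run_scores[["subject_id", "method", "score"]], on="subject_id", how="inner"
    )
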