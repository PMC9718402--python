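"""Testing-set metrics: AUC with DeLong 95% CI, odds ratio per
control-SD of the score, and logistic calibration intercept/slope.

The AUC is the Mann-Whitney statistic (ties count one half); its analytic
confidence interval uses the DeLong placement-variance estimator. The OR
per SD comes from a univariate logistic regression of status on the score
divided by the testing-control standard deviation. Calibration regresses
status on the logit of predicted probabilities; a well-calibrated model
has intercept 0 and slope 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats
from scipy.special import logit
from scipy.stats import rankdata


class EvaluationError(ValueError):
    pass


def auc_mann_whitney(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC as U/(n1*n0) with tied pairs counted one half."""
    y = np.asarray(y, dtype=bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise EvaluationError("both classes must be present")
    ranks = rankdata(scores)
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def auc_with_ci(scores: np.ndarray, y: np.ndarray, level: float = 0.95,
                bootstrap: int | None = None, seed: int = 0
                ) -> tuple[float, tuple[float, float]]:
    """AUC and its CI (DeLong by default; seeded percentile bootstrap with
    `bootstrap` resamples when requested). The CI is truncated to [0, 1]."""
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(y, dtype=bool)
    auc = auc_mann_whitney(scores, y)
    z = stats.norm.ppf(0.5 + level / 2)
    if bootstrap:
        rng = np.random.default_rng(seed)
        cases = scores[y]
        controls = scores[~y]
        reps = np.empty(bootstrap)
        yy = np.concatenate([np.ones(cases.size, bool),
                             np.zeros(controls.size, bool)])
        for b in range(bootstrap):
            s = np.concatenate([
                rng.choice(cases, cases.size, replace=True),
                rng.choice(controls, controls.size, replace=True),
            ])
            reps[b] = auc_mann_whitney(s, yy)
        lo, hi = np.quantile(reps, [(1 - level) / 2, 0.5 + level / 2])
    else:
        # DeLong: variance from case/control placement values
        n1, n0 = int(y.sum()), int((~y).sum())
        r_all = rankdata(scores)
        r_case = rankdata(scores[y])
        r_ctrl = rankdata(scores[~y])
        v10 = (r_all[y] - r_case) / n0          # placements of cases
        v01 = 1.0 - (r_all[~y] - r_ctrl) / n1   # placements of controls
        var = (np.var(v10, ddof=1) / n1 if n1 > 1 else 0.0) + \
              (np.var(v01, ddof=1) / n0 if n0 > 1 else 0.0)
        half = z * np.sqrt(var)
        lo, hi = auc - half, auc + half
    return auc, (float(max(0.0, lo)), float(min(1.0, hi)))


def _wald_logit(x: np.ndarray, y: np.ndarray):
    model = sm.Logit(np.asarray(y, dtype=float), sm.add_constant(x))
    return model.fit(disp=0, maxiter=200)


def or_per_sd(scores: np.ndarray, y: np.ndarray, control_sd: float,
              level: float = 0.95):
    """Odds ratio per control-SD of the score, with Wald CI.

    control_sd must come from the testing controls. Perfect separation is
    reported as a divergence (EvaluationError)."""
    if not control_sd > 0:
        raise EvaluationError("control_sd must be positive")
    x = np.asarray(scores, dtype=np.float64) / control_sd
    try:
        res = _wald_logit(x, y)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise EvaluationError(f"logistic fit diverged: {exc}") from exc
    if not np.all(np.isfinite(res.bse)):
        raise EvaluationError("logistic fit diverged (infinite SE)")
    beta = float(res.params[1])
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * float(res.bse[1])
    return float(np.exp(beta)), (float(np.exp(beta - half)),
                                 float(np.exp(beta + half)))


def calibration(y_test: np.ndarray, p_hat: np.ndarray, level: float = 0.95):
    """Calibration intercept and slope from a logistic regression of the
    outcome on logit(p_hat), with Wald CIs.

    p_hat values of exactly 0 or 1 are clipped to [1e-12, 1 - 1e-12].
    Constant p_hat leaves the slope undefined and raises."""
    p = np.clip(np.asarray(p_hat, dtype=np.float64), 1e-12, 1 - 1e-12)
    lp = logit(p)
    if np.ptp(lp) == 0:
        raise EvaluationError("constant predicted probabilities: "
                              "calibration slope undefined")
    res = _wald_logit(lp, y_test)
    z = stats.norm.ppf(0.5 + level / 2)
    out = {}
    for name, i in (("intercept", 0), ("slope", 1)):
        b, se = float(res.params[i]), float(res.bse[i])
        out[name] = (b, (b - z * se, b + z * se))
    return out["intercept"], out["slope"]


@dataclass
class EvaluationReport:
    auc: float
    auc_ci95: tuple[float, float]
    or_per_sd: float | None
    or_ci95: tuple[float, float] | None
    control_sd: float
    calib_intercept: float | None
    calib_intercept_ci95: tuple[float, float] | None
    calib_slope: float | None
    calib_slope_ci95: tuple[float, float] | None
    n_cases: int
    n_controls: int
    n_snps: int
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc, "auc_ci95": list(self.auc_ci95),
            "or_per_sd": self.or_per_sd,
            "or_ci95": None if self.or_ci95 is None else list(self.or_ci95),
            "control_sd": self.control_sd,
            "calib_intercept": self.calib_intercept,
            "calib_intercept_ci95": (
                None if self.calib_intercept_ci95 is None
                else list(self.calib_intercept_ci95)
            ),
            "calib_slope": self.calib_slope,
            "calib_slope_ci95": (
                None if self.calib_slope_ci95 is None
                else list(self.calib_slope_ci95)
            ),
            "n_cases": self.n_cases, "n_controls": self.n_controls,
            "n_snps": self.n_snps, "notes": self.notes,
        }


def evaluate_prs(train_scores: np.ndarray, y_train: np.ndarray,
                 test_scores: np.ndarray, y_test: np.ndarray,
                 n_snps: int = 0) -> EvaluationReport:
    """Full testing-set evaluation of one PRS.

    Calibration probabilities come from a univariate logistic model of
    training status on the training PRS, applied to the testing scores; the
    OR per SD standardizes by the testing controls' score SD.
    """
    y_test = np.asarray(y_test, dtype=bool)
    notes: list[str] = []
    auc, auc_ci = auc_with_ci(test_scores, y_test)
    control_sd = float(np.std(np.asarray(test_scores)[~y_test], ddof=1))

    orr = or_ci = None
    try:
        orr, or_ci = or_per_sd(test_scores, y_test, control_sd)
    except EvaluationError as exc:
        notes.append(f"or_per_sd: {exc}")

    ci_i = ci_s = None
    calib_i = calib_s = None
    try:
        res = _wald_logit(np.asarray(train_scores, dtype=np.float64), y_train)
        eta = res.params[0] + res.params[1] * np.asarray(test_scores)
        p_hat = 1.0 / (1.0 + np.exp(-eta))
        (calib_i, ci_i), (calib_s, ci_s) = calibration(y_test, p_hat)
    except Exception as exc:  # recorded, not fatal: PRS may be degenerate
        notes.append(f"calibration: {exc}")
        calib_i = calib_s = ci_i = ci_s = None

    return EvaluationReport(
        auc=auc, auc_ci95=auc_ci, or_per_sd=orr, or_ci95=or_ci,
        control_sd=control_sd, calib_intercept=calib_i,
        calib_intercept_ci95=ci_i, calib_slope=calib_s,
        calib_slope_ci95=ci_s, n_cases=int(y_test.sum()),
        n_controls=int((~y_test).sum()), n_snps=n_snps, notes=notes,
    )
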