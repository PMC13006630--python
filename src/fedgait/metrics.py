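"""Agreement and error metrics between true and predicted severity scores.

MAE and Pearson r quantify pointwise error and linear association on the
0-132 MDS-UPDRS III scale. Agreement between the true scores and a
model's predictions, treated as two raters scoring the same targets, is
measured with an average-measures intraclass correlation — absolute
agreement ICC(2,k) by default, with the consistency form ICC(3,k)
available — and with Bland–Altman bias and 95% limits of agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import mean_absolute_error

__all__ = [
    "AgreementReport",
    "mae",
    "pearson",
    "icc_average_raters_absolute",
    "bland_altman",
    "agreement_report",
]


def _check_pair(y_true, y_pred):
    y_true = np.asarray(y_true, dtype=float).reshape(-1)
    y_pred = np.asarray(y_pred, dtype=float).reshape(-1)
    if len(y_true) != len(y_pred):
        raise ValueError(
            f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted"
        )
    return y_true, y_pred


def mae(y_true, y_pred) -> float:
    """Mean absolute error in MDS-UPDRS III points."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    if len(y_true) == 0:
        raise ValueError("empty input")
    return float(mean_absolute_error(y_true, y_pred))


def pearson(y_true, y_pred) -> tuple[float, float]:
    """Product-moment correlation with two-sided p from the t transform."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    if len(y_true) < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        raise ValueError("correlation undefined: zero variance input")
    r, p = stats.pearsonr(y_true, y_pred)
    return float(r), float(p)


def icc_average_raters_absolute(
    true_scores,
    predicted_scores,
    targets,
    form: str = "absolute",
) -> tuple[float, float]:
    """Average-measures ICC of the (true, predicted) rater pair.

    Each target (by default one participant-visit) is rated twice: once by
    the clinical score and once by the model; ratings with multiple rows
    per target (several wear-days) are averaged per target first. Computed
    from the two-way ANOVA decomposition (Shrout & Fleiss): absolute
    agreement ICC(2,k) by default, ``form="consistency"`` for ICC(3,k).
    The p-value is the one-sided F-test against ICC = 0.
    """
    if form not in ("absolute", "consistency"):
        raise ValueError(f"unknown ICC form {form!r}")
    true_scores, predicted_scores = _check_pair(true_scores, predicted_scores)
    targets = np.asarray(targets)
    if len(targets) != len(true_scores):
        raise ValueError("targets length mismatch")
    tbl = (
        pd.DataFrame(
            {"target": targets, "true": true_scores, "pred": predicted_scores}
        )
        .groupby("target", sort=True)
        .mean()
    )
    if tbl[["true", "pred"]].isna().any().any():
        raise ValueError("a target is missing one of the raters")
    if len(tbl) < 2:
        raise ValueError("need at least 2 targets")

    import pingouin as pg

    long = tbl.reset_index().melt(
        id_vars="target", value_vars=["true", "pred"],
        var_name="rater", value_name="score",
    )
    res = pg.intraclass_corr(
        data=long, targets="target", raters="rater", ratings="score"
    ).set_index("Type")
    # average-measures two-way: absolute agreement ICC(2,k) / consistency ICC(3,k)
    row = res.loc["ICC(A,k)" if form == "absolute" else "ICC(C,k)"]
    return float(row["ICC"]), float(row["pval"])


def bland_altman(y_true, y_pred) -> tuple[float, float, float]:
    """Bias and 95% limits of agreement of the prediction differences.

    Returns ``(bias, lower, upper)`` where ``bias = mean(y_pred - y_true)``
    and the limits are ``bias +- 1.96 * SD(diff)`` (sample SD, ddof=1;
    0 for n < 2 spread).
    """
    y_true, y_pred = _check_pair(y_true, y_pred)
    if len(y_true) < 2:
        raise ValueError("need at least 2 pairs")
    diff = y_pred - y_true
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


@dataclass
class AgreementReport:
    mae: float
    pearson_r: float
    pearson_p: float
    icc: float
    icc_p: float
    icc_consistency: float
    icc_consistency_p: float
    ba_bias: float
    ba_lower: float
    ba_upper: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def agreement_report(y_true, y_pred, targets) -> AgreementReport:
    """All evaluation metrics for one model's pooled predictions.

    Degenerate inputs (e.g. zero-variance truth) leave the correlation
    and ICC entries as NaN rather than aborting the report.
    """
    y_true, y_pred = _check_pair(y_true, y_pred)
    try:
        icc_a, icc_a_p = icc_average_raters_absolute(y_true, y_pred, targets)
        icc_c, icc_c_p = icc_average_raters_absolute(
            y_true, y_pred, targets, form="consistency"
        )
    except (ValueError, ZeroDivisionError):
        icc_a = icc_a_p = icc_c = icc_c_p = float("nan")
    try:
        r, p = pearson(y_true, y_pred)
    except ValueError:
        r = p = float("nan")
    bias, lo, hi = bland_altman(y_true, y_pred)
    return AgreementReport(
        mae=mae(y_true, y_pred),
        pearson_r=r,
        pearson_p=p,
        icc=icc_a,
        icc_p=icc_a_p,
        icc_consistency=icc_c,
        icc_consistency_p=icc_c_p,
        ba_bias=bias,
        ba_lower=lo,
        ba_upper=hi,
        n=len(y_true),
    )
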