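"""Count-regression evaluation metrics.

Predictions are real-valued; reported metrics integerize them first
(round half away from zero), matching how leaf-count agreement is judged
against integer ground truth:

* AbsCountDiff — mean (sd) of |round(pred) - truth|
* CountDiff — mean (sd) of the signed difference
* MSE — mean squared integerized difference
* R² — coefficient of determination of the integerized predictions
  (can be negative when predictions are worse than the truth mean)
* Agreement (%) — fraction of exact matches
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

__all__ = ["EvalMetrics", "round_half_away", "compute_metrics"]


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero (so 2.5 -> 3, -2.5 -> -3)."""
    x = np.asarray(x, dtype=float)
    return np.copysign(np.floor(np.abs(x) + 0.5), x)


@dataclass
class EvalMetrics:
    abs_count_diff_mean: float
    abs_count_diff_sd: float
    count_diff_mean: float
    count_diff_sd: float
    mse: float
    r_squared: float
    agreement_pct: float
    n: int = 0

    def row(self) -> dict:
        """Metric row in the conventional reporting layout."""
        return {
            "AbsCountDiff": f"{self.abs_count_diff_mean:.2f} ({self.abs_count_diff_sd:.2f})",
            "CountDiff": f"{self.count_diff_mean:.2f} ({self.count_diff_sd:.2f})",
            "MSE": f"{self.mse:.2f}",
            "R2": f"{self.r_squared:.2f}",
            "Agreement (%)": f"{self.agreement_pct:.0f}",
        }


def compute_metrics(truths: np.ndarray, predictions: np.ndarray,
                    integerize: bool = True) -> EvalMetrics:
    """Metrics of real-valued ``predictions`` against integer ``truths``.

    With ``integerize=False`` the raw real-valued differences are used
    instead (a transparency variant; agreement still uses rounding).
    """
    t = np.asarray(truths, dtype=float)
    p = np.asarray(predictions, dtype=float)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("truths and predictions must be 1-d arrays of equal length")
    if len(t) == 0:
        raise ValueError("cannot evaluate an empty test set")
    r = round_half_away(p)
    used = r if integerize else p
    d = used - t
    ss_res = float((d ** 2).sum())
    ss_tot = float(((t - t.mean()) ** 2).sum())
    if ss_tot > 0:
        r2 = 1.0 - ss_res / ss_tot
    else:
        r2 = 1.0 if ss_res == 0 else float("nan")
    return EvalMetrics(
        abs_count_diff_mean=float(np.abs(d).mean()),
        abs_count_diff_sd=float(np.abs(d).std()),
        count_diff_mean=float(d.mean()),
        count_diff_sd=float(d.std()),
        mse=float((d ** 2).mean()),
        r_squared=r2,
        agreement_pct=float(100.0 * np.mean(r == t)),
        n=len(t),
    )
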