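"""Evaluation metrics for concentration recovery.

Parity metrics (R^2, RMSE, slope) pool every (true, predicted) component
pair into a single cloud, the convention used for headline comparisons of
unmixing methods; per-chromophore variants are also reported.  R^2 is
1 - SS_res/SS_tot with residuals (pred - true) about the mean of the true
values; the squared Pearson correlation of the parity cloud is emitted
alongside as a sensitivity check.  Average absolute error (AAE) is the mean
of |pred - true| per chromophore, optionally stratified by SNR, fluence
severity, or mixture class.  Cohort comparisons across independent test
sets use Welch's two-tailed t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .library import CHROMOPHORES

DEFAULT_SNR_BINS = tuple(np.arange(3.0, 40.0, 5.0)) + (40.0,)
DEFAULT_FLUENCE_BINS = tuple(np.arange(0.0, 22.0, 2.0))


@dataclass
class MetricsReport:
    """Pooled parity metrics plus per-chromophore breakdowns."""

    r2: float
    rmse: float
    slope: float
    intercept: float
    r2_pearson: float
    aae_per_chromophore: np.ndarray
    per_chromophore: pd.DataFrame = field(repr=False)
    n: int = 0
    r2_defined: bool = True

    def to_dict(self) -> dict:
        return {
            "r2": self.r2, "rmse": self.rmse, "slope": self.slope,
            "intercept": self.intercept, "r2_pearson": self.r2_pearson,
            "aae_per_chromophore": list(map(float, self.aae_per_chromophore)),
            "n": self.n, "r2_defined": self.r2_defined,
        }


def _check_pair(true: np.ndarray, pred: np.ndarray):
    true = np.atleast_2d(np.asarray(true, dtype=float))
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    if true.shape != pred.shape:
        raise ValueError(f"shape mismatch: true {true.shape} vs pred {pred.shape}")
    if true.shape[0] < 1:
        raise ValueError("need at least one record")
    return true, pred


def _parity(true_flat: np.ndarray, pred_flat: np.ndarray):
    ss_tot = float(np.sum((true_flat - true_flat.mean()) ** 2))
    ss_res = float(np.sum((pred_flat - true_flat) ** 2))
    if ss_tot <= 1e-14 * max(1.0, float(np.sum(true_flat**2))):
        ss_tot = 0.0
    if ss_tot == 0:
        r2, defined = float("nan"), False
    else:
        r2, defined = 1.0 - ss_res / ss_tot, True
    rmse = float(np.sqrt(np.mean((pred_flat - true_flat) ** 2)))
    if ss_tot == 0:
        slope, intercept, r2p = float("nan"), float("nan"), float("nan")
    else:
        slope, intercept = np.polyfit(true_flat, pred_flat, 1)
        sd_pred = pred_flat.std()
        r2p = (
            float(np.corrcoef(true_flat, pred_flat)[0, 1] ** 2)
            if sd_pred > 0 else 0.0
        )
    return r2, rmse, float(slope), float(intercept), r2p, defined


def parity_metrics(true, pred, chromophore_names=CHROMOPHORES) -> MetricsReport:
    """Pooled and per-chromophore parity metrics over paired records."""
    true, pred = _check_pair(true, pred)
    if true.shape[0] < 2:
        raise ValueError("parity metrics need at least 2 records")
    r2, rmse, slope, intercept, r2p, defined = _parity(true.ravel(), pred.ravel())
    rows = {}
    names = list(chromophore_names)[: true.shape[1]]
    for j, name in enumerate(names):
        jr2, jrmse, jslope, _, _, _ = _parity(true[:, j], pred[:, j])
        rows[name] = {
            "r2": jr2, "rmse": jrmse, "slope": jslope,
            "aae": float(np.mean(np.abs(pred[:, j] - true[:, j]))),
        }
    per = pd.DataFrame(rows).T
    return MetricsReport(
        r2=r2, rmse=rmse, slope=slope, intercept=intercept, r2_pearson=r2p,
        aae_per_chromophore=np.abs(pred - true).mean(axis=0),
        per_chromophore=per, n=true.shape[0], r2_defined=defined,
    )


def aae(
    true,
    pred,
    stratify_by: str | None = None,
    values: np.ndarray | None = None,
    bins=None,
    chromophore_names=CHROMOPHORES,
) -> pd.DataFrame:
    """Mean absolute error per chromophore, optionally per stratum.

    ``stratify_by`` is one of None, "snr", "fluence", or "mixture_class";
    ``values`` carries the per-record stratifier (dB, severity x, or class
    labels).  Numeric stratifiers are binned (default: 5 dB bins over
    [3, 40]; fluence bins of width 2 over [0, 20]); empty strata are simply
    absent from the table.
    """
    true, pred = _check_pair(true, pred)
    names = list(chromophore_names)[: true.shape[1]]
    err = np.abs(pred - true)
    if stratify_by is None:
        df = pd.DataFrame([err.mean(axis=0)], columns=names, index=["all"])
        df["n"] = true.shape[0]
        return df
    if values is None:
        raise ValueError(f"stratify_by={stratify_by!r} requires per-record values")
    values = np.asarray(values)
    if values.shape[0] != true.shape[0]:
        raise ValueError("stratifier length does not match records")

    if stratify_by == "mixture_class":
        labels = np.asarray([str(v) for v in values])
        rows, index, counts = [], [], []
        for lab in pd.unique(labels):
            m = labels == lab
            rows.append(err[m].mean(axis=0))
            index.append(lab)
            counts.append(int(m.sum()))
    elif stratify_by in ("snr", "fluence"):
        if bins is None:
            bins = DEFAULT_SNR_BINS if stratify_by == "snr" else DEFAULT_FLUENCE_BINS
        edges = np.asarray(bins, dtype=float)
        which = np.digitize(values.astype(float), edges[1:-1], right=False)
        rows, index, counts = [], [], []
        for b in range(edges.size - 1):
            m = which == b
            if not m.any():
                continue
            rows.append(err[m].mean(axis=0))
            index.append(f"[{edges[b]:g}, {edges[b + 1]:g})")
            counts.append(int(m.sum()))
    else:
        raise ValueError(f"unknown stratifier {stratify_by!r}")
    df = pd.DataFrame(rows, columns=names, index=index)
    df["n"] = counts
    return df


@dataclass(frozen=True)
class CohortComparison:
    """Welch two-tailed t-test between per-test-set metric cohorts."""

    metric_name: str
    values_a: tuple
    values_b: tuple
    t_statistic: float
    p_value: float


def compare_cohorts(values_a, values_b, metric_name: str = "metric") -> CohortComparison:
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each cohort needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        # degenerate-variance rule: identical means are indistinguishable
        # (t = 0, p = 1); different means are trivially separated (p -> 0).
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t = float(np.inf if a.mean() > b.mean() else -np.inf)
            p = 0.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
        t, p = float(t), float(p)
    return CohortComparison(metric_name, tuple(a), tuple(b), t, p)


def so2(c, chromophore_names=CHROMOPHORES) -> float:
    """Hemoglobin oxygen saturation HbO2 / (HbO2 + HbR); NaN when undefined."""
    c = np.asarray(c, dtype=float)
    i_o = list(chromophore_names).index("HbO2")
    i_r = list(chromophore_names).index("HbR")
    total = c[..., i_o] + c[..., i_r]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, c[..., i_o] / np.where(total > 0, total, 1.0), np.nan)
    return float(out) if np.isscalar(total) or total.ndim == 0 else out
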