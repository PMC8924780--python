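"""Agreement statistics between a criterion and a device HR series.

The suite reported per activity and overall:

* MAE — mean absolute error, ``mean(|dev - ref|)`` in bpm;
* MAPE — mean absolute percentage error,
  ``100 * mean(|dev - ref| / ref)``, with the criterion in the
  denominator; the conventional validity limit for wearable HR is
  MAPE < 10%;
* Bland-Altman bias and limits of agreement — ``bias = mean(dev - ref)``,
  ``LoA = bias ± 1.96 * sd(diff)`` with sample sd (n-1 denominator);
* Pearson product-moment correlation (PCC);
* Lin concordance correlation coefficient (CCC),
  ``2*s_xy / (s_x^2 + s_y^2 + (x̄ - ȳ)^2)`` with population (1/n)
  second moments, which penalizes location and scale shifts on top of
  imperfect correlation and therefore never exceeds |PCC|.

sd conventions are pinned for reproducibility: sample sd (n-1) for
descriptive SDs and Bland-Altman, population moments (1/n) inside Lin's
estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .series import PairedSeries

__all__ = [
    "mae",
    "mape",
    "bland_altman",
    "pearson",
    "lin_ccc",
    "metric_block",
    "BlandAltman",
    "MetricBlock",
    "MAPE_VALIDITY_LIMIT_PCT",
    "LOA_MULTIPLIER",
]

MAPE_VALIDITY_LIMIT_PCT = 10.0
LOA_MULTIPLIER = 1.96


def mae(p: PairedSeries) -> float:
    """Mean absolute error in bpm."""
    if p.n < 1:
        raise ValueError("empty paired series")
    return float(np.mean(np.abs(p.dev_values - p.ref_values)))


def mape(p: PairedSeries) -> float:
    """Mean absolute percentage error (percent of the criterion value)."""
    if p.n < 1:
        raise ValueError("empty paired series")
    if np.any(p.ref_values <= 0):
        raise ValueError("criterion HR must be strictly positive")
    return float(100.0 * np.mean(np.abs(p.dev_values - p.ref_values) / p.ref_values))


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    loa_lower: float
    loa_upper: float
    points: pd.DataFrame  # columns mean_bpm, diff_bpm; plot-ready export


def bland_altman(p: PairedSeries, loa_method: str = "sd") -> BlandAltman:
    """Bias and 95% limits of agreement of the differences dev - ref.

    ``loa_method='sd'`` (default): bias ± 1.96 · sample sd.
    ``loa_method='percentile'``: empirical 2.5th/97.5th percentiles of
    the differences, a distribution-free alternative.
    """
    if p.n < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    diff = p.dev_values - p.ref_values
    bias = float(np.mean(diff))
    if loa_method == "sd":
        half = LOA_MULTIPLIER * float(np.std(diff, ddof=1))
        lo, hi = bias - half, bias + half
    elif loa_method == "percentile":
        lo, hi = (float(q) for q in np.percentile(diff, [2.5, 97.5]))
    else:
        raise ValueError(f"unknown loa_method {loa_method!r}")
    points = pd.DataFrame(
        {"mean_bpm": (p.dev_values + p.ref_values) / 2.0, "diff_bpm": diff}
    )
    return BlandAltman(bias=bias, loa_lower=lo, loa_upper=hi, points=points)


def pearson(p: PairedSeries) -> float:
    """Pearson product-moment correlation coefficient."""
    if p.n < 2:
        raise ValueError("correlation needs at least 2 pairs")
    if np.std(p.ref_values) == 0 or np.std(p.dev_values) == 0:
        raise ValueError("correlation undefined for a constant series")
    return float(stats.pearsonr(p.ref_values, p.dev_values).statistic)


def lin_ccc(p: PairedSeries) -> float:
    """Lin concordance correlation coefficient (population moments)."""
    if p.n < 2:
        raise ValueError("concordance needs at least 2 pairs")
    x, y = p.ref_values, p.dev_values
    vx = float(np.var(x))  # 1/n
    vy = float(np.var(y))
    if vx == 0.0 and vy == 0.0:
        raise ValueError("concordance undefined when both series are constant")
    sxy = float(np.mean((x - x.mean()) * (y - y.mean())))
    return 2.0 * sxy / (vx + vy + (x.mean() - y.mean()) ** 2)


@dataclass(frozen=True)
class MetricBlock:
    """One cell of the validation report: all metrics for one data pool."""

    n: int
    ref_mean: float
    ref_sd: float
    dev_mean: float
    dev_sd: float
    mae: float
    mape: float
    ccc: float
    pcc: float
    bias: float
    loa_lower: float
    loa_upper: float
    valid_mape: bool

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "ref_mean": self.ref_mean,
            "ref_sd": self.ref_sd,
            "dev_mean": self.dev_mean,
            "dev_sd": self.dev_sd,
            "mae": self.mae,
            "mape": self.mape,
            "ccc": self.ccc,
            "pcc": self.pcc,
            "bias": self.bias,
            "loa_lower": self.loa_lower,
            "loa_upper": self.loa_upper,
            "valid_mape": self.valid_mape,
        }


def metric_block(
    p: PairedSeries,
    loa_method: str = "sd",
    validity_limit_pct: float = MAPE_VALIDITY_LIMIT_PCT,
) -> MetricBlock:
    """Assemble the full agreement-metric block for one data pool.

    ``valid_mape`` is True iff MAPE is strictly below the validity limit
    (default 10%), so a device sitting exactly on the limit is not
    declared valid.
    """
    if p.n < 2:
        raise ValueError("metric block needs at least 2 pairs")
    ba = bland_altman(p, loa_method=loa_method)
    m = mape(p)
    return MetricBlock(
        n=p.n,
        ref_mean=float(np.mean(p.ref_values)),
        ref_sd=float(np.std(p.ref_values, ddof=1)),
        dev_mean=float(np.mean(p.dev_values)),
        dev_sd=float(np.std(p.dev_values, ddof=1)),
        mae=mae(p),
        mape=m,
        ccc=lin_ccc(p),
        pcc=pearson(p),
        bias=ba.bias,
        loa_lower=ba.loa_lower,
        loa_upper=ba.loa_upper,
        valid_mape=bool(m < validity_limit_pct),
    )
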