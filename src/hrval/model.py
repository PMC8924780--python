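"""Model/Results front end for the agreement analysis.

:class:`HeartRateAgreement` wraps a paired criterion/device dataset the
way statistical modelling packages wrap data + design: construct from
arrays, aligned series or a DataFrame, call :meth:`fit`, and get an
:class:`AgreementResults` object carrying the estimates, a ``summary()``
table and plot-ready Bland-Altman points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import metrics
from .metrics import BlandAltman, MetricBlock
from .series import HRSeries, PairedSeries

__all__ = ["HeartRateAgreement", "AgreementResults"]


class HeartRateAgreement:
    """Agreement of a device HR measurement with a criterion measurement.

    Parameters
    ----------
    ref : array-like
        Criterion (gold standard) HR in bpm.
    dev : array-like
        Device HR in bpm, paired second-by-second with ``ref``.
    label : str
        Optional name for the device/pool (appears in the summary).
    """

    def __init__(self, ref, dev, label: str = ""):
        self.data = PairedSeries(
            ref_values=np.asarray(ref, float),
            dev_values=np.asarray(dev, float),
            label=label,
        )
        self.label = label

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, ref_col: str = "ref", dev_col: str = "dev",
        label: str = "",
    ) -> "HeartRateAgreement":
        sub = df[[ref_col, dev_col]].dropna()
        return cls(sub[ref_col].to_numpy(), sub[dev_col].to_numpy(), label=label)

    @classmethod
    def from_series(
        cls, ref: HRSeries, dev: HRSeries, label: str = ""
    ) -> "HeartRateAgreement":
        """Pair two aligned 1 Hz series by intersecting validity masks."""
        p = PairedSeries.from_aligned(ref, dev, label=label)
        obj = cls.__new__(cls)
        obj.data = p
        obj.label = label
        return obj

    def fit(
        self, loa_method: str = "sd",
        validity_limit_pct: float = metrics.MAPE_VALIDITY_LIMIT_PCT,
    ) -> "AgreementResults":
        block = metrics.metric_block(
            self.data, loa_method=loa_method, validity_limit_pct=validity_limit_pct
        )
        ba = metrics.bland_altman(self.data, loa_method=loa_method)
        return AgreementResults(model=self, block=block, bland_altman=ba)


@dataclass(frozen=True)
class AgreementResults:
    """Fitted agreement estimates for one criterion/device pool."""

    model: HeartRateAgreement
    block: MetricBlock
    bland_altman: BlandAltman

    def __getattr__(self, name):
        # expose block fields (mae, mape, ccc, pcc, bias, ...) directly
        block = object.__getattribute__(self, "block")
        if hasattr(block, name):
            return getattr(block, name)
        raise AttributeError(name)

    def to_dict(self) -> dict:
        return self.block.to_dict()

    def summary(self) -> str:
        b = self.block
        label = self.model.label or "device"
        lines = [
            f"Heart-rate agreement: {label}",
            "=" * 44,
            f"{'paired seconds (n)':<28}{b.n:>14d}",
            f"{'criterion mean (SD), bpm':<28}{b.ref_mean:>7.2f} ({b.ref_sd:.2f})",
            f"{'device mean (SD), bpm':<28}{b.dev_mean:>7.2f} ({b.dev_sd:.2f})",
            f"{'MAE, bpm':<28}{b.mae:>14.3f}",
            f"{'MAPE, %':<28}{b.mape:>14.3f}",
            f"{'Lin CCC':<28}{b.ccc:>14.3f}",
            f"{'Pearson r':<28}{b.pcc:>14.3f}",
            f"{'bias (dev - ref), bpm':<28}{b.bias:>14.2f}",
            f"{'95% limits of agreement':<28}{b.loa_lower:>6.2f} to {b.loa_upper:.2f}",
            f"{'valid (MAPE < 10%)':<28}{str(b.valid_mape):>14}",
        ]
        return "\n".join(lines)
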