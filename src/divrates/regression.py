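"""Regression through the origin of size contrasts on rate contrasts.

The line is forced through the origin because two clades with identical
substitution rates carry no information about the direction of their
size difference: the expected size contrast at zero rate contrast is
zero.  With predictor x (log rate contrast) and response y (log size
contrast),

    b  = sum(x*y) / sum(x^2)
    s2 = sum((y - b*x)^2) / (n - 1)
    SE = sqrt(s2 / sum(x^2))

and b/SE is referred to Student's t with n-1 degrees of freedom (Wald
test, two-sided).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class OriginRegressionResults:
    """Fit of a no-intercept least-squares line, with Wald inference."""

    slope: float
    bse: float
    tvalue: float
    pvalue: float
    nobs: int

    @property
    def df_resid(self) -> int:
        return self.nobs - 1

    def summary(self) -> str:
        lines = [
            "Regression through the origin (Wald test)",
            "=" * 45,
            f"{'n pairs':<18}{self.nobs:>12d}",
            f"{'coefficient':<18}{self.slope:>12.4f}",
            f"{'std. error':<18}{self.bse:>12.4f}",
            f"{'t':<18}{self.tvalue:>12.3f}",
            f"{'P>|t| (df=%d)' % self.df_resid:<18}{self.pvalue:>12.4g}",
        ]
        return "\n".join(lines)


class OriginRegression:
    """No-intercept OLS model: y = b * x + e.

    Parameters
    ----------
    y : array-like
        Response (log clade-size contrasts).
    x : array-like
        Predictor (log substitution-rate contrasts).
    """

    def __init__(self, y, x):
        self.y = np.asarray(y, dtype=float)
        self.x = np.asarray(x, dtype=float)
        if self.y.shape != self.x.shape or self.y.ndim != 1:
            raise ValueError("x and y must be 1-D and equal length")
        if len(self.y) < 2:
            raise ValueError("need at least two pairs")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("non-finite contrast values")

    @classmethod
    def from_contrasts(cls, contrasts: pd.DataFrame) -> "OriginRegression":
        return cls(contrasts["d_log_size"], contrasts["d_log_rate"])

    def fit(self) -> OriginRegressionResults:
        sxx = float(self.x @ self.x)
        if sxx == 0:
            raise ValueError("predictor contrasts are all zero")
        n = len(self.x)
        slope = float(self.x @ self.y) / sxx
        resid = self.y - slope * self.x
        s2 = float(resid @ resid) / (n - 1)
        bse = float(np.sqrt(s2 / sxx))
        if bse > 0:
            tval = slope / bse
            pval = 2 * stats.t.sf(abs(tval), df=n - 1)
        else:
            tval = np.inf if slope != 0 else 0.0
            pval = 0.0 if slope != 0 else 1.0
        return OriginRegressionResults(
            slope=slope, bse=bse, tvalue=float(tval), pvalue=float(pval),
            nobs=n,
        )


def regress_through_origin(x, y) -> OriginRegressionResults:
    """Functional form of OriginRegression: x predictor, y response."""
    return OriginRegression(y, x).fit()
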