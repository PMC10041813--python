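"""Correlation-based validation of the competition index.

Pearson's product-moment correlation between the Spatial Competition Index
and a facility's blood-transfusion capacity (units received from the
national service, units transfused), with the exact t statistic on n - 2
degrees of freedom, a two-sided p-value and the Fisher-z confidence
interval tanh(atanh(r) +/- z / sqrt(n - 3)). Q-Q diagnostics against the
standard normal use plotting positions (i - 0.5) / n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CorrelationResult", "pearson_validate", "qq_points"]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    t: float
    p: float
    ci: tuple[float, float]
    level: float

    @property
    def df(self) -> int:
        return self.n - 2

    def summary(self) -> str:
        lo, hi = self.ci
        return (
            f"Pearson correlation: r = {self.r:.4f} (n = {self.n}, df = {self.df})\n"
            f"t = {self.t:.4f}, two-sided p = {self.p:.4g}\n"
            f"{self.level * 100:.0f}% Fisher CI: [{lo:.4f}, {hi:.4f}]"
        )


def pearson_validate(x, y, level: float = 0.95) -> CorrelationResult:
    """Pearson r between two capacity vectors with t test and Fisher CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    for name, v in (("x", x), ("y", y)):
        if np.ptp(v) == 0:
            raise ValueError(f"zero variance in {name}; correlation undefined")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    t = r * np.sqrt(n - 2) / np.sqrt(max(1.0 - r * r, np.finfo(float).tiny))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    z = np.arctanh(np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15))
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    half = zcrit / np.sqrt(n - 3)
    ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    return CorrelationResult(r=r, n=n, t=float(t), p=p, ci=ci, level=level)


def qq_points(x) -> pd.DataFrame:
    """Normal Q-Q pairs: standard-normal quantiles at (i - 0.5)/n vs sorted data."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    probs = (np.arange(1, n + 1) - 0.5) / n
    theo = stats.norm.ppf(probs)
    return pd.DataFrame({"theoretical": theo, "sample": x})
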