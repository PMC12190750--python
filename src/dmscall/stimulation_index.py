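"""Glucose-stimulated insulin secretion (GSIS) stimulation index.

The stimulation index is the ratio of mean secreted insulin in the high-
glucose condition to the mean in the low-glucose condition.  Its 95%
confidence interval comes from Fieller's theorem for the ratio of two
independent normal means; the P-value tests the null that the index
equals one, which for positive means is equivalent to equality of the two
means, via a two-sample t statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class GsisResult:
    """Stimulation index with Fieller CI and t-test P-value.

    ``ci_low``/``ci_high`` are ``None`` when Fieller's g >= 1, i.e. the
    denominator mean is not significantly different from zero and the
    confidence set is unbounded (``unbounded=True``).
    """

    index: float
    ci_low: float | None
    ci_high: float | None
    unbounded: bool
    p: float
    n_high: int
    n_low: int
    df: int
    conf: float


def fieller_ratio_ci(
    high_values,
    low_values,
    conf: float = 0.95,
    df_mode: str = "pooled",
) -> GsisResult:
    """Fieller confidence interval and t-test for mean(high)/mean(low).

    With sample means xH, xL and squared standard errors vH = sH^2/nH,
    vL = sL^2/nL, the interval is

        [xH*xL +/- t*sqrt(xL^2 vH + xH^2 vL - t^2 vH vL)] / (xL^2 - t^2 vL)

    for the two-sided critical value t at level ``conf``.  When
    xL^2 <= t^2 vL (g >= 1) the interval is unbounded and flagged.
    Degrees of freedom are nH + nL - 2 (``df_mode="pooled"``, the default)
    or Welch-Satterthwaite (``df_mode="welch"``).
    """
    hi = np.asarray(high_values, dtype=float)
    lo = np.asarray(low_values, dtype=float)
    if hi.size < 2 or lo.size < 2:
        raise ValueError("need at least two replicates per condition")
    if not (np.all(np.isfinite(hi)) and np.all(np.isfinite(lo))):
        raise ValueError("insulin values must be finite")
    nH, nL = hi.size, lo.size
    xH, xL = hi.mean(), lo.mean()
    if xL == 0:
        raise ValueError("low-condition mean is zero; ratio undefined")
    vH = hi.var(ddof=1) / nH
    vL = lo.var(ddof=1) / nL

    if df_mode == "pooled":
        df = nH + nL - 2
    elif df_mode == "welch":
        if vH + vL == 0:
            df = nH + nL - 2
        else:
            df = (vH + vL) ** 2 / (
                vH**2 / (nH - 1) + vL**2 / (nL - 1)
            )
    else:
        raise ValueError("df_mode must be 'pooled' or 'welch'")

    index = xH / xL

    if vH == 0 and vL == 0:
        # degenerate: no sampling variability
        p = 1.0 if xH == xL else 0.0
        return GsisResult(
            index=index,
            ci_low=index,
            ci_high=index,
            unbounded=False,
            p=p,
            n_high=nH,
            n_low=nL,
            df=int(round(df)),
            conf=conf,
        )

    tcrit = stats.t.ppf(0.5 + conf / 2.0, df)
    denom = xL * xL - tcrit * tcrit * vL
    disc = xL * xL * vH + xH * xH * vL - tcrit * tcrit * vH * vL
    if denom <= 0 or disc < 0:
        ci_low, ci_high, unbounded = None, None, True
    else:
        root = tcrit * math.sqrt(disc)
        ci_low = (xH * xL - root) / denom
        ci_high = (xH * xL + root) / denom
        unbounded = False

    tstat = (xH - xL) / math.sqrt(vH + vL)
    p = float(2.0 * stats.t.sf(abs(tstat), df))
    return GsisResult(
        index=float(index),
        ci_low=ci_low,
        ci_high=ci_high,
        unbounded=unbounded,
        p=p,
        n_high=nH,
        n_low=nL,
        df=int(round(df)),
        conf=conf,
    )
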