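"""Bland–Altman method-agreement analysis between paired ω_peak (or duration)
series from two measurement sources.

Reports the mean difference (bias), the 95% limits of agreement
(bias ± 1.96·SD of the differences, normal-theory), and proportional-bias
diagnostics: the slope and p-value of the differences regressed on the pair
means, plus the correlation of |residuals| with the means as a
heteroscedasticity indicator.  The subtraction orientation (first minus
second series) is recorded in the report so signs stay auditable; the
replication recipe uses reference − estimate, making a positive bias an
underestimate by the phone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, PairingError

LOA_MULTIPLIER = 1.96


@dataclass
class AgreementReport:
    label_a: str
    label_b: str
    n_pairs: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    proportional_bias_slope: float
    proportional_bias_p: float
    heteroscedasticity_r: float

    @property
    def loa_width(self) -> float:
        return self.loa_high - self.loa_low


def bland_altman(a, b, labels: tuple[str, str] = ("a", "b")) -> AgreementReport:
    """Agreement of two paired series; differences are ``a − b``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise PairingError(f"paired series must be equal-length 1-D, got {a.shape} vs {b.shape}")
    n = a.size
    if n < 3:
        raise InsufficientDataError("Bland–Altman needs >= 3 pairs")
    diff = a - b
    mean = (a + b) / 2.0
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if np.ptp(mean) > 0 and sd > 0:
        with np.errstate(divide="ignore", invalid="ignore"):
            reg = stats.linregress(mean, diff)
            slope, pval = float(reg.slope), float(reg.pvalue)
            resid = diff - (reg.intercept + reg.slope * mean)
            abs_resid = np.abs(resid)
            hetero = float(np.corrcoef(mean, abs_resid)[0, 1])
        if not np.isfinite(hetero):
            hetero = 0.0
        if not np.isfinite(pval):
            pval = 1.0
    else:
        slope, pval, hetero = 0.0, 1.0, 0.0
    return AgreementReport(
        label_a=labels[0],
        label_b=labels[1],
        n_pairs=n,
        bias=bias,
        sd_diff=sd,
        loa_low=bias - LOA_MULTIPLIER * sd,
        loa_high=bias + LOA_MULTIPLIER * sd,
        proportional_bias_slope=slope,
        proportional_bias_p=pval,
        heteroscedasticity_r=hetero,
    )
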