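"""Two-sample statistics used by the polarity calls.

The study's sole inferential tool is the two-tailed unpaired Student's t-test
(equal-variance, pooled SD) at alpha = 0.05, applied without multiple-testing
correction.  It is written out explicitly here — pooled variance, t statistic,
two-tailed p from the t distribution with n_a + n_b - 2 degrees of freedom —
so the test's exact form is part of the package contract.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import t as t_dist

from .io import ValidationError

__all__ = ["ttest_two_tailed", "standard_error"]


def ttest_two_tailed(sample_a, sample_b) -> tuple[float, float]:
    """Pooled-variance Student's t-test; returns ``(t, p)`` with a two-tailed p.

    Degenerate inputs: zero pooled variance with equal means gives (0, 1);
    zero pooled variance with unequal means gives (inf, 0) — a flagged
    degenerate separation, not an error.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValidationError("each sample needs n >= 2")
    df = na + nb - 2
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if pooled_var == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, diff), 0.0
    t = diff / math.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    p = 2.0 * t_dist.sf(abs(t), df)
    return float(t), float(p)


def standard_error(values) -> float:
    """Sample SD / sqrt(n) — the SE quoted next to every population mean."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValidationError("standard error needs n >= 2")
    return float(v.std(ddof=1) / math.sqrt(len(v)))
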