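"""Two-sample pooled-variance Student's t-test.

The expected-vs-observed adjacency comparison treats the per-unit percentage
columns as two independent samples and applies the classical pooled test:

    t = (mean(x) - mean(y)) / sqrt(sp^2 * (1/n1 + 1/n2))
    sp^2 = ((n1 - 1) s1^2 + (n2 - 1) s2^2) / (n1 + n2 - 2)

with a two-tailed p-value from Student's t distribution on n1 + n2 - 2
degrees of freedom.  Implemented from the formula (the convention, including
its use on printed-precision percentages, is part of the analysis being
reproduced); scipy supplies only the t distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats as _sstats


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p_two_tailed: float
    mean_x: float
    mean_y: float
    pooled_variance: float


def pooled_t_test(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("pooled t-test needs at least 2 observations per sample")
    mx = sum(x) / n1
    my = sum(y) / n2
    s1 = sum((v - mx) ** 2 for v in x) / (n1 - 1)
    s2 = sum((v - my) ** 2 for v in y) / (n2 - 1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1 + (n2 - 1) * s2) / df
    if sp2 == 0:
        t = 0.0 if mx == my else math.copysign(math.inf, mx - my)
    else:
        t = (mx - my) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    if math.isinf(t):
        p = 0.0
    else:
        p = 2 * _sstats.t.sf(abs(t), df)
    return TTestResult(
        t=t, df=df, p_two_tailed=p, mean_x=mx, mean_y=my, pooled_variance=sp2
    )
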