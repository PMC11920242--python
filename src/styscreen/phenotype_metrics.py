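"""Flow-cytometry and T-cell killing phenotype statistics.

Relative MFI normalizes a sample's median fluorescence intensity to an
isotype-stained control and, optionally, further to safe-harbor control
cells. The competitive killing indices compare the odds of recovering the
tracked population with vs without effector T cells:

    index = 100 * (1 - [A/(100-A)] / [B/(100-B)])

with A the population percentage in the T-cell co-culture and B in the
paired no-T-cell control. The index is 0 when killing leaves the mix
untouched (A = B), 100 when the tracked population is eliminated (A = 0)
and negative when it is enriched under killing pressure.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


class MetricError(ValueError):
    pass


def relative_mfi(sample: float, isotype: float, control: float | None = None) -> float:
    """MFI ratio to isotype, optionally further ratioed to control cells.

    ``control`` is the isotype-normalized ratio of the safe-harbor
    control sample; when given the result is (sample/isotype)/control.
    """
    if sample <= 0 or isotype <= 0:
        raise MetricError("MFI values must be positive")
    r = sample / isotype
    if control is not None:
        if control <= 0:
            raise MetricError("control ratio must be positive")
        r /= control
    return r


def _odds(p: float) -> float:
    if not 0 <= p < 100:
        raise MetricError(f"percentage must be in [0, 100), got {p}")
    return p / (100.0 - p)


def killing_sensitivity(A1: float, B1: float) -> float:
    """Killing sensitivity of the edited (tracked) population, in percent."""
    ob = _odds(B1)
    if ob == 0:
        raise MetricError("B percentage is 0: odds ratio undefined")
    return 100.0 * (1.0 - _odds(A1) / ob)


def killing_resistance(A2: float, B2: float) -> float:
    """Killing resistance of the wild-type competitor population, in percent.

    Same odds-ratio formula as sensitivity, applied to the WT competitor;
    positive values mean the competitor was depleted by T cells.
    """
    return killing_sensitivity(A2, B2)


_STARS = [(1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")]


def significance_stars(p: float) -> str:
    for cut, s in _STARS:
        if p < cut:
            return s
    return "n.s."


def compare_groups(x, y, equal_var: bool = True) -> tuple[float, float]:
    """Two-tailed two-sample Student's t test (Welch with equal_var=False)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise MetricError("need at least 2 replicates per group")
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    if np.isnan(p):  # identical constant groups: no evidence of difference
        return 0.0, 1.0
    return float(t), float(p)
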