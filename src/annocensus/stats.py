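"""Small statistical helpers shared across census modules."""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats as sps

# Conventional floor used when rendering vanishingly small p-values in text.
P_FLOOR = 2.2e-16


def welch_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> dict:
    """Two-sided Welch (unequal-variance) t-test.

    Returns the statistic, Welch-Satterthwaite df, the exact p-value, and a
    text rendering that floors at "< 2.2e-16". Identical groups give t = 0,
    p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    res = sps.ttest_ind(a, b, equal_var=False)
    t = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(t):  # both groups constant and equal
        if np.allclose(a.mean(), b.mean()) and a.std() == b.std() == 0:
            t, p = 0.0, 1.0
        else:
            raise ValueError("degenerate groups: zero variance in both groups")
    df = float(res.df) if hasattr(res, "df") else float("nan")
    return {"t": t, "df": df, "p": p, "p_text": format_p(p)}


def format_p(p: float) -> str:
    return f"< {P_FLOOR:g}" if p < P_FLOOR else f"{p:.4g}"
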