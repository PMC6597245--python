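"""Condition comparisons, recovery metrics, and statistical conventions.

Implements the reporting conventions of the FRET time-course experiments:
two-tailed Student's t-tests (classical pooled variance by default, Welch
behind a flag), significance labels at p <= 0.05 (*), <= 0.005 (**) and
<= 0.0005 (***), aggregation at the cell level (mean +/- s.d.) or the
experiment level (mean of per-experiment means +/- s.e.m.), and the recovery
percentage — the fraction of an activation-induced drop in normalized cFRET
that is reversed after returning to the baseline condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError, StatisticsError
from .sefret import FretTimeCourse, condition_window_mean

ALPHA_LEVELS = (0.05, 0.005, 0.0005)


@dataclass
class GroupSummary:
    label: str
    n_cells: int
    n_experiments: int
    mean: float
    sd: float
    sem: float
    unit: str = "percent_cfret"


def recovery_percent(baseline: float, activated: float, recovered: float) -> float:
    """Fraction of the activation-induced drop that is reversed, in percent.

    ``100 * (recovered - activated) / (baseline - activated)`` on the
    normalized-percent scale (baseline typically 100).  Requires that a drop
    occurred (``activated < baseline``).
    """
    if activated >= baseline:
        raise ParameterError("recovery undefined: no drop (activated >= baseline)")
    return 100.0 * (recovered - activated) / (baseline - activated)


def significance_label(p: float, levels=ALPHA_LEVELS) -> str:
    """n.s. / * / ** / *** at p <= 0.05 / 0.005 / 0.0005."""
    if p <= levels[2]:
        return "***"
    if p <= levels[1]:
        return "**"
    if p <= levels[0]:
        return "*"
    return "n.s."


def two_tailed_t(a, b, paired: bool = False, welch: bool = False):
    """Two-tailed Student's t-test with significance label.

    Unpaired uses the classical pooled-variance t (Welch available behind
    the flag); paired requires equal lengths.  Zero variance in both samples
    with equal means returns t = 0, p = 1 by convention.

    Returns ``(t, df, p, label)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise StatisticsError("each sample needs n >= 2")
    if paired:
        if len(a) != len(b):
            raise StatisticsError("paired test requires equal lengths")
        d = a - b
        n = len(d)
        sd = d.std(ddof=1)
        if sd == 0:
            t = 0.0 if d.mean() == 0 else np.inf * np.sign(d.mean())
        else:
            t = d.mean() / (sd / np.sqrt(n))
        df = n - 1
    else:
        na, nb = len(a), len(b)
        va, vb = a.var(ddof=1), b.var(ddof=1)
        if welch:
            denom = np.sqrt(va / na + vb / nb)
            if denom == 0:
                t = 0.0 if a.mean() == b.mean() else np.inf * np.sign(a.mean() - b.mean())
                df = na + nb - 2
            else:
                t = (a.mean() - b.mean()) / denom
                df = (va / na + vb / nb) ** 2 / (
                    (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        else:
            sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            df = na + nb - 2
            if sp2 == 0:
                t = 0.0 if a.mean() == b.mean() else np.inf * np.sign(a.mean() - b.mean())
            else:
                t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    if np.isinf(t):
        p = 0.0
    else:
        p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p), significance_label(p)


def aggregate(values, experiment_labels=None, level: str = "cells",
              label: str = "", unit: str = "percent_cfret") -> GroupSummary:
    """Summarize per-cell values at the cell or experiment level.

    ``level="cells"``: mean and sd over individual cells.
    ``level="experiments"``: per-experiment means first, then mean +/- s.e.m.
    over experiments (requires experiment labels).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise StatisticsError("empty sample")
    n_cells = int(values.size)
    if level == "cells":
        sd = float(values.std(ddof=1)) if n_cells > 1 else 0.0
        n_exp = (int(len(np.unique(experiment_labels)))
                 if experiment_labels is not None else 1)
        return GroupSummary(label=label, n_cells=n_cells, n_experiments=n_exp,
                            mean=float(values.mean()), sd=sd,
                            sem=sd / np.sqrt(n_cells), unit=unit)
    if level == "experiments":
        if experiment_labels is None:
            raise StatisticsError("experiment labels required at level='experiments'")
        df = pd.DataFrame({"v": values, "exp": list(experiment_labels)})
        per_exp = df.groupby("exp")["v"].mean().to_numpy()
        n_exp = len(per_exp)
        sd = float(per_exp.std(ddof=1)) if n_exp > 1 else 0.0
        return GroupSummary(label=label, n_cells=n_cells, n_experiments=n_exp,
                            mean=float(per_exp.mean()), sd=sd,
                            sem=sd / np.sqrt(n_exp), unit=unit)
    raise ParameterError(f"unknown aggregation level {level!r}")


def compare_conditions(tcs, window_a: dict, window_b: dict):
    """Paired comparison of two condition windows across cells.

    ``window_a``/``window_b`` are dicts with keys ``condition``, ``which``
    (first_k/last_k) and ``k``, resolved per cell via
    :func:`cubefret.sefret.condition_window_mean`; the same cells contribute
    to both windows, so the test is paired.

    Returns ``(summary_a, summary_b, (t, df, p, label))``.
    """
    a_vals, b_vals = [], []
    for tc in tcs:
        a_vals.append(condition_window_mean(tc, **window_a))
        b_vals.append(condition_window_mean(tc, **window_b))
    if len(a_vals) < 2:
        raise StatisticsError("need >= 2 cells for a paired comparison")
    test = two_tailed_t(a_vals, b_vals, paired=True)
    sa = aggregate(a_vals, label=str(window_a.get("condition")))
    sb = aggregate(b_vals, label=str(window_b.get("condition")))
    return sa, sb, test
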