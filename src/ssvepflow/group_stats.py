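"""Condition-level inference for the repeated-measures study design.

One value per subject and condition (a model parameter or an aggregated PDC
flow) enters a one-way repeated-measures ANOVA.  Sphericity is handled with
the Greenhouse-Geisser correction: the usual F statistic is referred to an
F distribution with both degrees of freedom scaled by epsilon, the
sphericity index of the double-centred condition covariance matrix
(epsilon = 1 under compound symmetry, 1/(k-1) at maximal non-sphericity).
Post-hoc comparisons are two-sided paired t tests of a reference condition
against each other condition, Bonferroni-corrected over the tested pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ConditionTable",
    "AnovaResult",
    "PairedComparison",
    "DegenerateDataError",
    "rm_anova_gg",
    "gg_epsilon",
    "posthoc_paired_bonferroni",
]


class DegenerateDataError(ValueError):
    """Raised when the design has no within-cell variance at all."""


@dataclass(frozen=True)
class ConditionTable:
    """Complete subjects x conditions matrix of one measure."""

    values: np.ndarray
    subjects: tuple
    conditions: tuple

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        subjects = tuple(str(s) for s in self.subjects)
        conditions = tuple(str(c) for c in self.conditions)
        if v.ndim != 2 or v.shape != (len(subjects), len(conditions)):
            raise ValueError(
                f"values shape {v.shape} does not match {len(subjects)} subjects "
                f"x {len(conditions)} conditions"
            )
        if v.shape[0] < 2 or v.shape[1] < 2:
            raise ValueError("need at least 2 subjects and 2 conditions")
        if not np.isfinite(v).all():
            raise ValueError("repeated-measures design must be complete (no missing cells)")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "subjects", subjects)
        object.__setattr__(self, "conditions", conditions)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ConditionTable":
        """Rows are subjects, columns are conditions."""
        return cls(df.to_numpy(dtype=float), tuple(df.index), tuple(df.columns))

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_num: float
    df_den: float
    epsilon: float
    p_uncorrected: float
    p_gg: float
    ss_effect: float
    ss_error: float

    def as_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in (
            "F", "df_num", "df_den", "epsilon", "p_uncorrected", "p_gg",
            "ss_effect", "ss_error",
        )}


@dataclass(frozen=True)
class PairedComparison:
    pair: tuple
    t: float
    df: int
    p_raw: float
    p_corrected: float
    undefined: bool = False

    def as_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "t": None if self.undefined else float(self.t),
            "df": self.df,
            "p_raw": None if self.undefined else float(self.p_raw),
            "p_corrected": None if self.undefined else float(self.p_corrected),
            "undefined": self.undefined,
        }


def gg_epsilon(table: ConditionTable) -> float:
    """Greenhouse-Geisser epsilon of the double-centred condition covariance.

    epsilon = (sum lambda)^2 / ((k-1) sum lambda^2) over the eigenvalues of
    C S C with C the centring matrix; bounded by [1/(k-1), 1].  A singular
    (all-zero) centred covariance yields the lower bound with a warning.
    """
    k = table.n_conditions
    S = np.cov(table.values, rowvar=False, ddof=1)
    C = np.eye(k) - np.ones((k, k)) / k
    M = C @ S @ C
    tr2 = np.trace(M @ M)
    if tr2 <= 0 or not np.isfinite(tr2):
        warnings.warn(
            "singular condition covariance; returning the epsilon lower bound",
            RuntimeWarning,
            stacklevel=2,
        )
        return 1.0 / (k - 1)
    eps = np.trace(M) ** 2 / ((k - 1) * tr2)
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def rm_anova_gg(table: ConditionTable) -> AnovaResult:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction.

    F = MS_conditions / MS_error with df (k-1, (k-1)(n-1)); the corrected
    p value refers F to df scaled by epsilon.  A design with zero within-cell
    variance everywhere raises :class:`DegenerateDataError`; a zero effect
    sum of squares returns F = 0 directly.
    """
    y = table.values
    n, k = y.shape
    grand = y.mean()
    subj = y.mean(axis=1, keepdims=True)
    cond = y.mean(axis=0, keepdims=True)
    ss_effect = float(n * ((cond - grand) ** 2).sum())
    ss_error = float(((y - subj - cond + grand) ** 2).sum())
    df_num = k - 1
    df_den = (k - 1) * (n - 1)
    if ss_effect == 0.0:
        return AnovaResult(0.0, df_num, df_den, 1.0, 1.0, 1.0, 0.0, ss_error)
    if ss_error == 0.0:
        raise DegenerateDataError(
            "no residual (subject x condition) variance; F is undefined"
        )
    F = (ss_effect / df_num) / (ss_error / df_den)
    eps = gg_epsilon(table)
    p_unc = float(sps.f.sf(F, df_num, df_den))
    p_gg = float(sps.f.sf(F, eps * df_num, eps * df_den))
    return AnovaResult(float(F), df_num, df_den, eps, p_unc, p_gg, ss_effect, ss_error)


def posthoc_paired_bonferroni(table: ConditionTable, reference) -> list:
    """Two-sided paired t tests of ``reference`` against each other
    condition; p values are Bonferroni-corrected by the number of tested
    pairs (min(1, m * p)).  A zero-variance, zero-mean difference gives
    t = 0 / p = 1; a zero-variance, non-zero-mean difference is flagged
    undefined."""
    reference = str(reference)
    if reference not in table.conditions:
        raise ValueError(
            f"reference {reference!r} not among conditions {table.conditions}"
        )
    ref = table.values[:, table.conditions.index(reference)]
    others = [c for c in table.conditions if c != reference]
    m = len(others)
    n = table.n_subjects
    out = []
    for c in others:
        d = ref - table.values[:, table.conditions.index(c)]
        sd = d.std(ddof=1)
        if sd == 0.0:
            if d.mean() == 0.0:
                out.append(PairedComparison((reference, c), 0.0, n - 1, 1.0, 1.0))
            else:
                out.append(
                    PairedComparison((reference, c), np.nan, n - 1, np.nan, np.nan, True)
                )
            continue
        t = d.mean() / (sd / np.sqrt(n))
        p = 2.0 * float(sps.t.sf(abs(t), n - 1))
        out.append(
            PairedComparison((reference, c), float(t), n - 1, p, min(1.0, m * p))
        )
    return out
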