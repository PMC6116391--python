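"""DerSimonian–Laird random-effects meta-analysis of correlations.

Because the Discovery and Validation cohorts were profiled on different
platforms, per-cohort correlations are pooled by meta-analysis instead of
pooling the raw samples.  Each study contributes (r_i, n_i); correlations
are mapped to the Fisher z-scale, z_i = atanh(r_i), where the sampling
variance is the closed form 1/(n_i − 3).  Between-study variance τ² is the
DerSimonian–Laird moment estimator from the heterogeneity statistic Q, and
the pooled z is the inverse-variance weighted mean with weights
1/(v_i + τ²).  The pooled estimate and its 95 % CI are reported back on the
correlation scale via tanh.

The primary p-value is the one-sided upper-tail normal probability of
z_pooled/SE — the convention of correlation meta-analysis tooling in this
literature — with the two-sided value always available alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["StudyCorrelation", "MetaResult", "fisher_z", "inverse_fisher_z",
           "dsl_meta", "meta_scan"]


def fisher_z(r):
    """Fisher z-transform, atanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if (np.abs(r) >= 1).any():
        raise ValueError("|r| must be < 1 for the Fisher transform")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def inverse_fisher_z(z):
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class StudyCorrelation:
    label: str
    r: float
    n: int

    def __post_init__(self):
        if not -1 < self.r < 1:
            raise ValueError(f"correlation must lie in (-1, 1), got {self.r}")
        if self.n < 4:
            raise ValueError(f"study {self.label!r}: n must be >= 4 "
                             "(Fisher-z variance 1/(n-3))")


@dataclass
class MetaResult:
    k: int
    z_pooled: float
    se_pooled: float
    r_pooled: float
    ci95: tuple
    Q: float
    tau2: float
    p_one_sided: float
    p_two_sided: float


def dsl_meta(studies: Sequence[StudyCorrelation]) -> MetaResult:
    """Pool k >= 2 study correlations by DerSimonian–Laird on the z-scale.

    With a single study the estimate passes through unchanged (τ²=0, Q=0)
    and a ``UserWarning`` is issued.
    """
    if len(studies) == 0:
        raise ValueError("no studies supplied")
    if len(studies) == 1:
        import warnings
        warnings.warn("single study: meta-analysis is a pass-through")
    z = np.array([fisher_z(s.r) for s in studies])
    n = np.array([s.n for s in studies], dtype=float)
    v = 1.0 / (n - 3.0)
    w = 1.0 / v
    k = len(studies)
    z_fixed = float((w * z).sum() / w.sum())
    Q = float((w * (z - z_fixed) ** 2).sum())
    if k > 1:
        C = w.sum() - (w ** 2).sum() / w.sum()
        tau2 = max(0.0, (Q - (k - 1)) / C)
    else:
        tau2 = 0.0
    w_star = 1.0 / (v + tau2)
    z_pooled = float((w_star * z).sum() / w_star.sum())
    se = float(1.0 / np.sqrt(w_star.sum()))
    r_pooled = inverse_fisher_z(z_pooled)
    ci = (inverse_fisher_z(z_pooled - 1.96 * se),
          inverse_fisher_z(z_pooled + 1.96 * se))
    p1 = float(stats.norm.sf(z_pooled / se))
    return MetaResult(k, z_pooled, se, r_pooled, ci, Q, tau2,
                      p1, min(1.0, 2.0 * p1))


def meta_scan(cohort_tables: dict, key_cols=("predictor", "response", "contrast"),
              r_col: str = "r", n_col: str = "n") -> pd.DataFrame:
    """Pool matched association rows across cohorts.

    ``cohort_tables`` maps cohort label -> DataFrame with key columns plus
    signed correlation ``r`` and sample size ``n``.  Keys present in every
    cohort are pooled with :func:`dsl_meta`; keys present in a subset are
    emitted unpooled with ``pooled=False``.  Duplicate keys within one
    cohort are an error.
    """
    key_cols = list(key_cols)
    frames = []
    for label, df in cohort_tables.items():
        cols = [c for c in key_cols if c in df.columns]
        if df.duplicated(subset=cols).any():
            raise ValueError(f"duplicate association keys in cohort {label!r}")
        sub = df[cols + [r_col, n_col]].copy()
        sub["cohort"] = label
        frames.append(sub)
    combined = pd.concat(frames, ignore_index=True)
    used_keys = [c for c in key_cols if c in combined.columns]
    n_cohorts = len(cohort_tables)
    rows = []
    for key, grp in combined.groupby(used_keys, dropna=False, sort=False):
        key = key if isinstance(key, tuple) else (key,)
        rec = dict(zip(used_keys, key))
        rec["k"] = len(grp)
        if len(grp) < n_cohorts or len(grp) < 2:
            rec.update(pooled=False, r_pooled=float(grp[r_col].iloc[0]),
                       ci_low=np.nan, ci_high=np.nan, Q=np.nan, tau2=np.nan,
                       p_one_sided=np.nan, p_two_sided=np.nan)
        else:
            studies = [StudyCorrelation(str(c), float(r), int(n))
                       for c, r, n in zip(grp["cohort"], grp[r_col], grp[n_col])]
            m = dsl_meta(studies)
            rec.update(pooled=True, r_pooled=m.r_pooled, ci_low=m.ci95[0],
                       ci_high=m.ci95[1], Q=m.Q, tau2=m.tau2,
                       p_one_sided=m.p_one_sided, p_two_sided=m.p_two_sided)
        rows.append(rec)
    return pd.DataFrame(rows)
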