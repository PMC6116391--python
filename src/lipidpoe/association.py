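"""Per-cohort association statistics and the parent-of-origin contrast battery.

The follow-up of a screened (SNP, lipid) candidate runs five univariate
contrasts against the lipid's normalized intensity: the maternally
transmitted fetal allele, the paternally transmitted fetal allele, the fetal
genotype (additive), the maternal genotype (additive) and the maternal
untransmitted allele.  Comparing their effect sizes separates fetally
mediated, imprinted effects from effects of the maternal genome itself:
a fetal imprinted effect shows up in one transmitted-allele contrast only,
while a maternal-genome effect shows up at least as strongly in the maternal
genotype and the untransmitted-allele contrasts.

Clinical utilities (HOMA indices, summary-statistics group tests, logistic
and covariate-adjusted regression) support the glycaemia follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "AssociationResult",
    "correlate",
    "adjusted_regression",
    "logistic",
    "homa",
    "summary_group_test",
    "PoeContrastSet",
    "poe_classify",
    "maternal_transmission_enrichment",
]

# pmol/L per mU/L, WHO conversion for insulin
INSULIN_PMOL_PER_MU = 6.945


@dataclass
class AssociationResult:
    """One predictor-response association.

    ``r`` is the Pearson correlation magnitude (printed tables are unsigned
    because the allele coding direction is arbitrary); ``sign`` keeps the
    direction for meta-analytic harmonization.
    """

    predictor: str
    response: str
    r: float
    sign: int
    p: float
    n: int
    beta_std: Optional[float] = None
    covariates: tuple = ()

    @property
    def signed_r(self) -> float:
        return self.sign * self.r


def _complete_pairs(x, y):
    x = pd.to_numeric(pd.Series(np.asarray(x, dtype=float).ravel()), errors="coerce")
    y = pd.to_numeric(pd.Series(np.asarray(y, dtype=float).ravel()), errors="coerce")
    mask = x.notna() & y.notna()
    return x[mask].to_numpy(), y[mask].to_numpy()


def correlate(x, y, predictor: str = "x", response: str = "y") -> AssociationResult:
    """Pearson correlation with the exact two-sided t-test p-value.

    Masked (NaN) entries are dropped pairwise; ``n`` is the number of
    complete pairs.  Zero variance in either variable is an error.  An exact
    zero correlation reports p = 1 by convention.
    """
    xv, yv = _complete_pairs(x, y)
    n = xv.size
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("zero variance in x or y; correlation undefined")
    r = float(np.corrcoef(xv, yv)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    p = correlation_pvalue(r, n)
    return AssociationResult(predictor, response, abs(r),
                             int(np.sign(r)) or 1, p, n)


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation via the Student-t transform."""
    if n < 3:
        raise ValueError("n must be >= 3")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def adjusted_regression(y, x, covariates: Optional[pd.DataFrame] = None,
                        predictor: str = "x",
                        response: str = "y") -> AssociationResult:
    """OLS of ``y`` on ``x`` plus covariates, with a standardized slope.

    With no covariates this reduces exactly to :func:`correlate` (identical
    p-value).  ``beta_std`` is slope * sd(x)/sd(y).  Rank deficiency raises
    with the offending columns listed.
    """
    y = pd.Series(np.asarray(y, dtype=float).ravel(), name=response)
    x = pd.Series(np.asarray(x, dtype=float).ravel(), name=predictor)
    df = pd.concat([y, x], axis=1)
    cov_names: tuple = ()
    if covariates is not None and len(covariates.columns):
        cov = covariates.reset_index(drop=True).astype(float)
        cov_names = tuple(cov.columns)
        df = pd.concat([df, cov], axis=1)
    df = df.dropna()
    if len(df) < len(df.columns) + 1:
        raise ValueError("too few complete cases for the design")
    X = sm.add_constant(df.drop(columns=response))
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(f"rank-deficient design; check columns {list(X.columns)}")
    fit = sm.OLS(df[response], X).fit()
    slope = float(fit.params[predictor])
    p = float(fit.pvalues[predictor])
    beta_std = slope * df[predictor].std(ddof=1) / df[response].std(ddof=1)
    r_equiv = abs(beta_std) if not cov_names else np.nan
    if not cov_names:
        r_equiv = abs(float(np.corrcoef(df[predictor], df[response])[0, 1]))
    return AssociationResult(predictor, response, r_equiv,
                             int(np.sign(slope)) or 1, p, len(df),
                             beta_std=float(beta_std), covariates=cov_names)


def logistic(outcome, x, predictor: str = "x"):
    """Maximum-likelihood logistic fit; returns (OR, (lo, hi), p).

    Perfect separation is flagged by raising ``ValueError`` rather than
    returning a divergent estimate.
    """
    xv, yv = _complete_pairs(x, outcome)
    if len(np.unique(yv)) != 2:
        raise ValueError("outcome must have both classes present")
    X = sm.add_constant(xv)
    try:
        fit = sm.Logit(yv, X).fit(disp=0)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
        raise ValueError(f"logistic fit failed (separation?): {exc}") from None
    if not np.isfinite(fit.bse[1]) or fit.bse[1] > 1e3 * max(1.0, abs(fit.params[1])):
        raise ValueError("perfect or quasi-perfect separation; no stable estimate")
    slope, se = fit.params[1], fit.bse[1]
    or_ = float(np.exp(slope))
    ci = (float(np.exp(slope - 1.96 * se)), float(np.exp(slope + 1.96 * se)))
    return or_, ci, float(fit.pvalues[1])


def homa(glucose_mmol_l, insulin_pmol_l,
         insulin_conversion: float = INSULIN_PMOL_PER_MU):
    """HOMA1 insulin-resistance and beta-cell indices from fasting values.

    Insulin in pmol/L is converted to mU/L (divide by ``insulin_conversion``),
    then HOMA-IR = G*I/22.5 and HOMA-B = 20*I/(G-3.5).  These are the HOMA1
    closed forms, a documented approximation to the iterative HOMA2
    calculator (HOMA2 values run systematically lower).  HOMA-B is undefined
    (NaN) at glucose <= 3.5 mmol/L.
    """
    G = np.asarray(glucose_mmol_l, dtype=float)
    I_mu = np.asarray(insulin_pmol_l, dtype=float) / insulin_conversion
    if (G <= 0).any() or (I_mu < 0).any():
        raise ValueError("glucose must be positive and insulin non-negative")
    ir = G * I_mu / 22.5
    with np.errstate(divide="ignore", invalid="ignore"):
        b = np.where(G > 3.5, 20.0 * I_mu / (G - 3.5), np.nan)
    if np.isscalar(glucose_mmol_l) and np.isscalar(insulin_pmol_l):
        return float(ir), float(b)
    return ir, b


def summary_group_test(mean1, ci1, n1, mean2, ci2, n2):
    """Two-group z-test from printed means and symmetric 95 % CIs.

    Standard errors are recovered as CI half-width / 1.96; the statistic is
    the difference in means over the pooled SE, with a two-sided normal p.
    """
    se1 = (ci1[1] - ci1[0]) / 2.0 / 1.96
    se2 = (ci2[1] - ci2[0]) / 2.0 / 1.96
    pooled = np.hypot(se1, se2)
    if pooled <= 0:
        raise ValueError("zero pooled standard error")
    z = (mean1 - mean2) / pooled
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


CONTRAST_NAMES = ("maternal_transmitted", "paternal_transmitted",
                  "fetal_genotype", "maternal_genotype",
                  "maternal_untransmitted")

POE_CLASSES = ("fetal-effect-imprinted-maternal", "fetal-effect-imprinted-paternal",
               "fetal-biallelic", "maternal-mediated", "indeterminate")


@dataclass
class PoeContrastSet:
    """The five contrasts for one (SNP, species) pair.

    Any comparator may be None when not computable (e.g. too few informative
    trios); the transmitted-allele contrast of interest is required.
    """

    snp_id: str
    species: str
    maternal_transmitted: Optional[AssociationResult] = None
    paternal_transmitted: Optional[AssociationResult] = None
    fetal_genotype: Optional[AssociationResult] = None
    maternal_genotype: Optional[AssociationResult] = None
    maternal_untransmitted: Optional[AssociationResult] = None
    classification: str = "indeterminate"
    rationale: str = ""


def poe_classify(contrasts: PoeContrastSet, alpha: float = 0.05) -> str:
    """Classify a contrast battery as fetal/imprinted, biallelic or maternal.

    Decision rules, applied in order:

    1. both transmitted-allele contrasts significant -> ``fetal-biallelic``;
    2. one transmitted contrast significant, with correlation magnitude
       exceeding both the maternal-genotype and untransmitted-allele
       magnitudes, and the other parent's contrast non-significant ->
       ``fetal-effect-imprinted-<parent>``;
    3. maternal-genotype or untransmitted contrast significant with magnitude
       at least matching the best transmitted contrast ->
       ``maternal-mediated``;
    4. otherwise ``indeterminate``.

    The classification and a human-readable rationale are stored on the
    input and the label returned.
    """
    mat, pat = contrasts.maternal_transmitted, contrasts.paternal_transmitted
    if mat is None and pat is None:
        raise ValueError("need at least one transmitted-allele contrast")

    def sig(res):
        return res is not None and res.p < alpha

    def mag(res):
        return 0.0 if res is None else res.r

    comparators = [contrasts.maternal_genotype, contrasts.maternal_untransmitted]
    max_comp = max((mag(c) for c in comparators), default=0.0)
    best_trans = max(mag(mat), mag(pat))

    if sig(mat) and sig(pat):
        label, why = "fetal-biallelic", (
            "both parentally transmitted alleles associate significantly")
    elif sig(mat) and mag(mat) > max_comp and not sig(pat):
        label, why = "fetal-effect-imprinted-maternal", (
            "maternally transmitted allele dominates; paternal contrast null; "
            "maternal genotype and untransmitted allele weaker")
    elif sig(pat) and mag(pat) > max_comp and not sig(mat):
        label, why = "fetal-effect-imprinted-paternal", (
            "paternally transmitted allele dominates; maternal contrast null; "
            "maternal genotype and untransmitted allele weaker")
    elif any(sig(c) and mag(c) >= best_trans for c in comparators):
        label, why = "maternal-mediated", (
            "maternal genome contrast at least as strong as any transmitted-"
            "allele contrast")
    else:
        label, why = "indeterminate", "no contrast pattern reaches the rules"
    contrasts.classification = label
    contrasts.rationale = why
    return label


def maternal_transmission_enrichment(candidates: Sequence) -> dict:
    """Exact binomial test for excess maternal-transmission candidates.

    ``candidates`` is any sequence with a ``transmission`` attribute or key
    per element ("maternal" / "paternal").  Tests the maternal count against
    Binomial(k, 1/2); both one-sided (maternal excess) and two-sided exact
    p-values are reported, since the construction of the published test is
    ambiguous.
    """
    def trans(c):
        if hasattr(c, "transmission"):
            return c.transmission
        return c["transmission"]
    labels = [trans(c) for c in candidates]
    if not labels:
        raise ValueError("empty candidate list")
    n_mat = sum(1 for t in labels if t == "maternal")
    n_pat = sum(1 for t in labels if t == "paternal")
    k = n_mat + n_pat
    res_two = stats.binomtest(n_mat, k, 0.5)
    res_one = stats.binomtest(n_mat, k, 0.5, alternative="greater")
    return {"n_maternal": n_mat, "n_paternal": n_pat,
            "p_two_sided": float(res_two.pvalue),
            "p_one_sided": float(res_one.pvalue)}
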