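"""Lipid peak-table quality control and normalization.

A peak table is a samples x lipid-species intensity matrix from direct
infusion or LC-MS profiling, annotated with sample roles: study samples,
a pooled quality-control series at known relative concentrations
(QC1 undiluted, QC2 diluted 1:1 with PBS, QC3 diluted 1:4 -> relative
concentrations 1.0 / 0.5 / 0.2), quality-assurance plasma (QA) and blanks.

Screening-grade filtering keeps a species only if

* it is detected (above the limit of detection) in strictly more than 70 %
  of the study samples, and
* its mean QC intensities scale linearly with the dilution series
  (Pearson r above a threshold, with positive slope).

Normalization then maps raw intensities to analysis scale: per-sample
median scaling (removes overall abundance/injection differences), log10
transform, and per-species mean centring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

QC_RELATIVE_CONCENTRATION = {"QC1": 1.0, "QC2": 0.5, "QC3": 0.2}
SAMPLE_ROLES = ("study", "QC1", "QC2", "QC3", "QA", "blank")

__all__ = [
    "PeakTable",
    "detection_filter",
    "qc_linearity_filter",
    "impute_below_lod",
    "normalize",
    "preprocess",
    "read_peak_table",
]


@dataclass
class PeakTable:
    """Samples x species intensity matrix with role annotations.

    ``intensities`` is indexed by sample id with one column per species;
    non-detected (below-LOD) measurements are stored as 0 or NaN.  ``roles``
    maps each sample id onto one of :data:`SAMPLE_ROLES`.  ``lod`` is a
    per-species detection limit (Series) or a global scalar; intensities at
    or below the LOD count as non-detected.
    """

    intensities: pd.DataFrame
    roles: pd.Series
    lod: object = 0.0
    qc_relative_concentration: dict = field(
        default_factory=lambda: dict(QC_RELATIVE_CONCENTRATION))

    def __post_init__(self):
        self.roles = self.roles.reindex(self.intensities.index)
        if self.roles.isna().any():
            missing = list(self.roles.index[self.roles.isna()])[:5]
            raise ValueError(f"samples without a role annotation: {missing}")
        bad = set(self.roles.unique()) - set(SAMPLE_ROLES)
        if bad:
            raise ValueError(f"unknown sample roles: {sorted(bad)}")

    @property
    def species(self) -> pd.Index:
        return self.intensities.columns

    def lod_vector(self) -> pd.Series:
        if np.isscalar(self.lod):
            return pd.Series(float(self.lod), index=self.species)
        return pd.Series(self.lod).reindex(self.species).fillna(0.0)

    def detected(self) -> pd.DataFrame:
        """Boolean detection mask (strictly above LOD and not NaN)."""
        return self.intensities.gt(self.lod_vector(), axis=1).fillna(False)

    def samples_with_role(self, role: str) -> pd.Index:
        return self.intensities.index[self.roles == role]

    def study_samples(self) -> pd.Index:
        return self.samples_with_role("study")

    def subset_species(self, species) -> "PeakTable":
        return PeakTable(self.intensities[list(species)], self.roles,
                         self.lod, dict(self.qc_relative_concentration))


def detection_filter(table: PeakTable, min_fraction: float = 0.70) -> pd.DataFrame:
    """Flag species detected in strictly more than ``min_fraction`` of study
    samples.

    QC, QA and blank samples are excluded from the denominator.  Returns a
    per-species report with columns ``detect_fraction``, ``retained``,
    ``reason``.
    """
    if not 0.0 < min_fraction < 1.0:
        raise ValueError(f"min_fraction must be in (0, 1), got {min_fraction}")
    study = table.study_samples()
    if len(study) == 0:
        raise ValueError("peak table contains no study samples")
    frac = table.detected().loc[study].mean(axis=0)
    retained = frac > min_fraction
    return pd.DataFrame({
        "species_id": table.species,
        "detect_fraction": frac.values,
        "retained": retained.values,
        "reason": np.where(retained, "",
                           f"detected in <= {min_fraction:.0%} of study samples"),
    }).set_index("species_id")


def qc_linearity_filter(table: PeakTable, r_min: float = 0.9) -> pd.DataFrame:
    """Flag species whose mean QC intensity tracks the dilution series.

    Per species the mean intensity at each QC level is correlated (Pearson)
    against the relative concentrations; the species passes iff
    ``r > r_min`` and the least-squares slope is positive.  Species with
    constant QC response are failed as degenerate.
    """
    levels = [lv for lv in table.qc_relative_concentration
              if len(table.samples_with_role(lv)) > 0]
    if len(levels) < 2:
        raise ValueError("need QC samples at >= 2 dilution levels")
    conc = np.array([table.qc_relative_concentration[lv] for lv in levels])
    means = np.vstack([
        table.intensities.loc[table.samples_with_role(lv)].mean(axis=0).values
        for lv in levels
    ])  # levels x species
    rows = []
    for j, sp in enumerate(table.species):
        y = means[:, j]
        if np.allclose(y, y[0]) or np.isnan(y).any():
            rows.append((sp, np.nan, np.nan, False, "degenerate QC"))
            continue
        slope = np.polyfit(conc, y, 1)[0]
        r = stats.pearsonr(conc, y).statistic
        ok = (r > r_min) and (slope > 0)
        reason = "" if ok else (
            "non-positive QC dilution slope" if slope <= 0
            else f"QC dilution r <= {r_min}")
        rows.append((sp, r, slope, ok, reason))
    return pd.DataFrame(rows, columns=["species_id", "qc_dilution_r",
                                       "qc_slope", "retained", "reason"]
                        ).set_index("species_id")


def impute_below_lod(table: PeakTable, rule: str = "half-min") -> PeakTable:
    """Replace non-detected entries so the log transform is defined.

    ``half-min`` substitutes half the minimum detected intensity of the
    species; ``lod-over-sqrt2`` substitutes LOD/sqrt(2).  A species with no
    detected value at all should have been removed by the detection filter
    and raises a consistency error.
    """
    if rule not in ("half-min", "lod-over-sqrt2"):
        raise ValueError(f"unknown below-LOD rule {rule!r}")
    detected = table.detected()
    X = table.intensities.copy()
    lod = table.lod_vector()
    for sp in table.species:
        mask = ~detected[sp]
        if not mask.any():
            continue
        if mask.all():
            raise ValueError(
                f"species {sp!r} has no detected values; run detection_filter first")
        if rule == "half-min":
            fill = X.loc[detected[sp], sp].min() / 2.0
        else:
            fill = lod[sp] / np.sqrt(2.0)
            if fill <= 0:
                fill = X.loc[detected[sp], sp].min() / 2.0
        X.loc[mask, sp] = fill
    return PeakTable(X, table.roles, table.lod,
                     dict(table.qc_relative_concentration))


def normalize(table: PeakTable, log_base: float = 10.0) -> pd.DataFrame:
    """Median-scale, log-transform and mean-centre the study samples.

    Steps: (1) divide every study sample row by its own median intensity
    over the retained species, (2) log (base ``log_base``), (3) subtract the
    per-species mean.  Output columns therefore have zero mean.  Samples with
    a non-positive median (pathological, e.g. mostly-zero rows) are dropped
    with a ``UserWarning``.
    """
    X = table.intensities.loc[table.study_samples()].astype(float)
    if (X <= 0).any().any() or X.isna().any().any():
        raise ValueError("non-positive or missing intensities; apply "
                         "impute_below_lod before normalize")
    medians = X.median(axis=1)
    bad = medians <= 0
    if bad.any():
        import warnings
        warnings.warn(f"dropping {int(bad.sum())} sample(s) with non-positive "
                      "median intensity")
        X, medians = X.loc[~bad], medians[~bad]
    X = X.div(medians, axis=0)
    X = np.log(X) / np.log(log_base)
    return X - X.mean(axis=0)


def preprocess(table: PeakTable, min_fraction: float = 0.70,
               r_min: float = 0.9, lod_rule: str = "half-min",
               require_qc: bool = True, log_base: float = 10.0):
    """Full screening preprocessing chain.

    Runs the detection filter, the QC linearity filter (skipped with a note
    when no QC samples are present and ``require_qc`` is False), below-LOD
    imputation, and normalization.  Returns ``(normalized, report)`` where
    ``report`` is the per-species filter table.
    """
    det = detection_filter(table, min_fraction)
    has_qc = any(len(table.samples_with_role(lv)) > 0
                 for lv in table.qc_relative_concentration)
    if has_qc:
        qc = qc_linearity_filter(table, r_min)
    elif require_qc:
        raise ValueError("peak table has no QC dilution samples")
    else:
        qc = pd.DataFrame({"qc_dilution_r": np.nan, "qc_slope": np.nan,
                           "retained": True, "reason": "no QC samples"},
                          index=table.species)
    report = det.join(qc, lsuffix="_det")
    report["retained"] = det["retained"] & qc["retained"]
    report["reason"] = (det["reason"].where(det["reason"] != "", qc["reason"]))
    kept = report.index[report["retained"]]
    if len(kept) == 0:
        raise ValueError("no species survived filtering")
    filtered = table.subset_species(kept)
    filtered = impute_below_lod(filtered, lod_rule)
    return normalize(filtered, log_base=log_base), report


def read_peak_table(path, zero_is_missing: bool = True) -> PeakTable:
    """Read the peak-table CSV dialect: sample_id, sample_role, species...

    Empty cells (and zeros, unless ``zero_is_missing`` is False) encode
    below-LOD measurements and are stored as 0.
    """
    df = pd.read_csv(path, comment="#")
    if df.columns[0] != "sample_id" or df.columns[1] != "sample_role":
        raise ValueError("peak table must start with sample_id, sample_role")
    roles = df.set_index("sample_id")["sample_role"]
    X = df.set_index("sample_id").drop(columns="sample_role").astype(float)
    X = X.fillna(0.0)
    if not zero_is_missing:
        # zeros are genuine intensities only in exotic dialects; keep as-is
        pass
    return PeakTable(X, roles)
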