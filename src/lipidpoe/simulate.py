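"""Synthetic trio-genotype, lipidome and clinical data generation.

No raw cohort data accompany the study design this package implements, so
every pipeline stage is exercised against simulated data with the same
statistical structure:

* founder genotypes drawn under Hardy–Weinberg equilibrium at a per-SNP
  minor-allele frequency, children by fair Mendelian transmission, with the
  true transmitted alleles retained in a hidden truth table;
* log-normal lipid intensities with a per-sample scale factor (removed by
  median normalization), allele effects added on the log scale under
  maternal-only / paternal-only / biallelic / maternal-genome expression
  modes, below-detection censoring at a global intensity quantile, and a
  pooled-QC dilution series at relative concentrations 1.0 / 0.5 / 0.2;
* clinical outcomes (OGTT glucose, fasting insulin, HOMA indices, BMI,
  gestational age, parity, sex, GDM flag) whose glycaemic variables
  correlate with a chosen lipid species on the log scale.

Defaults mirror the emulated study: 767 families split 200/567 into
Discovery and Validation cohorts, 151 SNPs, 173 lipid species, one
maternally expressed causal SNP with a standardized log-scale effect.
Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .association import homa
from .preprocess import PeakTable
from .trio import MAJOR, MINOR, format_genotype

__all__ = ["EffectSpec", "ClinicalLink", "SimConfig", "SimData",
           "simulate_trios", "simulate_lipidome", "simulate_clinical",
           "simulate_dataset"]

MODES = ("maternal-only", "paternal-only", "biallelic", "maternal-genome")


@dataclass(frozen=True)
class EffectSpec:
    """One allele -> lipid effect: standardized size d under an expression mode."""

    snp: int
    species: int
    d: float
    mode: str = "maternal-only"

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown expression mode {self.mode!r}")
        if not np.isfinite(self.d):
            raise ValueError("effect size must be finite")


@dataclass(frozen=True)
class ClinicalLink:
    """Correlation of log glycaemic variables with one lipid species."""

    species: int
    rho_glucose: float = 0.1
    rho_insulin: float = 0.1


@dataclass
class SimConfig:
    seed: int
    n_families: int = 767
    n_snps: int = 151
    maf: Optional[np.ndarray] = None  # default: U(0.05, 0.5) per SNP
    n_species: int = 173
    effects: Sequence[EffectSpec] = field(
        default_factory=lambda: (EffectSpec(0, 0, 0.3, "maternal-only"),))
    baseline_log_mean_range: tuple = (2.5, 4.0)  # log10 a.u.
    baseline_log_sd: float = 0.25
    sample_scale_sd: float = 0.10  # per-sample log10 scale factor
    lod_quantile: float = 0.05
    qc_replicates: int = 4
    qc_noise_sd: float = 0.02
    n_blank: int = 6
    n_qa: int = 6
    clinical_link: ClinicalLink = field(default_factory=lambda: ClinicalLink(0))
    glucose_mean: float = 4.3   # mmol/L, fasting
    glucose_log_sd: float = 0.10
    glucose60_mean: float = 6.5
    glucose60_log_sd: float = 0.20
    insulin_mean: float = 45.0  # pmol/L
    insulin_log_sd: float = 0.45
    gdm_fasting_threshold: float = 5.1   # mmol/L (IADPSG fasting criterion)
    gdm_60min_threshold: float = 10.0
    cohort_fractions: tuple = (200 / 767, 567 / 767)
    cohort_labels: tuple = ("Discovery", "Validation")

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if abs(sum(self.cohort_fractions) - 1.0) > 1e-9:
            raise ValueError("cohort fractions must sum to 1")
        for e in self.effects:
            if not (0 <= e.snp < self.n_snps and 0 <= e.species < self.n_species):
                raise ValueError(f"effect {e} indexes outside the simulated grid")

    def resolve_maf(self, rng) -> np.ndarray:
        if self.maf is not None:
            maf = np.asarray(self.maf, dtype=float)
            if maf.shape != (self.n_snps,):
                raise ValueError("maf must have one entry per SNP")
        else:
            maf = rng.uniform(0.05, 0.5, size=self.n_snps)
        if ((maf < 0.0) | (maf > 0.5)).any():
            raise ValueError("minor-allele frequencies must lie in [0, 0.5]")
        return maf


@dataclass
class SimData:
    """Bundle of simulated inputs plus the hidden truth."""

    config: SimConfig
    trios: pd.DataFrame          # long genotype table (strings)
    truth: pd.DataFrame          # per (family, snp): true transmissions, dosages
    peak_tables: dict            # cohort label -> PeakTable
    clinical: pd.DataFrame
    cohorts: pd.Series           # family_id -> cohort label
    maf: np.ndarray
    snp_ids: list
    species_ids: list

    def truth_wide(self, column: str) -> pd.DataFrame:
        """families x SNPs matrix of one truth column."""
        return self.truth.pivot(index="family_id", columns="snp_id",
                                values=column)


def _draw_genotypes(rng, maf, n) -> np.ndarray:
    """HWE genotype dosages: Binomial(2, maf) per founder."""
    return rng.binomial(2, maf, size=(n, maf.size))


def _transmit(rng, parent_dosage) -> np.ndarray:
    """Fair Mendelian gamete draw: minor-allele indicator of the gamete."""
    u = rng.random(parent_dosage.shape)
    # hom: deterministic; het: fair coin
    return np.where(parent_dosage == 2, 1,
                    np.where(parent_dosage == 0, 0, (u < 0.5).astype(int)))


def simulate_trios(cfg: SimConfig, rng: Optional[np.random.Generator] = None):
    """Simulate family-trio genotypes under HWE with Mendelian transmission.

    Returns ``(trios, truth, maf)``: the long-format genotype table, the
    hidden truth table (true transmitted minor-allele indicators and allele
    labels, one row per family x SNP) and the realized MAF vector.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    maf = cfg.resolve_maf(rng)
    n = cfg.n_families
    fam_ids = [f"F{i:04d}" for i in range(n)]
    snp_ids = [f"snp{j:03d}" for j in range(cfg.n_snps)]
    father = _draw_genotypes(rng, maf, n)
    mother = _draw_genotypes(rng, maf, n)
    pat_gamete = _transmit(rng, father)
    mat_gamete = _transmit(rng, mother)
    child = pat_gamete + mat_gamete

    fam_col = np.repeat(fam_ids, cfg.n_snps)
    snp_col = np.tile(snp_ids, n)
    gt = np.vectorize(format_genotype)
    trios = pd.DataFrame({
        "family_id": fam_col,
        "snp_id": snp_col,
        "father_gt": gt(father).ravel(),
        "mother_gt": gt(mother).ravel(),
        "child_gt": gt(child).ravel(),
    })
    allele = np.array([MAJOR, MINOR])
    truth = pd.DataFrame({
        "family_id": fam_col,
        "snp_id": snp_col,
        "paternal_allele": allele[pat_gamete.ravel()],
        "maternal_allele": allele[mat_gamete.ravel()],
        "paternal_minor": pat_gamete.ravel(),
        "maternal_minor": mat_gamete.ravel(),
        "father": father.ravel(),
        "mother": mother.ravel(),
        "child": child.ravel(),
    })
    return trios, truth, maf


def _effect_dose(truth_wide, cfg: SimConfig, effect: EffectSpec,
                 snp_ids) -> np.ndarray:
    snp = snp_ids[effect.snp]
    if effect.mode == "maternal-only":
        return truth_wide["maternal_minor"][snp].to_numpy(float)
    if effect.mode == "paternal-only":
        return truth_wide["paternal_minor"][snp].to_numpy(float)
    if effect.mode == "biallelic":
        return truth_wide["child"][snp].to_numpy(float)
    return truth_wide["mother"][snp].to_numpy(float)  # maternal-genome


def simulate_lipidome(cfg: SimConfig, truth: pd.DataFrame,
                      cohorts: pd.Series,
                      rng: Optional[np.random.Generator] = None) -> dict:
    """Simulate a per-cohort peak table carrying the configured allele effects.

    Intensities are log10-normal: per-species baseline mean, a per-sample
    scale factor, measurement noise, plus ``d * baseline_log_sd`` per unit of
    the effect dose on the log scale.  A single global LOD at the configured
    pooled-intensity quantile censors low measurements to 0.  Each table
    gains a pooled-QC dilution series (levels 1.0/0.5/0.2), blanks and QA
    samples.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    species_ids = [f"L{j:03d}" for j in range(cfg.n_species)]
    snp_ids = sorted(truth["snp_id"].unique())
    fam_ids = sorted(truth["family_id"].unique())
    piv = {col: truth.pivot(index="family_id", columns="snp_id", values=col)
           .loc[fam_ids] for col in
           ("maternal_minor", "paternal_minor", "child", "mother")}
    lo, hi = cfg.baseline_log_mean_range
    base_mean = rng.uniform(lo, hi, size=cfg.n_species)

    n = len(fam_ids)
    log_x = (base_mean[None, :]
             + rng.normal(0.0, cfg.baseline_log_sd, size=(n, cfg.n_species))
             + rng.normal(0.0, cfg.sample_scale_sd, size=(n, 1)))
    for e in cfg.effects:
        dose = _effect_dose(piv, cfg, e, snp_ids)
        log_x[:, e.species] += e.d * cfg.baseline_log_sd * dose
    raw = 10.0 ** log_x
    lod = float(np.quantile(raw, cfg.lod_quantile))

    tables = {}
    cohorts = cohorts.reindex(fam_ids)
    for label in cfg.cohort_labels:
        idx = np.flatnonzero((cohorts == label).to_numpy())
        X = raw[idx].copy()
        study_ids = [fam_ids[i] for i in idx]
        pool = X.mean(axis=0)  # pooled QC sample from the cohort's sera
        qc_rows, qc_ids, roles = [], [], []
        for level, conc in (("QC1", 1.0), ("QC2", 0.5), ("QC3", 0.2)):
            for rep in range(cfg.qc_replicates):
                qc_rows.append(conc * pool
                               * 10 ** rng.normal(0, cfg.qc_noise_sd,
                                                  cfg.n_species))
                qc_ids.append(f"{label}_{level}_{rep}")
                roles.append(level)
        for rep in range(cfg.n_qa):
            qc_rows.append(0.9 * pool
                           * 10 ** rng.normal(0, 0.05, cfg.n_species))
            qc_ids.append(f"{label}_QA_{rep}")
            roles.append("QA")
        for rep in range(cfg.n_blank):
            qc_rows.append(np.abs(rng.normal(0, 1e-3 * lod, cfg.n_species)))
            qc_ids.append(f"{label}_blank_{rep}")
            roles.append("blank")
        full = np.vstack([X] + [np.atleast_2d(r) for r in qc_rows])
        ids = study_ids + qc_ids
        role_s = pd.Series(["study"] * len(study_ids) + roles, index=ids)
        df = pd.DataFrame(full, index=ids, columns=species_ids)
        study_mask = role_s == "study"
        df.loc[study_mask] = df.loc[study_mask].where(df.loc[study_mask] > lod,
                                                      0.0)
        tables[label] = PeakTable(df, role_s, lod=lod)
    return tables


def simulate_clinical(cfg: SimConfig, peak_tables: dict, cohorts: pd.Series,
                      rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Simulate OGTT/clinical outcomes correlated with one lipid species.

    The fasting glucose and insulin log values share a latent standardized
    lipid signal (the target species' log intensity, z-scored within cohort)
    with correlations ``rho_glucose`` / ``rho_insulin``; HOMA indices follow
    by the HOMA1 closed forms.  Remaining variables are independent draws
    matched to plausible pregnancy-cohort marginals.
    """
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    link = cfg.clinical_link
    species = f"L{link.species:03d}"
    rows = []
    for label, table in peak_tables.items():
        study = table.study_samples()
        x = table.intensities.loc[study, species].to_numpy(float)
        logx = np.log10(np.where(x > 0, x, np.nanmin(x[x > 0]) / 2.0))
        z = (logx - logx.mean()) / (logx.std() or 1.0)
        m = len(study)

        def corr_noise(rho):
            return rho * z + np.sqrt(max(0.0, 1 - rho ** 2)) * rng.normal(size=m)

        glucose = cfg.glucose_mean * np.exp(cfg.glucose_log_sd
                                            * corr_noise(link.rho_glucose))
        glucose60 = cfg.glucose60_mean * np.exp(cfg.glucose60_log_sd
                                                * corr_noise(link.rho_glucose))
        insulin = cfg.insulin_mean * np.exp(cfg.insulin_log_sd
                                            * corr_noise(link.rho_insulin))
        ir, b = homa(glucose, insulin)
        gdm = ((glucose >= cfg.gdm_fasting_threshold)
               | (glucose60 >= cfg.gdm_60min_threshold))
        gest = rng.normal(39.9, 1.4, m)
        rows.append(pd.DataFrame({
            "family_id": list(study),
            "cohort": label,
            "fasting_glucose": glucose,
            "glucose_60min": glucose60,
            "fasting_insulin": insulin,
            "homa_ir": ir,
            "homa_b": b,
            "gdm": gdm.astype(int),
            "bmi": rng.normal(24.1, 4.2, m),
            "gestational_age": gest,
            "parity": 1 + rng.poisson(0.7, m),
            "sex": rng.binomial(1, 0.51, m),
            "birth_weight": rng.normal(3500, 450, m) + 60 * (gest - 39.9),
        }))
    return pd.concat(rows, ignore_index=True)


def simulate_dataset(cfg: SimConfig) -> SimData:
    """Full simulation: trios + truth, cohort peak tables, clinical table."""
    rng = np.random.default_rng(cfg.seed)
    trios, truth, maf = simulate_trios(cfg, rng)
    fam_ids = sorted(truth["family_id"].unique())
    sizes = np.floor(np.asarray(cfg.cohort_fractions) * len(fam_ids)).astype(int)
    sizes[-1] = len(fam_ids) - sizes[:-1].sum()
    labels = np.repeat(list(cfg.cohort_labels), sizes)
    perm = rng.permutation(len(fam_ids))
    cohorts = pd.Series(labels[np.argsort(perm)], index=fam_ids,
                        name="cohort")
    peak_tables = simulate_lipidome(cfg, truth, cohorts, rng)
    clinical = simulate_clinical(cfg, peak_tables, cohorts, rng)
    snp_ids = sorted(truth["snp_id"].unique())
    species_ids = list(next(iter(peak_tables.values())).species)
    return SimData(cfg, trios, truth, peak_tables, clinical, cohorts,
                   maf, snp_ids, species_ids)
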