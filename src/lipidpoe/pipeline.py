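"""End-to-end orchestration of the discovery / validation analysis chain.

Stage sequence (mirroring the internal-validation design of the emulated
study):

1. preprocess every cohort's peak table (detection + QC-linearity filters,
   below-LOD imputation, median/log/centre normalization);
2. impute parental transmissions from the trio genotype table, excluding
   Mendelian-inconsistent triads (counted in the manifest);
3. PLS-DA screen on the designated Discovery cohort only, one model per
   (SNP, parental transmission), accepted when cross-validated Q² > 0;
   species with VIP above threshold in accepted models become candidates;
4. univariate follow-up of every candidate (SNP, species) pair in every
   cohort across five contrasts: maternally / paternally transmitted
   allele, fetal genotype, maternal genotype, maternal untransmitted allele;
5. DerSimonian–Laird meta-analysis per (SNP, species, contrast), with
   cohort signs harmonized to the Discovery-cohort direction;
6. parent-of-origin classification of each candidate pair from the pooled
   contrasts;
7. clinical follow-up correlations (lipid vs OGTT-derived biomarkers) for
   flagged species, per cohort plus meta-analysis.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .association import (AssociationResult, PoeContrastSet, correlate,
                          maternal_transmission_enrichment, poe_classify)
from .meta import meta_scan
from .plsda import select_candidates
from .preprocess import PeakTable, preprocess
from .trio import MAJOR, MINOR, impute_transmissions_frame

__all__ = ["PipelineParams", "PipelineResult", "run_pipeline"]

CONTRASTS = ("maternal_transmitted", "paternal_transmitted", "fetal_genotype",
             "maternal_genotype", "maternal_untransmitted")

CLINICAL_VARS = ("bmi", "fasting_glucose", "glucose_60min", "fasting_insulin",
                 "homa_ir", "homa_b")


@dataclass
class PipelineParams:
    seed: int
    screen_cohort: str = "Discovery"
    vip_threshold: float = 2.0
    a_max: int = 5
    cv_folds: int = 10
    alpha: float = 0.05
    min_fraction: float = 0.70
    r_min: float = 0.9
    lod_rule: str = "half-min"
    min_per_class: int = 5
    screen_all: bool = False  # exploratory override; stamps outputs
    clinical_species: Optional[tuple] = None  # default: candidate species


@dataclass
class PipelineResult:
    params: PipelineParams
    normalized: dict                 # cohort -> DataFrame
    filter_reports: dict             # cohort -> DataFrame
    transmissions: pd.DataFrame
    screen: pd.DataFrame             # per-model Q2 summary
    candidates: pd.DataFrame         # snp, transmission, species, vip, q2, n
    enrichment: Optional[dict]
    associations: pd.DataFrame       # per-cohort contrast battery
    meta: pd.DataFrame               # pooled contrasts
    poe: pd.DataFrame                # per-pair classification
    clinical: pd.DataFrame           # per-cohort + pooled clinical follow-up
    manifest: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        header = (f"# lipidpoe {__version__}  config_hash="
                  f"{self.manifest.get('config_hash', 'NA')}\n")

        def dump(df, name):
            with open(out / name, "w") as fh:
                fh.write(header)
                df.to_csv(fh, sep="\t", index=False)

        for label, rep in self.filter_reports.items():
            dump(rep.reset_index(), f"filter_report_{label}.tsv")
        dump(self.transmissions[["family_id", "snp_id", "paternal_allele",
                                 "maternal_allele", "maternal_untransmitted",
                                 "consistent"]], "transmissions.tsv")
        dump(self.screen, "screen.tsv")
        dump(self.candidates, "candidates.tsv")
        dump(self.associations, "associations.tsv")
        dump(self.meta, "meta.tsv")
        dump(self.poe, "poe_classification.tsv")
        dump(self.clinical, "clinical.tsv")
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


def _binary_code(alleles: pd.Series) -> pd.Series:
    coded = pd.Series(np.nan, index=alleles.index, dtype=float)
    coded[alleles == MAJOR] = 0.0
    coded[alleles == MINOR] = 1.0
    return coded


def _contrast_codes(imp_snp: pd.DataFrame) -> dict:
    """The five per-family codings for one SNP's imputed-transmission rows."""
    s = imp_snp.set_index("family_id")
    return {
        "maternal_transmitted": _binary_code(s["maternal_allele"]),
        "paternal_transmitted": _binary_code(s["paternal_allele"]),
        "fetal_genotype": pd.to_numeric(s["child"], errors="coerce"),
        "maternal_genotype": pd.to_numeric(s["mother"], errors="coerce"),
        "maternal_untransmitted": _binary_code(s["maternal_untransmitted"]),
    }


def _safe_correlate(x, y, predictor, response):
    try:
        return correlate(x, y, predictor, response)
    except ValueError:
        return None


def run_pipeline(trios: pd.DataFrame, peak_tables: dict,
                 clinical: Optional[pd.DataFrame] = None,
                 params: Optional[PipelineParams] = None) -> PipelineResult:
    """Run the full discovery -> validation -> meta-analysis chain.

    ``trios`` is the long genotype table; ``peak_tables`` maps cohort label
    onto :class:`~lipidpoe.preprocess.PeakTable`; ``clinical`` (optional) is
    the per-mother outcome table with a ``family_id`` and ``cohort`` column.
    """
    if params is None:
        raise ValueError("params (with a seed) are required")
    if params.screen_cohort not in peak_tables and not params.screen_all:
        raise ValueError(f"screening cohort {params.screen_cohort!r} not "
                         f"among cohorts {list(peak_tables)}")
    manifest = {
        "tool_version": __version__,
        "params": asdict(params),
        "cohorts": {label: int((t.roles == "study").sum())
                    for label, t in peak_tables.items()},
        "exclusions": [],
        "stages": [],
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(asdict(params), sort_keys=True, default=str).encode()
    ).hexdigest()[:12]

    # ---- stage 1: preprocessing -------------------------------------------
    normalized, reports = {}, {}
    for label, table in peak_tables.items():
        normalized[label], reports[label] = preprocess(
            table, min_fraction=params.min_fraction, r_min=params.r_min,
            lod_rule=params.lod_rule)
        dropped = reports[label].index[~reports[label]["retained"]]
        manifest["exclusions"].append(
            {"stage": "preprocess", "cohort": label, "kind": "species",
             "count": int(len(dropped))})
    manifest["stages"].append({"stage": "preprocess",
                               "retained": {label: int(df.shape[1])
                                            for label, df in normalized.items()}})

    # ---- stage 2: transmission imputation ---------------------------------
    imputed = impute_transmissions_frame(trios)
    inconsistent = imputed["consistent"] == False  # noqa: E712
    manifest["exclusions"].append({"stage": "impute", "kind": "trio",
                                   "reason": "mendelian_inconsistent",
                                   "count": int(inconsistent.sum())})
    usable = imputed[~inconsistent].copy()
    manifest["stages"].append({"stage": "impute", "n_rows": int(len(imputed)),
                               "n_usable": int(len(usable))})

    # ---- stage 3: PLS-DA screen on the Discovery cohort -------------------
    screen_cohorts = (list(peak_tables) if params.screen_all
                      else [params.screen_cohort])
    Xs = pd.concat([normalized[c] for c in screen_cohorts]) \
        if len(screen_cohorts) > 1 else normalized[screen_cohorts[0]]
    labels = {}
    for snp_id, grp in usable.groupby("snp_id", sort=True):
        codes = _contrast_codes(grp)
        labels[(snp_id, "maternal")] = codes["maternal_transmitted"]
        labels[(snp_id, "paternal")] = codes["paternal_transmitted"]
    models = select_candidates(Xs, labels, vip_threshold=params.vip_threshold,
                               a_max=params.a_max, folds=params.cv_folds,
                               seed=params.seed,
                               min_per_class=params.min_per_class)
    screen = pd.DataFrame([{
        "snp_id": m.snp_id, "transmission": m.transmission,
        "best_a": m.best_a, "q2": m.model_q2, "accepted": m.accepted,
        "n_samples": m.n_samples, "n_candidates": len(m.candidates),
    } for m in models])
    cand_rows = []
    for m in models:
        for rec in m.candidates.itertuples(index=False):
            cand_rows.append({"snp_id": m.snp_id,
                              "transmission": m.transmission,
                              "species": rec.species, "vip": rec.vip,
                              "vip_single": rec.vip_single,
                              "model_q2": m.model_q2,
                              "n_samples": m.n_samples})
    candidates = pd.DataFrame(cand_rows, columns=[
        "snp_id", "transmission", "species", "vip", "vip_single",
        "model_q2", "n_samples"])
    enrichment = (maternal_transmission_enrichment(
        candidates.to_dict("records")) if len(candidates) else None)
    manifest["stages"].append({"stage": "screen",
                               "n_models": len(models),
                               "n_accepted": int(screen["accepted"].sum()),
                               "n_candidates": int(len(candidates)),
                               "screen_all": params.screen_all,
                               "enrichment": enrichment})

    empty_assoc = pd.DataFrame(columns=["cohort", "snp_id", "species",
                                        "contrast", "r", "signed_r", "p", "n"])
    if candidates.empty:
        manifest["stages"].append(
            {"stage": "associate", "note": "skipped: empty candidate set"})
        clin = _clinical_stage(params, normalized, clinical, (), manifest)
        return PipelineResult(params, normalized, reports, imputed, screen,
                              candidates, enrichment, empty_assoc,
                              pd.DataFrame(), pd.DataFrame(), clin, manifest)

    # ---- stage 4: per-cohort contrast battery -----------------------------
    pairs = candidates[["snp_id", "species"]].drop_duplicates()
    assoc_rows = []
    for snp_id, grp in usable.groupby("snp_id", sort=True):
        wanted = pairs[pairs["snp_id"] == snp_id]["species"]
        if wanted.empty:
            continue
        codes = _contrast_codes(grp)
        for cohort, X in normalized.items():
            for species in wanted:
                if species not in X.columns:
                    continue
                y = X[species]
                for contrast in CONTRASTS:
                    coded = codes[contrast].reindex(X.index)
                    res = _safe_correlate(coded, y, snp_id, species)
                    if res is None:
                        continue
                    assoc_rows.append({
                        "cohort": cohort, "snp_id": snp_id,
                        "species": species, "contrast": contrast,
                        "r": res.r, "signed_r": res.signed_r,
                        "p": res.p, "n": res.n})
    associations = pd.DataFrame(assoc_rows) if assoc_rows else empty_assoc
    manifest["stages"].append({"stage": "associate",
                               "n_tests": int(len(associations))})

    # ---- stage 5: meta-analysis with Discovery-direction harmonization ----
    ref = params.screen_cohort if params.screen_cohort in peak_tables \
        else list(peak_tables)[0]
    harmonized = associations.copy()
    keys = ["snp_id", "species", "contrast"]
    ref_sign = (harmonized[harmonized["cohort"] == ref]
                .set_index(keys)["signed_r"].apply(np.sign).replace(0, 1))
    flip = harmonized.set_index(keys).index.map(ref_sign)
    harmonized["r_harmonized"] = harmonized["signed_r"] * pd.Series(
        flip, index=harmonized.index).fillna(1.0)
    cohort_tables = {
        c: harmonized[harmonized["cohort"] == c].rename(
            columns={"snp_id": "predictor", "species": "response"})
        for c in peak_tables}
    meta = meta_scan({c: t for c, t in cohort_tables.items() if len(t)},
                     key_cols=("predictor", "response", "contrast"),
                     r_col="r_harmonized", n_col="n")
    meta = meta.rename(columns={"predictor": "snp_id", "response": "species"})
    manifest["stages"].append({"stage": "meta", "n_pooled": int(len(meta))})

    # ---- stage 6: parent-of-origin classification -------------------------
    poe_rows = []
    for (snp_id, species), grp in meta.groupby(["snp_id", "species"]):
        cs = PoeContrastSet(snp_id, species)
        for rec in grp.itertuples(index=False):
            if not rec.pooled or not np.isfinite(rec.r_pooled):
                continue
            res = AssociationResult(snp_id, species, abs(rec.r_pooled),
                                    int(np.sign(rec.r_pooled)) or 1,
                                    rec.p_one_sided, 0)
            setattr(cs, rec.contrast, res)
        if cs.maternal_transmitted is None and cs.paternal_transmitted is None:
            continue
        label = poe_classify(cs, alpha=params.alpha)
        poe_rows.append({"snp_id": snp_id, "species": species,
                         "classification": label, "rationale": cs.rationale})
    poe = pd.DataFrame(poe_rows)
    manifest["stages"].append({"stage": "poe_classify", "n_pairs": len(poe_rows)})

    # ---- stage 7: clinical follow-up --------------------------------------
    flagged = (params.clinical_species if params.clinical_species is not None
               else tuple(candidates["species"].unique()))
    clin = _clinical_stage(params, normalized, clinical, flagged, manifest)

    return PipelineResult(params, normalized, reports, imputed, screen,
                          candidates, enrichment, associations, meta, poe,
                          clin, manifest)


def _clinical_stage(params, normalized, clinical, species_list, manifest):
    if clinical is None or not len(species_list):
        manifest["stages"].append({"stage": "clinical",
                                   "note": "skipped (no clinical table or "
                                           "no flagged species)"})
        return pd.DataFrame(columns=["cohort", "species", "biomarker",
                                     "r", "signed_r", "p", "n"])
    rows = []
    clin_by_cohort = dict(tuple(clinical.groupby("cohort")))
    for cohort, X in normalized.items():
        sub = clin_by_cohort.get(cohort)
        if sub is None:
            continue
        sub = sub.set_index("family_id")
        common = X.index.intersection(sub.index)
        for species in species_list:
            if species not in X.columns:
                continue
            for var in CLINICAL_VARS:
                if var not in sub.columns:
                    continue
                res = _safe_correlate(X.loc[common, species],
                                      sub.loc[common, var], species, var)
                if res is None:
                    continue
                rows.append({"cohort": cohort, "species": species,
                             "biomarker": var, "r": res.r,
                             "signed_r": res.signed_r, "p": res.p,
                             "n": res.n})
    percohort = pd.DataFrame(rows)
    manifest["stages"].append({"stage": "clinical",
                               "n_tests": int(len(percohort))})
    if percohort.empty or percohort["cohort"].nunique() < 2:
        return percohort
    pooled = meta_scan(
        {c: g.rename(columns={"species": "predictor", "biomarker": "response"})
         for c, g in percohort.groupby("cohort")},
        key_cols=("predictor", "response"), r_col="signed_r", n_col="n")
    pooled = pooled.rename(columns={"predictor": "species",
                                    "response": "biomarker"})
    pooled.insert(0, "cohort", "meta")
    return pd.concat([percohort, pooled], ignore_index=True)
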