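"""End-to-end study pipeline on a synthetic cohort.

Chains the full workflow: cohort simulation -> ROI triplet construction
-> per-ROI feature extraction -> (optional) inter-rater stability filter
-> mRMR -> LASSO Radscore per ROI -> the four isolated predictive models
(CT features, GTV / GPTV / GPR Radscores) -> ROC / DeLong / calibration /
decision-curve evaluation.

Radscores are constructed on the full cohort and the one-predictor
logistic models are then assessed by stratified 10-fold cross-validation,
the design used in single-cohort radiomics studies; both apparent
(resubstitution) and out-of-fold AUCs are reported and labeled.  A fully
nested mode (selection re-run inside every fold) is available for
leakage-free estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import compare_models, decision_curve, hosmer_lemeshow, roc_auc
from .features import ExtractionConfig, extract_all, features_to_frame
from .models import crossvalidate, fit_ct_model, fit_radscore_model
from .roi import build_roi_triplet
from .selection import RadscoreModel, SelectionConfig, lasso_cv, mrmr_select, stability_filter
from .synthetic import CohortSpec, perturb_mask, simulate_cohort

__all__ = ["StudyResult", "extract_cohort_features", "build_radscores", "run_study"]

ROI_KINDS = ("GTV", "GPTV", "GPR")
MODEL_NAMES = ("CTfeatures", "GTV", "GPTV", "GPR")


@dataclass
class StudyResult:
    """All artifacts of one synthetic-cohort study run."""

    table: pd.DataFrame                       # covariates + label + radscores
    features: pd.DataFrame                    # (case_id, roi) x feature
    radscore_models: dict[str, RadscoreModel]
    apparent_auc: dict[str, float]
    cv_auc: dict[str, float]
    oof_probabilities: pd.DataFrame           # case x model
    delong_table: pd.DataFrame
    calibration: dict
    decision_curves: dict


def extract_cohort_features(cases, margin_mm: float = 5.0,
                            extraction: ExtractionConfig | None = None,
                            second_rater_seed: int | None = None):
    """Extract GTV/GPTV/GPR features for every case.

    With ``second_rater_seed`` set, a perturbed-contour re-extraction
    emulating a second reader is returned as well (for ICC filtering).
    """
    extraction = extraction or ExtractionConfig()
    per_case, per_case_r2 = {}, {}
    for c in cases:
        triplet = build_roi_triplet(c.gtv_mask, c.image.spacing_mm, margin_mm)
        per_case[c.case_id] = extract_all(c.image, triplet, extraction)
        if second_rater_seed is not None:
            m2 = perturb_mask(c.gtv_mask, seed=second_rater_seed + c.seed_used)
            triplet2 = build_roi_triplet(m2, c.image.spacing_mm, margin_mm)
            per_case_r2[c.case_id] = extract_all(c.image, triplet2, extraction)
    feats = features_to_frame(per_case)
    if second_rater_seed is None:
        return feats
    return feats, features_to_frame(per_case_r2)


def build_radscores(features: pd.DataFrame, labels: pd.Series,
                    selection: SelectionConfig | None = None,
                    features_rater2: pd.DataFrame | None = None
                    ) -> tuple[pd.DataFrame, dict[str, RadscoreModel]]:
    """mRMR -> LASSO Radscore per ROI kind; returns scores and models."""
    selection = selection or SelectionConfig()
    scores = {}
    models = {}
    y = labels.loc[features.index.get_level_values("case_id").unique()]
    y01 = (y == "IAC").astype(int)
    for roi in ROI_KINDS:
        X = features.xs(roi, level="roi")
        X = X.loc[y.index]
        if features_rater2 is not None:
            X2 = features_rater2.xs(roi, level="roi").loc[y.index]
            kept = stability_filter(X, X2, selection.icc_threshold)
            X = X[kept]
        ranked = mrmr_select(X, y01.to_numpy(), selection.mrmr_keep)
        model = lasso_cv(X[ranked], y01.to_numpy(), selection, roi_kind=roi)
        models[roi] = model
        scores[f"radscore_{roi}"] = pd.Series(model.predict(X), index=X.index)
    return pd.DataFrame(scores), models


def nested_radscore_auc(features: pd.DataFrame, labels: pd.Series,
                        selection: SelectionConfig | None = None,
                        folds: int = 10, seed: int = 0) -> float:
    """Leakage-free out-of-fold AUC of the Radscore pipeline.

    The whole selection chain (mRMR -> cross-validated LASSO) is re-run
    inside every training fold and the held-out cases are scored by that
    fold's model, so no case contributes to its own signature.  This is
    the honest estimate; the single-cohort design that selects on all
    cases first (as run_study reports) is optimistically biased,
    especially near the null.
    """
    from .evaluation import roc_auc
    from .selection import stratified_folds

    selection = selection or SelectionConfig(seed=seed)
    y = pd.Series((pd.Series(labels) == "IAC").astype(int).to_numpy()
                  if pd.Series(labels).dtype == object else np.asarray(labels),
                  index=features.index)
    assign = stratified_folds(features.index, y, folds, seed)
    oof = pd.Series(np.nan, index=features.index)
    for f in sorted(assign.unique()):
        tr = assign.index[assign != f]
        te = assign.index[assign == f]
        ranked = mrmr_select(features.loc[tr], y.loc[tr].to_numpy(),
                             selection.mrmr_keep)
        model = lasso_cv(features.loc[tr, ranked], y.loc[tr].to_numpy(), selection)
        oof.loc[te] = model.predict(features.loc[te])
    return roc_auc(oof.to_numpy(), y.to_numpy()).auc


def run_study(spec: CohortSpec | None = None,
              selection: SelectionConfig | None = None,
              extraction: ExtractionConfig | None = None,
              folds: int = 10,
              use_stability_filter: bool = False) -> StudyResult:
    """Run the complete synthetic study once; deterministic given spec."""
    spec = spec or CohortSpec()
    selection = selection or SelectionConfig(seed=spec.seed)

    cases, table = simulate_cohort(spec)
    if use_stability_filter:
        feats, feats2 = extract_cohort_features(
            cases, spec.margin_mm, extraction, second_rater_seed=spec.seed + 7919)
    else:
        feats = extract_cohort_features(cases, spec.margin_mm, extraction)
        feats2 = None

    scores, models = build_radscores(feats, table["label"], selection, feats2)
    table = table.join(scores)

    predictors = {
        "CTfeatures": ["max_diameter_mm", "vcs"],
        "GTV": ["radscore_GTV"],
        "GPTV": ["radscore_GPTV"],
        "GPR": ["radscore_GPR"],
    }
    apparent_auc, cv_auc = {}, {}
    oof = {}
    apparent_scores = {}
    for name, cols in predictors.items():
        if name == "CTfeatures":
            fitted = fit_ct_model(table)
        else:
            fitted = fit_radscore_model(table, cols[0], name=name)
        apparent_scores[name] = fitted.fitted_probabilities.to_numpy()
        apparent_auc[name] = roc_auc(fitted.fitted_probabilities, table["label"]).auc
        cvres = crossvalidate(table, cols, folds=folds, seed=selection.seed)
        oof[name] = cvres["probability"]
        cv_auc[name] = roc_auc(cvres["probability"], table["label"]).auc
    oof_df = pd.DataFrame(oof)

    delong = compare_models(
        {k: v.to_numpy() for k, v in oof_df.items()}, table["label"].to_numpy(),
        order=[("GTV", "CTfeatures"), ("GPTV", "CTfeatures"), ("GPR", "CTfeatures"),
               ("GTV", "GPR"), ("GPTV", "GPR"), ("GTV", "GPTV")],
    )
    calibration = {name: hosmer_lemeshow(oof_df[name], table["label"])
                   for name in MODEL_NAMES}
    curves = {name: decision_curve(oof_df[name], table["label"])
              for name in MODEL_NAMES}

    return StudyResult(
        table=table, features=feats, radscore_models=models,
        apparent_auc=apparent_auc, cv_auc=cv_auc, oof_probabilities=oof_df,
        delong_table=delong, calibration=calibration, decision_curves=curves,
    )
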