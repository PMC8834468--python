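"""End-to-end analysis: preprocess -> MWPLSR -> SCMWPLS -> calibrate -> validate.

`run_analysis` reproduces the full two-stage workflow for one analyte:
the saturated water band is excluded, spectra are second-derivative
pretreated per segment, residue lines locate informative regions, SCMWPLS
optimizes their combination, and the final model's dimensionality is
re-selected by full (leave-one-out) cross-validation before validation on
the independent test batch.  A whole-region PLS model is built the same way
for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import EvaluationReport, evaluate_predictions
from .grid import RegionSet, ReferenceTable, SpectraSet, exclude_regions
from .io import join_spectra_references
from .pls import PLSModel, loo_rmsecv, pls1_fit, pls1_predict
from .preprocess import PreprocessSpec, apply_preprocess
from .regions import SCMWPLSResult, detect_informative_regions, mwplsr, scmwpls_combine

__all__ = ["AnalysisConfig", "AnalysisResult", "run_analysis", "prepare_spectra"]

DEFAULT_EXCLUSION = RegionSet.from_string("5248-4984")


@dataclass
class AnalysisConfig:
    """Tunable knobs of the pipeline, defaulting to the study settings."""

    exclusions: RegionSet = field(default_factory=lambda: DEFAULT_EXCLUSION)
    preprocess: PreprocessSpec = field(default_factory=PreprocessSpec)
    window_size: int = 20
    k_max: int = 10
    lv_ref: int = 3
    quantile_threshold: float = 0.15
    min_run: int = 3
    order_policy: str = "wavenumber"
    w_min: int = 1
    w_max: int | None = None
    stride: int = 1
    rel_improvement: float = 0.02
    alpha: float = 0.05
    n_effective: int | None = None
    manual_regions: RegionSet | None = None


@dataclass
class AnalysisResult:
    analyte: str
    informative_regions: RegionSet
    scmwpls: SCMWPLSResult
    model: PLSModel
    whole_model: PLSModel
    report: EvaluationReport
    whole_report: EvaluationReport


def prepare_spectra(
    spectra: SpectraSet, config: AnalysisConfig | None = None
) -> SpectraSet:
    """Exclude the saturated region, then pretreat per segment."""
    config = config or AnalysisConfig()
    out = exclude_regions(spectra, config.exclusions)
    return apply_preprocess(out, config.preprocess)


def _select_lv_and_fit(
    X: np.ndarray, y: np.ndarray, k_max: int, **fit_kw
) -> PLSModel:
    k_cv = min(k_max, X.shape[0] - 2, X.shape[1])
    cv = loo_rmsecv(X, y, k_cv)
    return pls1_fit(X, y, cv.chosen_lv, **fit_kw)


def run_analysis(
    cal_spectra: SpectraSet,
    cal_refs: ReferenceTable,
    test_spectra: SpectraSet,
    test_refs: ReferenceTable,
    analyte: str,
    config: AnalysisConfig | None = None,
) -> AnalysisResult:
    config = config or AnalysisConfig()
    cal = prepare_spectra(cal_spectra, config)
    test = prepare_spectra(test_spectra, config)
    y_cal = join_spectra_references(cal, cal_refs).y(analyte)
    y_test = join_spectra_references(test, test_refs).y(analyte)

    lines = mwplsr(cal, y_cal, config.window_size, config.k_max)
    informative = detect_informative_regions(
        lines,
        lv_ref=config.lv_ref,
        quantile_threshold=config.quantile_threshold,
        min_run=config.min_run,
        manual_regions=config.manual_regions,
    )
    sc = scmwpls_combine(
        cal,
        y_cal,
        informative,
        order_policy=config.order_policy,
        k_max=config.k_max,
        w_min=config.w_min,
        w_max=config.w_max,
        stride=config.stride,
        rel_improvement=config.rel_improvement,
    )

    def n_events(s: SpectraSet) -> int:
        if config.n_effective is not None:
            return config.n_effective
        if s.metadata is not None and {"batch", "time_h"} <= set(s.metadata):
            return len(s.metadata[["batch", "time_h"]].drop_duplicates())
        return s.n_samples

    # final SCMWPLS model: dimensionality re-selected by full cross-validation
    cols = cal.columns_for(sc.optimized_regions)
    model = _select_lv_and_fit(
        cal.absorbance[:, cols],
        y_cal,
        config.k_max,
        region_set=sc.optimized_regions,
        preprocess=config.preprocess,
        analyte=analyte,
    )
    pred_cal = pls1_predict(model, cal.absorbance[:, cols])
    pred_test = pls1_predict(model, test.absorbance[:, test.columns_for(sc.optimized_regions)])
    report = evaluate_predictions(
        y_cal, pred_cal, y_test, pred_test,
        lv_used=model.n_lv, analyte=analyte,
        n_effective=n_events(test), alpha=config.alpha,
    )

    whole_model = _select_lv_and_fit(
        cal.absorbance, y_cal, config.k_max,
        region_set=cal.regions, preprocess=config.preprocess, analyte=analyte,
    )
    whole_report = evaluate_predictions(
        y_cal,
        pls1_predict(whole_model, cal.absorbance),
        y_test,
        pls1_predict(whole_model, test.absorbance),
        lv_used=whole_model.n_lv, analyte=analyte,
        n_effective=n_events(test), alpha=config.alpha,
    )
    return AnalysisResult(
        analyte=analyte,
        informative_regions=informative,
        scmwpls=sc,
        model=model,
        whole_model=whole_model,
        report=report,
        whole_report=whole_report,
    )
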