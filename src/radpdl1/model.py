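"""Top-level Model/Results interface over the full radiomics pipeline.

:class:`RadiomicsPDL1Model` is built from per-subject feature tables and
clinical covariates; ``fit(seed)`` runs the three-step feature selection
(interobserver ICC filter, univariate t screen, repeated-CV LASSO), builds
the Rad-score signature with its Youden cutoff, and fits and compares the
clinical and clinical+radiomic logistic models. The returned
:class:`RadiomicsPDL1Results` carries every intermediate table and a
``summary()`` in the shape of the usual cohort/selection/model report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import models as _models
from . import selection as _selection
from .reliability import reliability_filter
from .signature import RadScoreSignature, dichotomize, rad_score, youden_cutoff


@dataclass(frozen=True)
class PipelineConfig:
    """Tunables of the analysis pipeline (defaults follow the emulated study)."""

    G: int = 32                     # gray levels for texture discretization
    icc_threshold: float = 0.75     # step-1 reliability filter
    alpha: float = 0.05             # step-2 univariate screen
    folds: int = 3                  # LASSO CV folds
    repeats: int = 100              # LASSO CV repetitions
    n_lambdas: int = 100
    B: int = 1000                   # bootstrap resamples
    age_cutoff: float | None = None  # None -> Youden-derived from the data
    icc_model: str = "absolute"

    def __post_init__(self) -> None:
        if not (0 <= self.icc_threshold <= 1 and 0 < self.alpha < 1):
            raise ValueError("thresholds out of range")
        if self.folds < 2 or self.repeats < 1 or self.B < 1 or self.G < 2:
            raise ValueError("folds/repeats/B/G out of range")


class RadiomicsPDL1Model:
    """The radiomics PD-L1 prediction analysis, statsmodels-style.

    Parameters
    ----------
    features :
        Reader-1 feature table (subjects x 58 catalogue features).
    cohort :
        Clinical table with subject_id, pdl1_positive, age, sex, smoking,
        egfr_mutant. Aligned to ``features`` by subject_id when present as
        a column, else by position.
    features_reader2 :
        Optional second reader's features; enables the ICC filter step.
        When omitted, step 1 retains everything.
    config :
        Pipeline tunables; defaults are the emulated study's values.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        cohort: pd.DataFrame,
        features_reader2: pd.DataFrame | None = None,
        config: PipelineConfig | None = None,
    ) -> None:
        cohort = cohort.copy()
        if "subject_id" in cohort.columns:
            cohort = cohort.set_index("subject_id")
        if not features.index.equals(cohort.index):
            if len(features) != len(cohort):
                raise ValueError("features and cohort have different subjects")
            features = features.set_axis(cohort.index)
            if features_reader2 is not None:
                features_reader2 = features_reader2.set_axis(cohort.index)
        self.features = features
        self.features_reader2 = features_reader2
        self.cohort = cohort
        self.labels = cohort["pdl1_positive"].astype(int)
        self.config = config or PipelineConfig()

    @classmethod
    def from_cohort_tables(cls, cohort, features_r1, features_r2=None, config=None):
        return cls(features_r1, cohort, features_r2, config)

    def fit(self, seed: int = 0) -> "RadiomicsPDL1Results":
        cfg = self.config
        y = self.labels.values

        # step 1: interobserver reliability filter
        if self.features_reader2 is not None:
            step1, icc_table = reliability_filter(
                self.features, self.features_reader2, threshold=cfg.icc_threshold,
                model=cfg.icc_model,
            )
        else:
            step1 = list(self.features.columns)
            icc_table = pd.DataFrame(index=pd.Index(step1, name="feature"))
        if not step1:
            raise ValueError("reliability filter removed every feature")

        # step 2: univariate screen
        step2, pvals = _selection.univariate_screen(
            self.features[step1], y, alpha=cfg.alpha
        )

        # step 3: LASSO with repeated stratified CV
        if step2:
            report = _selection.lasso_cv_select(
                self.features[step2], y, folds=cfg.folds, repeats=cfg.repeats,
                seed=seed, n_lambdas=cfg.n_lambdas,
                step1_retained=step1, step2_table=pvals,
            )
        else:
            report = _selection.SelectionReport(
                step1_retained=step1, step2_retained=[], step2_pvalues=pvals,
                lambda_grid=np.array([]), mean_auc_per_lambda=np.array([]),
                chosen_lambda=np.nan, best_mean_auc=np.nan,
                nonzero_features={}, intercept=0.0, seed=seed,
                warnings=["univariate screen retained no feature"],
            )
        report.step2_retained = step2

        scores = np.asarray(rad_score(
            RadScoreSignature(report.intercept, report.nonzero_features), self.features
        ), dtype=float)
        if np.ptp(scores) > 0:
            cutoff, sens, spec, auc = youden_cutoff(scores, y)
        else:
            cutoff, sens, spec, auc = np.nan, np.nan, np.nan, 0.5
        signature = _selection.build_signature(report, cutoff=None if np.isnan(cutoff) else cutoff)

        age_cutoff = cfg.age_cutoff
        if age_cutoff is None:
            age_cutoff = youden_cutoff(-self.cohort["age"].values, y)[0] * -1.0

        analysis = self.cohort.copy()
        analysis["rad_score"] = scores
        analysis["radscore_positive"] = (
            dichotomize(scores, cutoff) if np.isfinite(cutoff) else 0
        )
        if analysis["radscore_positive"].nunique() < 2:
            comparison = None
        else:
            comparison = _models.compare_models(
                analysis, age_cutoff=age_cutoff, B=cfg.B, seed=seed
            )
        return RadiomicsPDL1Results(
            model=self,
            seed=seed,
            icc_table=icc_table,
            selection=report,
            signature=signature,
            rad_scores=pd.Series(scores, index=self.cohort.index, name="rad_score"),
            cutoff=cutoff,
            sensitivity=sens,
            specificity=spec,
            rad_score_auc=auc,
            age_cutoff=float(age_cutoff),
            comparison=comparison,
            analysis_table=analysis,
        )


@dataclass
class RadiomicsPDL1Results:
    """Fitted pipeline: selection trace, signature, cutoff, model comparison."""

    model: RadiomicsPDL1Model
    seed: int
    icc_table: pd.DataFrame
    selection: _selection.SelectionReport
    signature: RadScoreSignature
    rad_scores: pd.Series
    cutoff: float
    sensitivity: float
    specificity: float
    rad_score_auc: float
    age_cutoff: float
    comparison: _models.ModelComparison | None
    analysis_table: pd.DataFrame = field(repr=False, default=None)

    def group_means(self) -> pd.DataFrame:
        """Rad-score mean +/- SD by PD-L1 group."""
        df = pd.DataFrame({"rad_score": self.rad_scores, "label": self.model.labels})
        return df.groupby("label")["rad_score"].agg(["mean", "std", "count"])

    def summary(self) -> str:
        lines = []
        n = len(self.model.labels)
        npos = int(self.model.labels.sum())
        lines.append("Radiomics PD-L1 prediction pipeline")
        lines.append("=" * 60)
        lines.append(f"Subjects: {n} ({npos} PD-L1 positive, {n - npos} negative)")
        lines.append(
            f"Feature selection: {len(self.selection.step1_retained)} after ICC filter, "
            f"{len(self.selection.step2_retained)} after univariate screen, "
            f"{len(self.selection.nonzero_features)} in the signature"
        )
        lines.append("Rad-score signature (raw feature scale):")
        lines.append(f"  intercept  {self.signature.intercept:+.5f}")
        for name, coef in self.signature.coefficients.items():
            lines.append(f"  {name:<28s} {coef:+.5f}")
        gm = self.group_means()
        if set(gm.index) == {0, 1}:
            lines.append(
                f"Rad-score by group: positive {gm.loc[1, 'mean']:.3f} +/- {gm.loc[1, 'std']:.3f}"
                f" vs negative {gm.loc[0, 'mean']:.3f} +/- {gm.loc[0, 'std']:.3f}"
            )
        lines.append(
            f"ROC: AUC {self.rad_score_auc:.3f}, Youden cutoff {self.cutoff:.3f} "
            f"(sens {self.sensitivity:.1%}, spec {self.specificity:.1%})"
        )
        if self.comparison is not None:
            c = self.comparison
            lines.append("-" * 60)
            lines.append("Model 1 (clinical) vs Model 2 (clinical + Rad-score)")
            lines.append(
                f"  c-statistic: {c.model1.c_statistic:.3f} "
                f"({c.model1.c_ci[0]:.3f}-{c.model1.c_ci[1]:.3f}) vs "
                f"{c.model2.c_statistic:.3f} ({c.model2.c_ci[0]:.3f}-{c.model2.c_ci[1]:.3f})"
            )
            lines.append(f"  DeLong p for c difference: {c.delong_p:.4f}")
            b = c.bootstrap
            lines.append(
                f"  bootstrap-corrected c: {b.corrected_c1:.3f} vs {b.corrected_c2:.3f} "
                f"(B={b.B}); delta-c 95% CI ({b.delta_c_ci[0]:.3f}, {b.delta_c_ci[1]:.3f})"
            )
            lines.append("  Odds ratios (95% CI):")
            for term, row in c.model2.odds_ratios.iterrows():
                lines.append(
                    f"    {term:<20s} {row['OR']:.4f} ({row['ci_low']:.4f}-{row['ci_high']:.4f})"
                    f"  p={row['p_value']:.4f}"
                )
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        """ROC curve of the Rad-score with the Youden operating point."""
        import matplotlib.pyplot as plt
        from sklearn.metrics import roc_curve

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        y = self.model.labels.values
        fpr, tpr, _ = roc_curve(y, self.rad_scores.values)
        ax.plot(fpr, tpr, label=f"Rad-score AUC={self.rad_score_auc:.3f}")
        if np.isfinite(self.cutoff):
            ax.plot([1 - self.specificity], [self.sensitivity], "o", label="Youden cutoff")
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(loc="lower right")
        return ax
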