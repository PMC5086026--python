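"""Model/Results interface to the panel-weighting pipeline.

:class:`PanelWeightModel` is constructed from an encounter table and a
patient roster; :meth:`~PanelWeightModel.fit` runs the full pipeline —
specialty caps and visit vectors, the 70/30 train/test split, rule-plus-
k-means phenotyping on the training split, work-cluster assignment of the
whole empaneled population on the concurrent-year vectors, the
conservation-constrained weight solve, per-provider and per-clinic weighted
panel sizes, and the predictive-validation model comparison — and returns a
:class:`PanelWeightResults` carrying every stage's output plus a
``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as pio
from .config import PipelineConfig
from .features import (
    VECTOR_COLUMNS,
    SpecialtyCaps,
    build_visit_vectors,
    compute_specialty_caps,
    specialty_patient_counts,
)
from .phenotyping import PHENOTYPES, PhenotypeClassifier
from .validation import (
    build_feature_table,
    model_comparison_table,
    train_test_split_ids,
)
from .weighting import (
    ClusterWeights,
    compute_cluster_weights,
    panel_change_report,
    weighted_panel_size,
)
from .work_clusters import FINAL_ORDER, assign_work_clusters

logger = logging.getLogger("panelweight")


class PanelWeightModel:
    """Panel-weighting pipeline over one health system's encounter history.

    Parameters
    ----------
    encounters
        Encounter-level records (patient_id, category, date, specialty,
        med_count, msg_direction) spanning the two configured 12-month
        windows.
    patients
        Empanelment roster (patient_id, age, sex, payer, clinic, provider).
    config
        Algorithm constants; defaults reproduce the published settings.
    """

    def __init__(
        self,
        encounters: pd.DataFrame,
        patients: pd.DataFrame,
        config: PipelineConfig | None = None,
    ):
        pio._require_columns(encounters, pio.ENCOUNTER_COLUMNS, "encounters")
        pio._require_columns(patients, pio.PATIENT_COLUMNS, "patients")
        self.encounters = encounters
        self.patients = patients
        self.config = config or PipelineConfig()

    @classmethod
    def from_csv(
        cls,
        encounters_path: str | Path,
        patients_path: str | Path,
        config: PipelineConfig | None = None,
    ) -> "PanelWeightModel":
        return cls(
            pio.read_encounters(encounters_path),
            pio.read_patients(patients_path),
            config,
        )

    def fit(self, seed: int = 0, validate: bool = True) -> "PanelWeightResults":
        cfg = self.config
        ids = self.patients["patient_id"]
        logger.info("fit: %d patients, %d encounters, config=%s, seed=%d",
                    len(ids), len(self.encounters), cfg.hash(), seed)

        # Specialty caps are system-wide, estimated once over the whole
        # collection period (pooled per-year user counts) and frozen.
        spec_counts: dict = {}
        for window in (cfg.year1, cfg.year2):
            for specialty, arr in specialty_patient_counts(
                self.encounters, window
            ).items():
                spec_counts.setdefault(specialty, [])
                spec_counts[specialty] = list(spec_counts[specialty]) + list(arr)
        caps = (compute_specialty_caps(spec_counts) if spec_counts
                else SpecialtyCaps(cap={}))

        vectors_y1 = build_visit_vectors(
            self.encounters, ids, cfg.year1, caps, cfg.med_weights
        )
        vectors_y2 = build_visit_vectors(
            self.encounters, ids, cfg.year2, caps, cfg.med_weights
        )

        # Model development uses patients active in the first window.
        active = vectors_y1.index[(vectors_y1[VECTOR_COLUMNS] > 0).any(axis=1)]
        train_ids, test_ids = train_test_split_ids(
            active, cfg.train_fraction, seed
        )
        logger.info("split: %d active -> %d train / %d test",
                    len(active), len(train_ids), len(test_ids))

        classifier = PhenotypeClassifier(config=cfg, seed=seed)
        classifier.fit(vectors_y1.loc[train_ids])
        phenotypes_train = classifier.training_assignments_

        # The whole empaneled population is assigned on concurrent-year
        # (second window) activity using the frozen algorithm.
        phenotypes_full = classifier.predict(vectors_y2)
        work = assign_work_clusters(
            phenotypes_full["phenotype"], vectors_y2, cfg
        )
        weights = compute_cluster_weights(
            work["final"], vectors_y2["effective_pcp"], cfg.inactive_weight
        )

        roster = self.patients.set_index("patient_id")
        assignments = work.join(roster[["provider", "clinic"]])
        provider_panels = weighted_panel_size(assignments, weights, "provider")
        clinic_panels = weighted_panel_size(assignments, weights, "clinic")

        comparison = None
        if validate:
            phen_test = classifier.predict(vectors_y1.loc[test_ids])
            train_tab = build_feature_table(
                self.patients, phenotypes_train["phenotype"],
                vectors_y1.loc[train_ids], vectors_y2,
                cfg.payer_scheme, log_offset=cfg.log_offset,
            )
            test_tab = build_feature_table(
                self.patients, phen_test["phenotype"],
                vectors_y1.loc[test_ids], vectors_y2,
                cfg.payer_scheme, log_offset=cfg.log_offset,
            )
            comparison = model_comparison_table(train_tab, test_tab)

        return PanelWeightResults(
            model=self,
            config=cfg,
            seed=seed,
            caps_=caps,
            vectors_y1_=vectors_y1,
            vectors_y2_=vectors_y2,
            train_ids_=train_ids,
            test_ids_=test_ids,
            classifier_=classifier,
            phenotypes_train_=phenotypes_train,
            phenotypes_=phenotypes_full,
            work_clusters_=work,
            weights_=weights,
            provider_panels_=provider_panels,
            clinic_panels_=clinic_panels,
            validation_=comparison,
        )


@dataclass
class PanelWeightResults:
    """Fitted pipeline outputs (trailing underscores mark estimated state)."""

    model: PanelWeightModel
    config: PipelineConfig
    seed: int
    caps_: SpecialtyCaps
    vectors_y1_: pd.DataFrame
    vectors_y2_: pd.DataFrame
    train_ids_: pd.Index
    test_ids_: pd.Index
    classifier_: PhenotypeClassifier
    phenotypes_train_: pd.DataFrame
    phenotypes_: pd.DataFrame          # full population, concurrent year
    work_clusters_: pd.DataFrame
    weights_: ClusterWeights
    provider_panels_: pd.DataFrame
    clinic_panels_: pd.DataFrame
    validation_: pd.DataFrame | None = None

    @property
    def cluster_sizes_(self) -> dict:
        counts = self.work_clusters_["final"].value_counts()
        return {c: int(counts.get(c, 0)) for c in FINAL_ORDER}

    @property
    def total_weighted_size_(self) -> float:
        sizes = self.cluster_sizes_
        return float(sum(sizes[c] * self.weights_.weight[c] for c in FINAL_ORDER))

    def panel_report(self, min_panel: int | None = None) -> dict:
        min_panel = self.config.min_panel if min_panel is None else min_panel
        return panel_change_report(self.provider_panels_, min_panel)

    def summary(self) -> str:
        lines = ["Panel weighting results", "=" * 60]
        lines.append(f"patients: {len(self.model.patients)}   "
                     f"train/test: {len(self.train_ids_)}/{len(self.test_ids_)}   "
                     f"seed: {self.seed}")
        counts = self.phenotypes_["phenotype"].value_counts()
        lines.append("\nUtilization phenotypes (full population, concurrent year):")
        lines.append("  " + "  ".join(
            f"{p}:{int(counts.get(p, 0))}" for p in PHENOTYPES
        ))
        sizes = self.cluster_sizes_
        w = self.weights_
        lines.append("\nWork clusters, medians and weights "
                     f"(scaling factor w = {w.w:.4f}):")
        lines.append(f"  {'cluster':<10}{'n':>8}{'median eff. PCP':>18}"
                     f"{'weight':>10}{'weighted n':>12}")
        for c in FINAL_ORDER:
            med = w.medians.get(c)
            med_str = f"{med:.2f}" if med is not None else "-"
            lines.append(
                f"  {c:<10}{sizes[c]:>8}{med_str:>18}"
                f"{w.weight[c]:>10.3f}{sizes[c] * w.weight[c]:>12.1f}"
            )
        lines.append(f"  total weighted size: {self.total_weighted_size_:.3f} "
                     f"(unweighted {sum(sizes.values())})")
        rep = self.panel_report()
        lines.append(
            f"\nProviders with panels > {self.config.min_panel}: "
            f"{rep['n_units']} (excluded {rep['n_excluded']}); "
            f"mean panel change {rep['mean_change_pct']:+.1f}%"
        )
        if self.validation_ is not None:
            lines.append("\nNext-year utilization prediction "
                         "(log-linear, test-set R2):")
            tab = self.validation_
            for _, row in tab.iterrows():
                star = " *" if row["best_aic"] else ""
                lines.append(
                    f"  {row['model']:<28} adjR2(test)={row['adjusted_r2_test']:.3f}"
                    f"  AIC={row['aic']:.0f}{star}"
                )
        return "\n".join(lines)

    def plot_panel_change(self, ax=None, min_panel: int | None = None):
        """Histogram of relative panel-size change across providers."""
        import matplotlib.pyplot as plt

        min_panel = self.config.min_panel if min_panel is None else min_panel
        eligible = self.provider_panels_[
            self.provider_panels_["unweighted_size"] > min_panel
        ]
        if ax is None:
            _, ax = plt.subplots()
        ax.hist(eligible["relative_change_pct"], bins=20, edgecolor="black")
        ax.set_xlabel("relative change in panel size (%)")
        ax.set_ylabel("providers")
        ax.axvline(0, color="grey", lw=1)
        return ax

    def save(self, outdir: str | Path) -> None:
        """Write every stage's artifact as CSV/JSON with provenance headers."""
        outdir = Path(outdir)
        h, s = self.config.hash(), self.seed
        pio.write_csv(self.vectors_y1_, outdir / "visit_vectors_y1.csv", h, s)
        pio.write_csv(self.vectors_y2_, outdir / "visit_vectors_y2.csv", h, s)
        pio.write_csv(self.phenotypes_, outdir / "phenotypes.csv", h, s)
        pio.write_csv(self.work_clusters_, outdir / "work_clusters.csv", h, s)
        pio.write_csv(self.provider_panels_, outdir / "panel_summary.csv", h, s)
        pio.write_csv(self.clinic_panels_, outdir / "clinic_summary.csv", h, s)
        if self.validation_ is not None:
            pio.write_csv(self.validation_, outdir / "model_comparison.csv",
                          h, s, index=False)
        pio.write_json(
            {
                "weights": self.weights_.weight,
                "w": self.weights_.w,
                "medians": self.weights_.medians,
                "ratios": self.weights_.ratios,
                "inactive_weight_raw": self.weights_.inactive_weight_raw,
                "cluster_sizes": self.cluster_sizes_,
                "total_weighted_size": self.total_weighted_size_,
                "config_hash": h,
                "seed": s,
                "specialty_caps": self.caps_.cap,
            },
            outdir / "weights.json",
        )
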