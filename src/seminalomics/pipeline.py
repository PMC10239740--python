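"""End-to-end orchestration of the seminal-fluid metabolomics analysis.

The full chain, on synthetic data (or a loaded table): cohort ->
quantile-extreme stratification (+ contingency) -> injection sequence ->
feature table -> dQC/QC reliability filter -> QC-anchored LOESS drift
correction -> PQN -> two OPLS-DA models (morphology contrast and
sperm-count contrast, each with its orthogonal-component count chosen by
leave-one-out DQ²) -> MCUVE-PLS refinement of the count model ->
volcano statistics -> optional accurate-mass/RT annotation.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chemometrics import OPLSDA, loo_cv, select_n_orthogonal
from .containers import FeatureTable
from .mcuve import MCUVESelector
from .normalize import DEFAULT_SPAN_GRID, UVScaler, correct_drift, pqn_normalize
from .qc import DilutionFilter
from .simulate import (
    generate_cohort,
    generate_feature_table,
    generate_injection_sequence,
    make_ground_truth,
)
from .study import add_contingency, annotate_features, stratify_extremes, volcano


@dataclass
class PipelineConfig:
    """Knobs of the end-to-end run (defaults mirror the study design)."""

    seed: int = 0
    n_subjects: int = 2731
    n_per_group: int = 50
    contingency_fraction: float = 0.05
    batch_sizes: tuple[int, ...] = (105, 105)
    qc_interval: int = 8
    n_conditioning: int = 5
    n_features: int = 300
    n_discriminant: int = 30
    effect_log2: float = 1.0
    drift_amplitude: float = 0.3
    noise_cv: float = 0.10
    dilution_factor: float = 0.5
    rsd_max: float = 20.0
    ratio_bounds: tuple[float, float] = (0.2, 0.8)
    span_init: float = 0.75
    span_grid: tuple[float, ...] = DEFAULT_SPAN_GRID
    max_orth: int = 3
    n_models: int = 10000
    train_ratio: float = 0.7
    ri_threshold: float = 1.5


@dataclass
class ModelSummary:
    r2y: float
    dq2y: float
    accuracy_cv: float
    n_orth: int
    n_variables: int


@dataclass
class Report:
    """Machine-readable summary of one pipeline run."""

    config: PipelineConfig
    n_selected: int
    n_with_contingency: int
    n_features_input: int
    n_features_retained: int
    models: dict[str, ModelSummary]
    volcano: pd.DataFrame
    annotation: pd.DataFrame | None = None
    qc_report: pd.DataFrame | None = None
    audit: pd.DataFrame | None = None
    mcuve_profile: pd.DataFrame | None = None

    def summary_dict(self) -> dict:
        return {
            "n_selected": self.n_selected,
            "n_with_contingency": self.n_with_contingency,
            "n_features_input": self.n_features_input,
            "n_features_retained": self.n_features_retained,
            "models": {k: asdict(v) for k, v in self.models.items()},
        }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(
                {"config": asdict(self.config), **self.summary_dict()}, fh, indent=2
            )
        self.volcano.rename_axis("feature_id").to_csv(out / "volcano.tsv", sep="\t")
        for name, df in (
            ("annotation", self.annotation),
            ("qc_report", self.qc_report),
            ("audit", self.audit),
            ("mcuve_profile", self.mcuve_profile),
        ):
            if df is not None:
                df.to_csv(out / f"{name}.tsv", sep="\t")


def _fit_contrast(X: np.ndarray, y: np.ndarray, max_orth: int) -> tuple[ModelSummary, int]:
    n_orth = select_n_orthogonal(X, y, max_orth)
    cv = loo_cv(X, y, n_orth)
    full = OPLSDA(n_orth=n_orth).fit(UVScaler().fit_transform(X), y)
    return (
        ModelSummary(
            r2y=float(full.r2y_),
            dq2y=float(cv.dq2y),
            accuracy_cv=float(cv.accuracy_cv),
            n_orth=n_orth,
            n_variables=X.shape[1],
        ),
        n_orth,
    )


def run_pipeline(
    config: PipelineConfig | None = None,
    library: pd.DataFrame | None = None,
) -> Report:
    """Run the whole synthetic-data analysis; deterministic in the seed."""
    cfg = config or PipelineConfig()
    seeds = np.random.SeedSequence(cfg.seed).generate_state(4) % (2**31)

    # 1. cohort and stratified design
    cohort = generate_cohort(cfg.n_subjects, seed=int(seeds[0]))
    design = stratify_extremes(cohort, n_per_group=cfg.n_per_group)
    n_selected = design.n_selected
    design = add_contingency(design, fraction=cfg.contingency_fraction)

    # 2. randomized injection order over the configured batches
    rng = np.random.default_rng(int(seeds[1]))
    subjects = design.table.index.to_numpy()
    run_order = subjects[rng.permutation(len(subjects))]
    sequence = generate_injection_sequence(
        list(run_order),
        batch_sizes=list(cfg.batch_sizes),
        qc_interval=cfg.qc_interval,
        n_conditioning=cfg.n_conditioning,
    )
    sample_classes = {
        sid: {
            "group": design.table.loc[sid, "group"],
            "ts_class": design.table.loc[sid, "ts_class"],
            "mo_class": design.table.loc[sid, "mo_class"],
        }
        for sid in subjects
    }
    truth = make_ground_truth(
        sequence,
        n_features=cfg.n_features,
        drift_amplitude=cfg.drift_amplitude,
        n_discriminant=cfg.n_discriminant,
        effect_log2=cfg.effect_log2,
        dilution_factor=cfg.dilution_factor,
        noise_cv=cfg.noise_cv,
        sample_classes=sample_classes,
        seed=int(seeds[2]),
    )
    table = generate_feature_table(sequence, truth, cfg.n_features, seed=int(seeds[3]))

    # 3. reliability filter, drift correction, PQN
    filt = DilutionFilter(rsd_max=cfg.rsd_max, ratio_bounds=cfg.ratio_bounds)
    table_f = filt.fit_transform(table)
    table_c, corrector = correct_drift(
        table_f, span_init=cfg.span_init, span_grid=cfg.span_grid
    )
    table_n, _ = pqn_normalize(table_c)

    # 4. study matrices
    study_mask = table_n.role_mask("study").to_numpy()
    X = table_n.intensities.loc[study_mask].to_numpy(dtype=float)
    meta = table_n.sample_meta.loc[study_mask]
    y_mo = meta["mo_class"].to_numpy()
    y_ts = meta["ts_class"].to_numpy()

    models: dict[str, ModelSummary] = {}
    models["morphology"], _ = _fit_contrast(X, y_mo, cfg.max_orth)
    models["count"], n_orth_count = _fit_contrast(X, y_ts, cfg.max_orth)

    # 5. MCUVE refinement of the count contrast
    selector = MCUVESelector(
        n_models=cfg.n_models,
        train_ratio=cfg.train_ratio,
        n_components=min(3, 1 + n_orth_count),
        threshold=cfg.ri_threshold,
        random_state=int(seeds[2]),
    ).fit(X, y_ts)
    X_ref = selector.transform(X)
    if X_ref.shape[1] >= 2:
        models["count_refined"], _ = _fit_contrast(X_ref, y_ts, cfg.max_orth)

    # 6. volcano + annotation
    study_intens = table_n.intensities.loc[study_mask]
    vol = volcano(study_intens, meta["ts_class"])
    annotation = None
    if library is not None:
        annotation = annotate_features(table_n.feature_meta, library)

    profile = selector.profile_.copy()
    profile.index = table_n.feature_ids
    profile["retained"] = selector.support_
    return Report(
        config=cfg,
        n_selected=n_selected,
        n_with_contingency=design.n_selected,
        n_features_input=cfg.n_features,
        n_features_retained=table_f.intensities.shape[1],
        models=models,
        volcano=vol,
        annotation=annotation,
        qc_report=filt.report(),
        audit=corrector.audit_,
        mcuve_profile=profile,
    )
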