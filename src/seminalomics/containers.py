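"""Central data containers for the pipeline.

The pipeline starts from an *aligned feature table*: a matrix of peak
intensities (one row per analytical injection, one column per LC-MS
feature), per-feature m/z and retention-time metadata, and per-injection
sequence metadata (injection order, batch, role in the sequence, and —
for study samples — class labels).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

#: roles an injection can play in the analytical sequence
ROLES = ("study", "qc", "dqc", "blank", "conditioning")

SAMPLE_META_COLUMNS = (
    "injection_order",
    "batch",
    "role",
    "sample_id",
    "group",
    "ts_class",
    "mo_class",
)


@dataclass
class GroundTruth:
    """Known generative structure of a synthetic feature table.

    Used as the oracle for every downstream stage: drift curves and batch
    offsets for the correction step, the dilution factor for the dQC/QC
    filter, and the planted discriminant features for the modelling steps.

    Parameters
    ----------
    drift_fns
        Per-batch smooth, strictly positive function of injection order
        (multiplicative drift).
    batch_offsets
        Per-batch multiplicative offset.
    discriminant_features
        Mapping feature id -> log2 effect size applied to study samples
        whose ``ts_class`` is ``"high"``.
    dilution_factor
        Expected dQC/QC intensity ratio; 0.5 for a 1:1 dilution.
    noise_cv
        Coefficient of variation of the multiplicative log-normal noise.
    sample_classes
        Mapping sample_id -> dict with keys ``group``, ``ts_class``,
        ``mo_class`` for study samples.
    blank_level
        Relative intensity level of blank injections (near zero).
    missing_rate
        Probability that any single entry is reported missing.
    """

    drift_fns: Mapping[int, Callable[[np.ndarray], np.ndarray]]
    batch_offsets: Mapping[int, float]
    discriminant_features: Mapping[str, float] = field(default_factory=dict)
    dilution_factor: float = 0.5
    noise_cv: float = 0.0
    sample_classes: Mapping[str, Mapping[str, str]] = field(default_factory=dict)
    blank_level: float = 1e-4
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.dilution_factor <= 1.0):
            raise ValueError("dilution_factor must lie in (0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        for fid, eff in self.discriminant_features.items():
            if not np.isfinite(eff):
                raise ValueError(f"effect size for feature {fid!r} is not finite")


@dataclass
class FeatureTable:
    """Aligned LC-MS feature table plus sequence and feature metadata.

    Attributes
    ----------
    intensities
        DataFrame (injections x features), indexed by injection order,
        columns are feature ids. Non-negative; NaN marks missing peaks.
    feature_meta
        DataFrame indexed by feature id with columns ``mz`` (Th) and
        ``rt`` (min).
    sample_meta
        DataFrame indexed by injection order with columns ``batch``,
        ``role``, ``sample_id`` and, for study samples, ``group``,
        ``ts_class``, ``mo_class``.
    """

    intensities: pd.DataFrame
    feature_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.intensities) != len(self.sample_meta):
            raise ValueError("intensities and sample_meta row counts differ")
        if not self.intensities.index.equals(self.sample_meta.index):
            raise ValueError("intensities and sample_meta indices differ")
        if not self.intensities.columns.equals(self.feature_meta.index):
            raise ValueError("intensity columns do not match feature_meta index")
        bad_roles = set(self.sample_meta["role"]) - set(ROLES)
        if bad_roles:
            raise ValueError(f"unknown injection roles: {sorted(bad_roles)}")
        if (self.feature_meta["mz"] <= 0).any():
            raise ValueError("feature m/z must be positive")
        if (self.feature_meta["rt"] < 0).any():
            raise ValueError("feature RT must be non-negative")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("intensities must be non-negative")

    # -- convenience selectors -------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.intensities.columns

    def role_mask(self, *roles: str) -> pd.Series:
        return self.sample_meta["role"].isin(roles)

    def rows(self, *roles: str) -> pd.DataFrame:
        """Intensity rows restricted to the given sequence roles."""
        return self.intensities.loc[self.role_mask(*roles).to_numpy()]

    def subset_features(self, feature_ids) -> "FeatureTable":
        feature_ids = pd.Index(feature_ids)
        return FeatureTable(
            intensities=self.intensities.loc[:, feature_ids].copy(),
            feature_meta=self.feature_meta.loc[feature_ids].copy(),
            sample_meta=self.sample_meta.copy(),
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.intensities.copy(), self.feature_meta.copy(), self.sample_meta.copy()
        )

    # -- plain-text persistence ------------------------------------------
    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.intensities.rename_axis("injection_order").to_csv(
            out / "intensities.tsv", sep="\t"
        )
        self.feature_meta.rename_axis("id").to_csv(out / "feature_meta.tsv", sep="\t")
        self.sample_meta.rename_axis("injection_order").to_csv(
            out / "sample_meta.tsv", sep="\t"
        )

    @classmethod
    def read(cls, in_dir: str | Path) -> "FeatureTable":
        src = Path(in_dir)
        intens = pd.read_csv(src / "intensities.tsv", sep="\t", index_col=0)
        fmeta = pd.read_csv(src / "feature_meta.tsv", sep="\t", index_col=0)
        smeta = pd.read_csv(
            src / "sample_meta.tsv", sep="\t", index_col=0, keep_default_na=False
        )
        for col in ("sample_id", "group", "ts_class", "mo_class"):
            if col in smeta:
                smeta[col] = smeta[col].mask(smeta[col] == "", np.nan)
        return cls(intens, fmeta, smeta)
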