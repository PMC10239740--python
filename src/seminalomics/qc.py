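"""Feature reliability filtering from QC/dQC dilution pairs.

A pooled QC and its 1:1 dilution (dQC) are injected as adjacent pairs
through the sequence. A feature responding linearly to concentration
shows a dQC/QC intensity ratio near the theoretical 0.5; features whose
mean pair ratio falls outside [0.2, 0.8] or whose ratio RSD exceeds 20%
are considered analytically unreliable and removed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FeatureTable

REASON_NONE = "none"
REASON_UNDEFINED = "undefined_stats"
REASON_RANGE = "ratio_out_of_range"
REASON_RSD = "rsd_too_high"


@dataclass
class FeatureQCStats:
    """Per-feature dQC/QC dilution statistics.

    ``per_feature`` has columns ``ratio_center`` (mean pair ratio),
    ``ratio_rsd`` (% of the mean, sample sd), ``n_pairs`` (valid pairs)
    and ``defined`` (at least 2 valid pairs). ``pair_ratios`` holds one
    row per QC/dQC pair (NaN where a pair was skipped for a feature).
    """

    per_feature: pd.DataFrame
    pair_ratios: pd.DataFrame


def find_qc_dqc_pairs(sample_meta: pd.DataFrame) -> list[tuple[int, int]]:
    """Adjacent (QC order, dQC order) pairs, scanning the sequence in order."""
    meta = sample_meta.sort_index()
    orders = meta.index.to_numpy()
    roles = meta["role"].to_numpy()
    pairs = []
    i = 0
    while i < len(meta) - 1:
        a, b = roles[i], roles[i + 1]
        if {a, b} == {"qc", "dqc"}:
            qc = orders[i] if a == "qc" else orders[i + 1]
            dqc = orders[i + 1] if a == "qc" else orders[i]
            pairs.append((int(qc), int(dqc)))
            i += 2
        else:
            i += 1
    return pairs


def compute_dqc_qc_stats(table: FeatureTable) -> FeatureQCStats:
    """Per-pair dQC/QC intensity ratios and their center/RSD per feature.

    Pairs with a missing or zero QC intensity (or a missing dQC
    intensity) are skipped for that feature. The center is the
    arithmetic mean of pair ratios; the RSD is 100 * sample sd / mean.
    """
    pairs = find_qc_dqc_pairs(table.sample_meta)
    if not pairs:
        raise ValueError("no adjacent QC/dQC pairs found in the sequence")
    qc_rows = table.intensities.loc[[q for q, _ in pairs]].to_numpy(dtype=float)
    dqc_rows = table.intensities.loc[[d for _, d in pairs]].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(
            np.isfinite(qc_rows) & (qc_rows != 0) & np.isfinite(dqc_rows),
            dqc_rows / qc_rows,
            np.nan,
        )
    n_valid = np.sum(np.isfinite(ratios), axis=0)
    sums = np.nansum(np.where(np.isfinite(ratios), ratios, 0.0), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        center = np.where(n_valid > 0, sums / np.maximum(n_valid, 1), np.nan)
    sd = np.full(ratios.shape[1], np.nan)
    for j in range(ratios.shape[1]):
        col = ratios[:, j]
        col = col[np.isfinite(col)]
        if len(col) >= 2:
            sd[j] = np.std(col, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = 100.0 * sd / center
    defined = n_valid >= 2
    per_feature = pd.DataFrame(
        {
            "ratio_center": center,
            "ratio_rsd": rsd,
            "n_pairs": n_valid,
            "defined": defined,
        },
        index=table.feature_ids,
    )
    pair_index = pd.Index([f"pair_{q}_{d}" for q, d in pairs], name="pair")
    return FeatureQCStats(
        per_feature=per_feature,
        pair_ratios=pd.DataFrame(ratios, index=pair_index, columns=table.feature_ids),
    )


def filter_features(
    stats: FeatureQCStats,
    rsd_max: float = 20.0,
    ratio_bounds: tuple[float, float] = (0.2, 0.8),
) -> pd.DataFrame:
    """Reliability mask from dilution statistics.

    A feature is retained iff its stats are defined, its mean dQC/QC
    ratio lies in the closed interval ``ratio_bounds`` and its ratio RSD
    is at most ``rsd_max`` (%). ``reject_reason`` records the first rule
    failed, checked in the order undefined -> ratio range -> RSD.
    """
    lo, hi = ratio_bounds
    if lo > hi:
        raise ValueError("ratio_bounds must be ordered (lo <= hi)")
    pf = stats.per_feature
    reason = np.full(len(pf), REASON_NONE, dtype=object)
    defined = pf["defined"].to_numpy(dtype=bool)
    center = pf["ratio_center"].to_numpy(dtype=float)
    rsd = pf["ratio_rsd"].to_numpy(dtype=float)
    reason[~defined] = REASON_UNDEFINED
    out_of_range = defined & ((center < lo) | (center > hi))
    reason[out_of_range] = REASON_RANGE
    too_noisy = defined & ~out_of_range & (rsd > rsd_max)
    reason[too_noisy] = REASON_RSD
    return pd.DataFrame(
        {"retained": reason == REASON_NONE, "reject_reason": reason}, index=pf.index
    )


class DilutionFilter:
    """Estimator-style wrapper: fit dilution stats, transform the table.

    Parameters mirror :func:`filter_features`. After ``fit``,
    ``stats_`` holds the :class:`FeatureQCStats` and ``mask_`` the
    retained/reject table; ``transform`` drops rejected features.
    """

    def __init__(self, rsd_max: float = 20.0, ratio_bounds=(0.2, 0.8)):
        self.rsd_max = rsd_max
        self.ratio_bounds = ratio_bounds

    def get_params(self, deep: bool = True) -> dict:
        return {"rsd_max": self.rsd_max, "ratio_bounds": self.ratio_bounds}

    def set_params(self, **params) -> "DilutionFilter":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, table: FeatureTable) -> "DilutionFilter":
        self.stats_ = compute_dqc_qc_stats(table)
        self.mask_ = filter_features(
            self.stats_, rsd_max=self.rsd_max, ratio_bounds=tuple(self.ratio_bounds)
        )
        return self

    def transform(self, table: FeatureTable) -> FeatureTable:
        retained = self.mask_.index[self.mask_["retained"]]
        return table.subset_features(retained)

    def fit_transform(self, table: FeatureTable) -> FeatureTable:
        return self.fit(table).transform(table)

    def report(self) -> pd.DataFrame:
        """Per-feature QC report (center, RSD, n_pairs, retained, reason)."""
        rep = self.stats_.per_feature.join(self.mask_)
        return rep
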