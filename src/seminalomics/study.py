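"""Study-level operations: cohort stratification, annotation, volcano.

The original seminal-fluid study this pipeline re-implements selected,
from a cohort of 2731 young men, the 200 subjects most extreme in the
joint quantile distribution of total sperm count (TS) and normal
morphology (MO): four groups of 50 crossing low/high TS with
abnormal/normal MO, plus a 5% contingency margin (10 extra subjects,
for 210 analysed samples). Features were annotated against an in-house
accurate-mass/RT library and class differences summarised in a volcano
plot (positive fold change = higher in the high-sperm-count group).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

GROUP_LABELS = {
    ("low", "abnormal"): "G1",
    ("low", "normal"): "G2",
    ("high", "abnormal"): "G3",
    ("high", "normal"): "G4",
}

#: proton/sodium/water-loss adduct mass offsets (Da) for positive ESI
ADDUCT_MASSES = {
    "[M+H]+": 1.007276,
    "[M+Na]+": 22.989218,
    "[M+H-H2O]+": -17.003289,
    "[M+H-2H2O]+": -35.013854,
}

#: composition of the annotated metabolite panel in the reference study
#: (accurate-mass/RT level-1 annotations per source library)
REFERENCE_PANEL_COUNTS = {"MSMLS": 110, "steroid": 69, "oxylipin": 22, "acylcarnitine": 9}

#: semen-parameter PCA variance shares (%) reported for the full cohort
REFERENCE_PCA_VARIANCE_PCT = (33.5, 21.0, 19.2, 11.3)

#: size of the MCUVE-refined variable panel in the reference study
REFERENCE_REFINED_PANEL = 87


@dataclass
class StratifiedDesign:
    """Quantile-extreme group assignment of selected subjects.

    ``table`` is indexed by subject id with columns ``group`` (G1–G4),
    ``ts_class`` (low/high), ``mo_class`` (abnormal/normal) and
    ``contingency`` (extra samples added to cover losses).
    """

    table: pd.DataFrame
    n_per_group: int
    _pool: pd.DataFrame = field(default=None, repr=False)

    @property
    def n_selected(self) -> int:
        return len(self.table)

    def group(self, label: str) -> pd.Index:
        return self.table.index[self.table["group"] == label]


def _quantiles(cohort: pd.DataFrame) -> pd.DataFrame:
    n = len(cohort)
    q = pd.DataFrame(index=cohort.index)
    q["q_ts"] = cohort["TS"].rank(method="average") / n
    q["q_mo"] = cohort["MO"].rank(method="average") / n
    q["mo_class"] = np.where(q["q_mo"] < 0.5, "abnormal", "normal")
    return q


def stratify_extremes(cohort: pd.DataFrame, n_per_group: int = 50) -> StratifiedDesign:
    """Select the 4 x ``n_per_group`` most TS-extreme subjects per MO stratum.

    Subjects are split at the MO quantile median into abnormal/normal
    strata; within each stratum the ``n_per_group`` lowest and highest
    TS-quantile subjects form the low-TS and high-TS groups (extremeness
    is the distance of the TS quantile from the median). Ties are broken
    by subject id, so the selection is deterministic.
    """
    if len(cohort) < 4 * n_per_group:
        raise ValueError("cohort smaller than 4 * n_per_group")
    q = _quantiles(cohort)
    rows = []
    for mo_class in ("abnormal", "normal"):
        # stable sort on q_ts after an id sort == tie-break by subject id
        stratum = (
            q[q["mo_class"] == mo_class]
            .sort_index()
            .sort_values("q_ts", kind="mergesort")
        )
        if len(stratum) < 2 * n_per_group:
            raise ValueError(
                f"stratum {mo_class!r} has only {len(stratum)} subjects; "
                f"needs {2 * n_per_group}"
            )
        low = stratum.index[:n_per_group]
        high = stratum.index[-n_per_group:]
        for ids, ts_class in ((low, "low"), (high, "high")):
            for sid in ids:
                rows.append(
                    {
                        "subject_id": sid,
                        "group": GROUP_LABELS[(ts_class, mo_class)],
                        "ts_class": ts_class,
                        "mo_class": mo_class,
                        "contingency": False,
                    }
                )
    table = pd.DataFrame(rows).set_index("subject_id")
    return StratifiedDesign(table=table, n_per_group=n_per_group, _pool=q)


def add_contingency(design: StratifiedDesign, fraction: float = 0.05) -> StratifiedDesign:
    """Add ``round(fraction * n)`` next-most-extreme subjects as spares.

    Rounding is half-away-from-zero (5% of 200 -> 10). Extras are spread
    evenly over the four groups; any remainder goes to the groups whose
    next candidate is most extreme (largest TS-quantile distance from
    the median, group label as tie-break). Added subjects are flagged
    ``contingency = True``.
    """
    if fraction < 0:
        raise ValueError("fraction must be non-negative")
    n_extra = int(math.floor(fraction * design.n_selected + 0.5))
    if n_extra == 0:
        return design
    q = design._pool
    selected = set(design.table.index)
    # per-group candidate queues: next-most-extreme unselected subjects
    queues: dict[str, list] = {}
    margins: dict[str, float] = {}
    for (ts_class, mo_class), label in GROUP_LABELS.items():
        stratum = q[(q["mo_class"] == mo_class) & (~q.index.isin(selected))]
        stratum = stratum.sort_index().sort_values("q_ts", kind="mergesort")
        ids = list(stratum.index) if ts_class == "low" else list(stratum.index[::-1])
        queues[label] = ids
        if ids:
            margins[label] = abs(q.loc[ids[0], "q_ts"] - 0.5)
        else:
            margins[label] = -np.inf
    base, rem = divmod(n_extra, 4)
    labels = sorted(GROUP_LABELS.values())
    bonus = sorted(labels, key=lambda g: (-margins[g], g))[:rem]
    allocation = {g: base + (1 if g in bonus else 0) for g in labels}
    rows = []
    for g, k in allocation.items():
        if len(queues[g]) < k:
            raise ValueError(f"candidate pool exhausted for group {g}")
        meta = design.table[design.table["group"] == g].iloc[0]
        for sid in queues[g][:k]:
            rows.append(
                {
                    "subject_id": sid,
                    "group": g,
                    "ts_class": meta["ts_class"],
                    "mo_class": meta["mo_class"],
                    "contingency": True,
                }
            )
    extra = pd.DataFrame(rows).set_index("subject_id")
    return StratifiedDesign(
        table=pd.concat([design.table, extra]),
        n_per_group=design.n_per_group,
        _pool=q,
    )


def annotate_features(
    feature_meta: pd.DataFrame,
    library: pd.DataFrame,
    ppm_tol: float = 5.0,
    rt_tol: float = 0.2,
) -> pd.DataFrame:
    """Accurate-mass + RT annotation with positive-ESI adduct enumeration.

    ``library`` needs columns ``compound``, ``mass`` (monoisotopic,
    Da), ``rt`` (min) and ``library`` (source class). For each feature,
    every library entry whose adduct m/z matches within ``ppm_tol`` and
    whose RT matches within ``rt_tol`` is reported; hits are ranked by
    absolute ppm error within each feature. A feature may hit several
    entries (and vice versa).
    """
    if ppm_tol <= 0 or rt_tol <= 0:
        raise ValueError("tolerances must be positive")
    if len(library) == 0:
        raise ValueError("annotation library is empty")
    lib_mass = library["mass"].to_numpy(dtype=float)
    lib_rt = library["rt"].to_numpy(dtype=float)
    hits = []
    for fid, row in feature_meta.iterrows():
        for adduct, delta in ADDUCT_MASSES.items():
            expected = lib_mass + delta
            ppm = (row["mz"] - expected) / expected * 1e6
            rt_err = row["rt"] - lib_rt
            ok = (np.abs(ppm) <= ppm_tol) & (np.abs(rt_err) <= rt_tol)
            for j in np.where(ok)[0]:
                hits.append(
                    {
                        "feature_id": fid,
                        "compound": library["compound"].iloc[j],
                        "library": library["library"].iloc[j],
                        "adduct": adduct,
                        "ppm_error": ppm[j],
                        "rt_error": rt_err[j],
                    }
                )
    out = pd.DataFrame(
        hits,
        columns=["feature_id", "compound", "library", "adduct", "ppm_error", "rt_error"],
    )
    if len(out):
        out["abs_ppm"] = out["ppm_error"].abs()
        out = (
            out.sort_values(["feature_id", "abs_ppm"], kind="mergesort")
            .drop(columns="abs_ppm")
            .reset_index(drop=True)
        )
    return out


def volcano(intensities: pd.DataFrame, ts_class: pd.Series) -> pd.DataFrame:
    """Per-metabolite fold change and Welch test between TS classes.

    Fold change is log2(mean high / mean low) — positive means higher in
    the high-sperm-count class. P-values come from a two-sided Welch
    (unequal-variance) t-test on the supplied intensities; q-values are
    Benjamini–Hochberg adjusted across the panel.
    """
    labels = ts_class.loc[intensities.index]
    hi = intensities.loc[(labels == "high").to_numpy()]
    lo = intensities.loc[(labels == "low").to_numpy()]
    if len(hi) < 2 or len(lo) < 2:
        raise ValueError("each TS class needs at least 2 samples")
    mean_hi = hi.mean(axis=0, skipna=True)
    mean_lo = lo.mean(axis=0, skipna=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(mean_hi / mean_lo)
    res = sps.ttest_ind(
        hi.to_numpy(dtype=float), lo.to_numpy(dtype=float),
        equal_var=False, nan_policy="omit", axis=0,
    )
    p = np.asarray(res.pvalue, dtype=float)
    # degenerate zero-variance columns: equal means are not evidence
    var_hi = hi.var(axis=0, ddof=1).to_numpy()
    var_lo = lo.var(axis=0, ddof=1).to_numpy()
    degenerate = (var_hi == 0) & (var_lo == 0)
    p[degenerate & (mean_hi.to_numpy() == mean_lo.to_numpy())] = 1.0
    p[degenerate & (mean_hi.to_numpy() != mean_lo.to_numpy())] = 0.0
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"log2_fc": log2fc, "p_value": p, "q_value": q}, index=intensities.columns
    )
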