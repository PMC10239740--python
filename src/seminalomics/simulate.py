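"""Synthetic cohorts and QC/dQC-structured LC-MS feature tables.

Everything downstream of vendor peak alignment can be exercised on data
generated here: a semen-parameter cohort with a four-latent-factor
structure (a global motility factor opposing static sperm, a count
factor driving concentration and total sperm count together, a second
motility contrast, and an independent morphology factor), and a
multi-batch injection sequence where a pooled QC and a 1:1-diluted QC
(dQC) are injected as a pair every ``qc_interval`` study samples.

The feature-table generator plants known multiplicative structure —
smooth within-batch drift, per-batch offsets, a dQC dilution factor, and
log2 class effects on a chosen feature subset — so each processing stage
has an exact or distributional oracle.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import FeatureTable, GroundTruth

COHORT_COLUMNS = ("SP", "QP", "NP", "HY", "ST", "CO", "TS", "MO")


@dataclass
class CohortConfig:
    """Latent-factor settings for the semen-parameter generator.

    ``rho_co_ts`` is the target Pearson correlation between sperm
    concentration (CO, million/mL) and total sperm count (TS,
    million/ejaculate); the two share a single latent count factor.
    ``noise_scale`` multiplies the per-parameter residual noise of the
    motility and morphology blocks.
    """

    rho_co_ts: float = 0.9
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho_co_ts <= 1.0):
            raise ValueError("rho_co_ts must lie in [0, 1]")
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be positive")


def generate_cohort(
    n_subjects: int, config: CohortConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """Generate ``n_subjects`` semen-parameter records.

    Returns a DataFrame indexed by ``subject_id`` with the eight CASA
    parameters: SP, QP, NP, HY, ST (motility class counts, millions),
    CO (million/mL), TS (million/ejaculate) and MO (% normal morphology).
    Deterministic given ``seed``; values clipped to their valid ranges.
    """
    if n_subjects < 0:
        raise ValueError("n_subjects must be non-negative")
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)
    ids = [f"S{i:05d}" for i in range(n_subjects)]
    if n_subjects == 0:
        return pd.DataFrame(columns=list(COHORT_COLUMNS), index=pd.Index(ids, name="subject_id"))

    motility, motility2, count, morph = rng.standard_normal((4, n_subjects))
    e = rng.standard_normal((8, n_subjects)) * config.noise_scale

    sp = 20 + 9 * motility - 4 * motility2 + 3 * e[0]
    qp = 25 + 11 * motility + 5 * motility2 + 3 * e[1]
    np_ = 12 + 5 * motility - 3 * motility2 + 2 * e[2]
    hy = 6 + 3 * motility + 2 * motility2 + 1.5 * e[3]
    st = 30 - 12 * motility + 4 * e[4]
    # CO and TS share the count factor; corr(CO, TS) = rho by construction
    r = config.rho_co_ts
    co = 60 + 20 * (np.sqrt(r) * count + np.sqrt(1 - r) * e[5] / config.noise_scale)
    ts = 180 + 60 * (np.sqrt(r) * count + np.sqrt(1 - r) * e[6] / config.noise_scale)
    mo = 40 + 14 * morph + 4 * e[7]

    out = pd.DataFrame(
        {
            "SP": sp, "QP": qp, "NP": np_, "HY": hy, "ST": st,
            "CO": co, "TS": ts, "MO": mo,
        },
        index=pd.Index(ids, name="subject_id"),
    ).clip(lower=0.0)
    out["MO"] = out["MO"].clip(upper=100.0)
    return out


def generate_injection_sequence(
    study_sample_ids: Sequence[str],
    batch_sizes: Sequence[int],
    qc_interval: int = 8,
    n_conditioning: int = 5,
    n_blanks: int = 0,
) -> pd.DataFrame:
    """Lay out the analytical sequence as a table of injection records.

    Each batch opens with blanks (if any) and conditioning injections,
    then a leading QC/dQC pair, then blocks of at most ``qc_interval``
    study samples each followed by a QC/dQC pair; the pair after the last
    block closes the batch. Injection order is globally strictly
    increasing and contiguous within a batch.
    """
    if qc_interval < 1:
        raise ValueError("qc_interval must be >= 1")
    if n_conditioning < 0 or n_blanks < 0:
        raise ValueError("counts must be non-negative")
    if sum(batch_sizes) != len(study_sample_ids):
        raise ValueError(
            f"batch_sizes sum to {sum(batch_sizes)} but "
            f"{len(study_sample_ids)} study samples were given"
        )
    records: list[tuple[int, int, str, str]] = []
    order = 1
    pos = 0

    def add(batch: int, role: str, sample_id: str = "") -> None:
        nonlocal order
        records.append((order, batch, role, sample_id))
        order += 1

    for batch, size in enumerate(batch_sizes, start=1):
        for _ in range(n_blanks):
            add(batch, "blank")
        for _ in range(n_conditioning):
            add(batch, "conditioning")
        if size == 0:
            continue
        add(batch, "qc")
        add(batch, "dqc")
        done = 0
        while done < size:
            block = min(qc_interval, size - done)
            for sid in study_sample_ids[pos : pos + block]:
                add(batch, "study", sid)
            pos += block
            done += block
            add(batch, "qc")
            add(batch, "dqc")
    seq = pd.DataFrame(
        records, columns=["injection_order", "batch", "role", "sample_id"]
    )
    return seq


def make_ground_truth(
    sequence: pd.DataFrame,
    n_features: int,
    feature_ids: Sequence[str] | None = None,
    drift_amplitude: float = 0.3,
    batch_offset_step: float = 0.15,
    n_discriminant: int = 0,
    effect_log2: float = 1.0,
    dilution_factor: float = 0.5,
    noise_cv: float = 0.05,
    sample_classes: Mapping[str, Mapping[str, str]] | None = None,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> GroundTruth:
    """Build a :class:`GroundTruth` consistent with an injection sequence.

    Drift within batch ``b`` is a smooth cosine ramp of relative
    amplitude ``drift_amplitude`` over the batch's order range; batch
    offsets are ``1, 1 + step, 1 + 2*step, ...``. The first
    ``n_discriminant`` features carry a ``effect_log2`` log2 effect on
    the high total-sperm-count class. If ``sample_classes`` is omitted,
    study samples are split into low/high TS classes at random
    (deterministic in ``seed``).
    """
    rng = np.random.default_rng(seed)
    if feature_ids is None:
        feature_ids = [f"F{i:05d}" for i in range(n_features)]
    batches = sorted(sequence["batch"].unique())
    drift_fns = {}
    for b in batches:
        orders = sequence.loc[sequence["batch"] == b, "injection_order"]
        lo, hi = float(orders.min()), float(orders.max())
        span = max(hi - lo, 1.0)
        amp = drift_amplitude

        def drift(order, lo=lo, span=span, amp=amp):
            phase = (np.asarray(order, dtype=float) - lo) / span
            return 1.0 - amp * 0.5 * (1.0 - np.cos(np.pi * phase))

        drift_fns[b] = drift
    offsets = {b: 1.0 + batch_offset_step * i for i, b in enumerate(batches)}

    if sample_classes is None:
        sample_classes = {}
        study_ids = [s for s in sequence.loc[sequence["role"] == "study", "sample_id"]]
        flips = rng.random(len(study_ids)) < 0.5
        for sid, hi_class in zip(study_ids, flips):
            ts = "high" if hi_class else "low"
            sample_classes[sid] = {"group": "", "ts_class": ts, "mo_class": ""}

    disc = {fid: effect_log2 for fid in list(feature_ids)[:n_discriminant]}
    return GroundTruth(
        drift_fns=drift_fns,
        batch_offsets=offsets,
        discriminant_features=disc,
        dilution_factor=dilution_factor,
        noise_cv=noise_cv,
        sample_classes=sample_classes,
        missing_rate=missing_rate,
    )


def generate_feature_table(
    sequence: pd.DataFrame,
    truth: GroundTruth,
    n_features: int,
    seed: int = 0,
    feature_meta: pd.DataFrame | None = None,
) -> FeatureTable:
    """Simulate an aligned feature table over an injection sequence.

    Expected intensity of feature f at injection i is
    ``baseline(f) * drift(order_i) * batch_offset * class_effect(f, i) *
    role_factor`` with role_factor = ``dilution_factor`` for dQC, ~0 for
    blanks and 1 otherwise, times mean-one multiplicative log-normal
    noise of coefficient of variation ``truth.noise_cv``.

    ``feature_meta`` may be supplied to pin feature ids, m/z and RT
    (e.g. to engineer annotation matches); otherwise both are drawn
    uniformly over typical reversed-phase ranges.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    rng = np.random.default_rng(seed)
    if feature_meta is None:
        ids = pd.Index([f"F{i:05d}" for i in range(n_features)], name="id")
        feature_meta = pd.DataFrame(
            {
                "mz": rng.uniform(80.0, 1000.0, n_features),
                "rt": rng.uniform(0.5, 16.0, n_features),
            },
            index=ids,
        )
    else:
        feature_meta = feature_meta.copy()
        if len(feature_meta) != n_features:
            raise ValueError("feature_meta length does not match n_features")
    ids = feature_meta.index
    unknown = set(truth.discriminant_features) - set(ids)
    if unknown:
        raise ValueError(f"ground truth references unknown features: {sorted(unknown)}")

    seq = sequence.sort_values("injection_order").reset_index(drop=True)
    n_inj = len(seq)
    baseline = np.exp(rng.normal(np.log(1e5), 0.8, n_features))

    batches = seq["batch"].to_numpy()
    orders = seq["injection_order"].to_numpy(dtype=float)
    drift = np.empty(n_inj)
    offset = np.empty(n_inj)
    for b in np.unique(batches):
        m = batches == b
        if b not in truth.drift_fns or b not in truth.batch_offsets:
            raise ValueError(f"ground truth missing drift/offset for batch {b}")
        d = np.asarray(truth.drift_fns[b](orders[m]), dtype=float)
        if np.any(d <= 0):
            raise ValueError(f"drift function for batch {b} is not positive")
        drift[m] = d
        offset[m] = truth.batch_offsets[b]

    roles = seq["role"].to_numpy()
    role_factor = np.ones(n_inj)
    role_factor[roles == "dqc"] = truth.dilution_factor
    role_factor[roles == "blank"] = truth.blank_level

    expected = np.outer(drift * offset * role_factor, baseline)

    if truth.discriminant_features:
        eff = np.zeros(n_features)
        col_pos = {fid: j for j, fid in enumerate(ids)}
        for fid, e in truth.discriminant_features.items():
            eff[col_pos[fid]] = e
        high = np.array(
            [
                r == "study"
                and truth.sample_classes.get(s, {}).get("ts_class") == "high"
                for r, s in zip(roles, seq["sample_id"])
            ]
        )
        expected[high] *= 2.0 ** eff[None, :]

    if truth.noise_cv > 0:
        sigma = np.sqrt(np.log1p(truth.noise_cv**2))
        noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, expected.shape))
        expected = expected * noise
    if truth.missing_rate > 0:
        expected[rng.random(expected.shape) < truth.missing_rate] = np.nan

    intens = pd.DataFrame(
        expected, index=pd.Index(seq["injection_order"], name="injection_order"),
        columns=ids,
    )
    smeta = seq.set_index("injection_order")
    for col in ("group", "ts_class", "mo_class"):
        smeta[col] = [
            truth.sample_classes.get(s, {}).get(col, "") if r == "study" else ""
            for r, s in zip(smeta["role"], smeta["sample_id"])
        ]
    return FeatureTable(intens, feature_meta, smeta)
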