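"""Drift correction, probabilistic quotient normalization, UV scaling.

Instrument response in long LC-MS sequences drifts smoothly with
injection order and jumps between batches. Both effects are removed
with a single multiplicative map anchored on the pooled QC injections:
for every feature and batch a degree-1 LOESS curve (tricube weights) is
fitted to QC intensity versus injection order, the smoothing span being
chosen per feature by leave-one-QC-out cross-validation; every
intensity in the batch is then rescaled by (global QC reference level /
curve value at its order), where the reference is the feature's median
QC intensity across all batches.

LOESS here is a linear smoother in the fitted x-positions only, so one
set of local weights serves every feature at once — the whole table is
corrected with a handful of matrix products.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FeatureTable

DEFAULT_SPAN_GRID = (0.3, 0.45, 0.6, 0.75, 0.9, 1.0)


# ---------------------------------------------------------------------------
# local-linear tricube smoother
# ---------------------------------------------------------------------------
def loess_smooth(
    x_train: np.ndarray, y_train: np.ndarray, x_eval: np.ndarray, span: float
) -> np.ndarray:
    """Degree-1 LOESS with tricube weights, vectorised over columns.

    ``y_train`` may be 1-D (one series) or 2-D ``(n_train, n_series)``;
    the window holds the ``ceil(span * n_train)`` nearest neighbours
    (at least 2). Evaluation points outside the training range are
    linearly extrapolated from the nearest window. Returns fitted
    values with shape ``(n_eval,)`` or ``(n_eval, n_series)``.
    """
    if not (0.0 < span <= 1.0):
        raise ValueError("span must lie in (0, 1]")
    x_train = np.asarray(x_train, dtype=float)
    x_eval = np.atleast_1d(np.asarray(x_eval, dtype=float))
    y = np.asarray(y_train, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    n = len(x_train)
    if n < 2:
        raise ValueError("need at least 2 training points")
    k = int(min(n, max(2, np.ceil(span * n))))
    out = np.empty((len(x_eval), y.shape[1]))
    for i, x0 in enumerate(x_eval):
        d = np.abs(x_train - x0)
        dmax = np.partition(d, k - 1)[k - 1]
        if dmax == 0:
            w = (d == 0).astype(float)
        else:
            u = np.clip(d / dmax, 0.0, 1.0)
            w = (1.0 - u**3) ** 3
            if w.sum() <= 0:
                # window edge ties (all neighbours at dmax): uniform weights
                w = (d <= dmax).astype(float)
        xc = x_train - x0
        sw = w.sum()
        swx = w @ xc
        swxx = w @ (xc * xc)
        swy = w @ y
        swxy = (w * xc) @ y
        denom = sw * swxx - swx * swx
        scale = max(sw * swxx, swx * swx)
        if denom <= 1e-12 * scale or scale == 0.0:
            out[i] = swy / sw  # weighted-mean fallback (degenerate window)
        else:
            beta = (sw * swxy - swx * swy) / denom
            out[i] = (swy - beta * swx) / sw  # local line at xc = 0
    return out[:, 0] if squeeze else out


def loo_span_errors(
    x: np.ndarray, y: np.ndarray, span_grid
) -> np.ndarray:
    """Leave-one-out squared prediction error summed over points.

    Returns an array ``(n_spans, n_series)`` of mean squared LOO
    prediction errors for each candidate span.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n = len(x)
    mse = np.zeros((len(span_grid), y.shape[1]))
    for s, span in enumerate(span_grid):
        err = np.zeros(y.shape[1])
        for j in range(n):
            keep = np.arange(n) != j
            pred = loess_smooth(x[keep], y[keep], np.array([x[j]]), span)[0]
            err += (y[j] - pred) ** 2
        mse[s] = err / n
    return mse


def choose_spans(mse: np.ndarray, span_grid) -> np.ndarray:
    """Per-series span minimising LOO MSE, ties broken to the larger span."""
    grid = np.asarray(span_grid, dtype=float)
    order = np.argsort(grid)
    mse_sorted = mse[order]
    # scan from the largest span down so argmin keeps the smoothest tie
    rev = mse_sorted[::-1]
    idx_rev = np.argmin(rev, axis=0)
    return grid[order][len(grid) - 1 - idx_rev]


# ---------------------------------------------------------------------------
# drift correction
# ---------------------------------------------------------------------------
@dataclass
class DriftModel:
    """Fitted QC drift curves for one feature table.

    ``spans`` (features x batches) holds the chosen span per feature and
    batch; ``fit_ok`` flags feature/batch combinations with enough valid
    QCs (>= 4); ``reference`` is the per-feature global median QC
    intensity used as the correction target; ``qc_orders``/``qc_values``
    keep the anchor points so the curve can be evaluated anywhere.
    """

    spans: pd.DataFrame
    fit_ok: pd.DataFrame
    reference: pd.Series
    qc_orders: dict = field(default_factory=dict)
    qc_values: dict = field(default_factory=dict)

    def curve(self, batch: int, feature_ids, orders: np.ndarray) -> pd.DataFrame:
        """Evaluate fitted drift curves for ``feature_ids`` at ``orders``."""
        return _eval_curves(self, batch, pd.Index(feature_ids), np.asarray(orders, float))


class DriftCorrector:
    """QC-anchored LOESS drift and batch-offset correction.

    Parameters
    ----------
    span_init : float
        Initial smoothing span; must be a member of ``span_grid``.
    span_grid : sequence of float
        Candidate spans searched by leave-one-QC-out cross-validation
        (ties resolved toward the larger span).
    min_qc : int
        Minimum valid QC injections per batch for a fit.

    After ``fit``, ``model_`` holds the :class:`DriftModel`; after
    ``transform``, ``audit_`` holds per-feature QC RSD before/after and
    any uncorrectable flags.
    """

    def __init__(self, span_init: float = 0.75, span_grid=DEFAULT_SPAN_GRID, min_qc: int = 4):
        self.span_init = span_init
        self.span_grid = tuple(span_grid)
        self.min_qc = min_qc

    def get_params(self, deep: bool = True) -> dict:
        return {
            "span_init": self.span_init,
            "span_grid": self.span_grid,
            "min_qc": self.min_qc,
        }

    def set_params(self, **params) -> "DriftCorrector":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, table: FeatureTable) -> "DriftCorrector":
        if len(self.span_grid) == 0:
            raise ValueError("span_grid must not be empty")
        if self.span_init not in self.span_grid:
            raise ValueError("span_grid must contain span_init")
        meta = table.sample_meta
        qc_mask = (meta["role"] == "qc").to_numpy()
        feats = table.feature_ids
        batches = sorted(meta["batch"].unique())
        spans = pd.DataFrame(self.span_init, index=feats, columns=batches, dtype=float)
        fit_ok = pd.DataFrame(False, index=feats, columns=batches)
        qc_orders: dict = {}
        qc_values: dict = {}
        for b in batches:
            bm = qc_mask & (meta["batch"] == b).to_numpy()
            qc = table.intensities.loc[bm]
            x = qc.index.to_numpy(dtype=float)
            qc_orders[b] = x
            qc_values[b] = qc
            if len(x) < self.min_qc:
                continue
            Y = qc.to_numpy(dtype=float)
            complete = ~np.isnan(Y).any(axis=0)
            if complete.any():
                mse = loo_span_errors(x, Y[:, complete], self.span_grid)
                chosen = choose_spans(mse, self.span_grid)
                spans.loc[feats[complete], b] = chosen
                fit_ok.loc[feats[complete], b] = True
            # features with missing QC values: fit on the valid subset only
            for j in np.where(~complete)[0]:
                valid = ~np.isnan(Y[:, j])
                if valid.sum() < self.min_qc:
                    continue
                mse = loo_span_errors(x[valid], Y[valid, j], self.span_grid)
                spans.iloc[j, spans.columns.get_loc(b)] = choose_spans(
                    mse, self.span_grid
                )[0]
                fit_ok.iloc[j, fit_ok.columns.get_loc(b)] = True
        qc_all = table.rows("qc")
        reference = qc_all.median(axis=0, skipna=True)
        self.model_ = DriftModel(
            spans=spans, fit_ok=fit_ok, reference=reference,
            qc_orders=qc_orders, qc_values=qc_values,
        )
        return self

    def transform(self, table: FeatureTable) -> FeatureTable:
        model = self.model_
        feats = table.feature_ids
        if not feats.equals(model.spans.index):
            raise ValueError("drift model was fitted on a different feature set")
        corrected = table.intensities.copy()
        meta = table.sample_meta
        flagged: dict = {}
        rsd_before = _qc_rsd(table)
        for b in model.spans.columns:
            bm = (meta["batch"] == b).to_numpy()
            orders = table.intensities.index[bm].to_numpy(dtype=float)
            ok = model.fit_ok[b]
            ok_feats = ok.index[ok]
            if len(ok_feats) == 0:
                flagged[b] = list(feats)
                continue
            curves = _eval_curves(model, b, ok_feats, orders)
            ref = model.reference[ok_feats]
            bad = (curves <= 0).any(axis=0) | (ref <= 0)
            usable = ok_feats[~bad.to_numpy()]
            factor = ref[usable] / curves.loc[:, usable]
            block = corrected.loc[bm, usable]
            corrected.loc[bm, usable] = block.to_numpy() * factor.to_numpy()
            flagged[b] = sorted(set(feats) - set(usable))
        out = FeatureTable(corrected, table.feature_meta.copy(), table.sample_meta.copy())
        rsd_after = _qc_rsd(out)
        self.audit_ = pd.DataFrame(
            {"qc_rsd_before": rsd_before, "qc_rsd_after": rsd_after}
        )
        self.uncorrected_ = flagged
        return out

    def fit_transform(self, table: FeatureTable) -> FeatureTable:
        return self.fit(table).transform(table)


def _eval_curves(model: DriftModel, batch, feature_ids, orders) -> pd.DataFrame:
    x = model.qc_orders[batch]
    Y = model.qc_values[batch].loc[:, feature_ids].to_numpy(dtype=float)
    out = np.empty((len(orders), len(feature_ids)))
    spans = model.spans.loc[feature_ids, batch].to_numpy()
    for span in np.unique(spans):
        cols = spans == span
        Yc = Y[:, cols]
        nan_cols = np.isnan(Yc).any(axis=0)
        fitted = np.empty((len(orders), Yc.shape[1]))
        if (~nan_cols).any():
            fitted[:, ~nan_cols] = loess_smooth(x, Yc[:, ~nan_cols], orders, span)
        for j in np.where(nan_cols)[0]:
            valid = ~np.isnan(Yc[:, j])
            fitted[:, j] = loess_smooth(x[valid], Yc[valid, j], orders, span)
        out[:, cols] = fitted
    return pd.DataFrame(out, index=orders, columns=feature_ids)


def _qc_rsd(table: FeatureTable) -> pd.Series:
    qc = table.rows("qc")
    mean = qc.mean(axis=0, skipna=True)
    sd = qc.std(axis=0, ddof=1, skipna=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        return 100.0 * sd / mean


def correct_drift(
    table: FeatureTable,
    span_init: float = 0.75,
    span_grid=DEFAULT_SPAN_GRID,
) -> tuple[FeatureTable, DriftCorrector]:
    """Convenience wrapper: fit and apply the QC-anchored drift model."""
    corr = DriftCorrector(span_init=span_init, span_grid=span_grid)
    out = corr.fit_transform(table)
    return out, corr


# ---------------------------------------------------------------------------
# probabilistic quotient normalization
# ---------------------------------------------------------------------------
class PQNNormalizer:
    """Probabilistic quotient normalization against a reference spectrum.

    ``fit(X)`` sets the reference to the per-feature median of the rows
    passed (typically the corrected QC injections) unless an explicit
    ``reference`` array was given at construction. ``transform(X)``
    divides each row by the median of its per-feature quotients against
    the reference, computed over features positive and present in both.
    Rows sharing no positive feature with the reference are left
    unchanged and flagged in ``unnormalized_``.
    """

    def __init__(self, reference=None):
        self.reference = reference

    def get_params(self, deep: bool = True) -> dict:
        return {"reference": self.reference}

    def set_params(self, **params) -> "PQNNormalizer":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "PQNNormalizer":
        if self.reference is not None:
            self.reference_ = np.asarray(self.reference, dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.reference_ = np.nanmedian(X, axis=0)
        return self

    def quotients(self, X) -> np.ndarray:
        """Per-row median quotient against the reference (NaN if undefined)."""
        X = np.asarray(X, dtype=float)
        ref = self.reference_
        valid = np.isfinite(X) & (X > 0) & np.isfinite(ref)[None, :] & (ref > 0)[None, :]
        q = np.full(len(X), np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = X / ref[None, :]
        for i in range(len(X)):
            r = ratios[i, valid[i]]
            if r.size:
                q[i] = np.median(r)
        return q

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        q = self.quotients(X)
        self.quotients_ = q
        self.unnormalized_ = np.where(~np.isfinite(q))[0]
        factor = np.where(np.isfinite(q), q, 1.0)
        return X / factor[:, None]

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)


def pqn_normalize(
    table: FeatureTable,
    reference: np.ndarray | None = None,
    normalize_roles: tuple[str, ...] = ("study", "qc", "dqc", "conditioning"),
) -> tuple[FeatureTable, pd.Series]:
    """Apply PQN to a feature table; blanks are left untouched by default.

    The reference defaults to the per-feature median over QC injections.
    Returns the normalized table and the per-injection quotient series.
    """
    norm = PQNNormalizer(reference=reference)
    if reference is None:
        norm.fit(table.rows("qc").to_numpy(dtype=float))
    else:
        norm.fit(None)
    mask = table.role_mask(*normalize_roles).to_numpy()
    out = table.intensities.copy()
    normed = norm.transform(table.intensities.loc[mask].to_numpy(dtype=float))
    out.loc[mask, :] = normed
    quot = pd.Series(np.nan, index=table.intensities.index, name="pqn_quotient")
    quot.loc[mask] = norm.quotients_
    return FeatureTable(out, table.feature_meta.copy(), table.sample_meta.copy()), quot


# ---------------------------------------------------------------------------
# unit-variance scaling
# ---------------------------------------------------------------------------
class UVScaler:
    """Mean-center and scale each column to unit sample variance (ddof=1).

    Raises on zero-variance columns, naming them, since they carry no
    information and would divide by zero.
    """

    def fit(self, X, y=None) -> "UVScaler":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        zero = np.where(self.scale_ == 0)[0]
        if zero.size:
            raise ValueError(f"zero-variance columns cannot be UV-scaled: {zero.tolist()}")
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) / self.scale_

    def inverse_transform(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) * self.scale_ + self.mean_

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "UVScaler":
        return self


def uv_scale(X) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """UV-scale a matrix; returns (scaled, column means, column sds)."""
    scaler = UVScaler().fit(X)
    return scaler.transform(X), scaler.mean_, scaler.scale_
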