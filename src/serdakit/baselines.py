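"""Comparator QC-based normalizers: SERRF-style random forest and
batchwise LOESS.

SERRF is compound-by-compound: for each compound it regresses the QC
intensities on the most-correlated other compounds with a random forest and
divides every sample by the predicted drift. LOESS is time-only: per
compound and batch it smooths the QC trace against injection order and
divides by the fitted curve. Both use the conventional multiplicative
correction ``corrected = raw * median(QC) / fitted``.

Defaults (``top_k=10``, ``trees=500``, ``span=0.75``) are reasonable
baseline choices, not claims of bit-compatibility with any published
implementation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core import NormalizationResult
from .datamodel import FeatureTable, RoleSelection, select_samples
from .sumnorm import NormalizationError

logger = logging.getLogger("serdakit")

_PRED_FLOOR_REL = 1e-6  # fitted-drift floor, relative to the QC median


@dataclass(frozen=True)
class SerrfSpec:
    top_k: int = 10
    trees: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise NormalizationError("top_k must be >= 1")
        if self.trees < 1:
            raise NormalizationError("trees must be >= 1")


@dataclass(frozen=True)
class LoessSpec:
    span: float = 0.75
    degree: int = 1
    per_batch: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.span <= 1.0:
            raise NormalizationError("span must lie in (0, 1]")
        if self.degree != 1:
            raise NormalizationError("only locally linear (degree 1) is supported")


def serrf_normalize(
    table: FeatureTable,
    selection: RoleSelection | None = None,
    spec: SerrfSpec | None = None,
) -> NormalizationResult:
    """Compound-by-compound random-forest drift correction.

    Per compound j: pick the ``top_k`` compounds most |correlated| with j
    over the training QCs (log2 scale), fit a random forest of j's QC
    values on them, predict a drift level for every target sample, and
    rescale ``raw * median(QC_j) / max(pred, floor)``.
    """
    selection = selection or RoleSelection()
    spec = spec or SerrfSpec()
    train_tbl, target_tbl = select_samples(table, selection)
    if train_tbl.n_samples < 5:
        raise NormalizationError(
            f"SERRF needs >= 5 training QCs, got {train_tbl.n_samples}"
        )
    d = table.n_compounds
    if spec.top_k >= d:
        raise NormalizationError(f"top_k must be < {d} compounds")

    log_train = np.log2(np.maximum(train_tbl.intensities, 1e-12))
    log_target = np.log2(np.maximum(target_tbl.intensities, 1e-12))
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(log_train, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 0.0)

    corrected = target_tbl.intensities.copy()
    predictors: dict[str, list[str]] = {}
    qc_sd = log_train.std(axis=0, ddof=1)
    for j in range(d):
        cid = table.compound_ids[j]
        if qc_sd[j] < 1e-12:
            logger.warning("compound %r constant on QCs; passed through", cid)
            continue
        top = np.argsort(-np.abs(corr[:, j]))[: spec.top_k]
        predictors[cid] = [table.compound_ids[t] for t in top]
        rf = RandomForestRegressor(
            n_estimators=spec.trees,
            random_state=spec.seed + j,
            n_jobs=1,
        )
        rf.fit(log_train[:, top], log_train[:, j])
        pred_log = rf.predict(log_target[:, top])
        if not np.isfinite(pred_log).all():
            raise NormalizationError(f"non-finite SERRF prediction for {cid!r}")
        pred = np.exp2(pred_log)
        qc_median = float(np.median(train_tbl.intensities[:, j]))
        floor = _PRED_FLOOR_REL * max(qc_median, 1e-12)
        corrected[:, j] = (
            target_tbl.intensities[:, j] * qc_median / np.maximum(pred, floor)
        )

    return NormalizationResult(
        normalized=target_tbl.with_intensities(corrected),
        provenance={
            "method": "serrf",
            "top_k": spec.top_k,
            "trees": spec.trees,
            "seed": spec.seed,
            "predictors": predictors,
        },
    )


def _loess_fit_batch(
    qc_order: np.ndarray,
    qc_values: np.ndarray,
    eval_order: np.ndarray,
    span: float,
) -> np.ndarray:
    if int(np.ceil(span * len(qc_order))) < 3:
        raise NormalizationError(
            f"span {span} covers fewer than 3 of {len(qc_order)} QCs; "
            "use a larger span"
        )
    # it=0: plain local linear fit, deterministic. The smooth is evaluated
    # at the QC points and carried to the other injections by linear
    # interpolation, with linear extrapolation at the batch edges.
    fit = lowess(qc_values, qc_order.astype(float), frac=span, it=0)
    xf, yf = fit[:, 0], fit[:, 1]
    ev = eval_order.astype(float)
    out = np.interp(ev, xf, yf)
    if len(xf) >= 2:
        left = ev < xf[0]
        if left.any():
            s = (yf[1] - yf[0]) / (xf[1] - xf[0])
            out[left] = yf[0] + s * (ev[left] - xf[0])
        right = ev > xf[-1]
        if right.any():
            s = (yf[-1] - yf[-2]) / (xf[-1] - xf[-2])
            out[right] = yf[-1] + s * (ev[right] - xf[-1])
    return out


def loess_normalize(
    table: FeatureTable,
    selection: RoleSelection | None = None,
    spec: LoessSpec | None = None,
) -> NormalizationResult:
    """Batchwise LOESS of QC intensity vs injection order, ratio correction.

    Batches with fewer than 4 QCs fall back to a flat median correction
    (logged). The fitted curve is floored at a small positive value before
    dividing.
    """
    selection = selection or RoleSelection()
    spec = spec or LoessSpec()
    train_tbl, target_tbl = select_samples(table, selection)
    if train_tbl.n_samples < 4:
        raise NormalizationError(
            f"LOESS needs >= 4 training QCs, got {train_tbl.n_samples}"
        )

    qc_order = train_tbl.samples["injection_order"].to_numpy()
    qc_batch = train_tbl.samples["batch"].to_numpy()
    t_order = target_tbl.samples["injection_order"].to_numpy()
    t_batch = target_tbl.samples["batch"].to_numpy()

    corrected = target_tbl.intensities.copy()
    for j in range(table.n_compounds):
        qc_all = train_tbl.intensities[:, j]
        qc_median = float(np.median(qc_all))
        floor = _PRED_FLOOR_REL * max(abs(qc_median), 1e-12)
        fitted = np.empty(target_tbl.n_samples)
        for b in np.unique(t_batch) if spec.per_batch else ["__all__"]:
            t_rows = (
                np.full(len(t_batch), True) if b == "__all__" else t_batch == b
            )
            q_rows = (
                np.full(len(qc_batch), True) if b == "__all__" else qc_batch == b
            )
            if q_rows.sum() < 4:
                logger.warning(
                    "batch %r has %d QCs; flat median fallback", b, q_rows.sum()
                )
                fitted[t_rows] = (
                    np.median(qc_all[q_rows]) if q_rows.any() else qc_median
                )
                continue
            fitted[t_rows] = _loess_fit_batch(
                qc_order[q_rows], qc_all[q_rows], t_order[t_rows], spec.span
            )
        corrected[:, j] = (
            target_tbl.intensities[:, j] * qc_median / np.maximum(fitted, floor)
        )

    return NormalizationResult(
        normalized=target_tbl.with_intensities(corrected),
        provenance={
            "method": "loess",
            "span": spec.span,
            "per_batch": spec.per_batch,
        },
    )
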