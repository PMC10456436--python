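"""Scaling normalizations: mTIC / fTIC / iTIC sums, ISTD ratios, batch medians.

These are the classic per-sample scaling schemes used in GC-MS profiling:

* ``mTIC`` — divide by the sample's summed intensity over all identified
  metabolites (excluding spiked standards), the usual "total useful signal".
* ``fTIC`` — divide by the sum over the FAME retention-index markers.
* ``iTIC`` — divide by the sum over the labeled internal standards.
* one-to-one ISTD — each endogenous compound divided by its own deuterated
  internal standard.
* one-to-class ISTD — one surrogate standard divides a whole compound class.
* batch-median equalization on an additive (glog) scale.

By default the divided values are rescaled by the median of the divisors so
outputs stay on an intensity-like scale; RSD is scale-invariant, so the
rescale never affects evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import FeatureTable, FeatureTableError


class NormalizationError(ValueError):
    """Raised when a normalization's preconditions fail."""


@dataclass(frozen=True)
class SumSpec:
    mode: str  # mTIC | fTIC | iTIC
    rescale: str = "median-of-sums"  # or "none"

    def __post_init__(self) -> None:
        if self.mode not in {"mTIC", "fTIC", "iTIC"}:
            raise NormalizationError(f"unknown sum mode {self.mode!r}")
        if self.rescale not in {"median-of-sums", "none"}:
            raise NormalizationError(f"unknown rescale {self.rescale!r}")


def _mode_mask(table: FeatureTable, mode: str) -> np.ndarray:
    c = table.compounds
    if mode == "iTIC":
        mask = c["is_istd"].to_numpy()
    elif mode == "fTIC":
        mask = c["is_fame"].to_numpy()
    else:  # mTIC: identified endogenous metabolites, not spiked standards
        mask = (
            c["is_identified"] & ~c["is_istd"] & ~c["is_fame"]
        ).to_numpy()
    if not mask.any():
        raise NormalizationError(
            f"no compounds available for {mode} (empty compound set)"
        )
    return mask


def sum_normalize(table: FeatureTable, spec: SumSpec) -> FeatureTable:
    """Divide each sample by its summed intensity over the mode's compound set."""
    mask = _mode_mask(table, spec.mode)
    sums = table.intensities[:, mask].sum(axis=1)
    zero = sums <= 0
    if zero.any():
        bad = [table.sample_ids[i] for i in np.where(zero)[0]]
        raise NormalizationError(f"zero {spec.mode} sum for samples {bad}")
    out = table.intensities / sums[:, None]
    if spec.rescale == "median-of-sums":
        out = out * np.median(sums)
    return table.with_intensities(out)


def istd_one_to_one(table: FeatureTable, rescale: bool = True) -> FeatureTable:
    """Divide each mapped endogenous compound by its internal standard.

    Unmapped compounds pass through unchanged; the returned table is
    otherwise identical. Callers needing provenance can diff against
    ``table.istd_map``.
    """
    if not table.istd_map:
        raise NormalizationError("istd_map is empty")
    out = table.intensities.copy()
    cidx = {c: j for j, c in enumerate(table.compound_ids)}
    for endog, istd in table.istd_map.items():
        j, k = cidx[endog], cidx[istd]
        denom = table.intensities[:, k]
        zero = denom <= 0
        if zero.any():
            sid = table.sample_ids[int(np.where(zero)[0][0])]
            raise NormalizationError(
                f"nonpositive ISTD {istd!r} intensity in sample {sid!r}"
            )
        out[:, j] = table.intensities[:, j] / denom
        if rescale:
            out[:, j] *= np.median(denom)
    return table.with_intensities(out)


def istd_one_to_class(
    table: FeatureTable, class_name: str, surrogate: str, rescale: bool = True
) -> FeatureTable:
    """Divide every compound of ``class_name`` by one surrogate standard."""
    if surrogate not in table.compound_ids:
        raise NormalizationError(f"surrogate {surrogate!r} absent")
    if not table.compounds.at[surrogate, "is_istd"]:
        raise NormalizationError(f"surrogate {surrogate!r} is not an ISTD")
    classes = table.compounds.get("compound_class")
    members = (classes == class_name).to_numpy()
    if not members.any():
        raise NormalizationError(f"compound class {class_name!r} is empty")
    k = table.compound_ids.index(surrogate)
    denom = table.intensities[:, k]
    if (denom <= 0).any():
        raise NormalizationError(f"surrogate {surrogate!r} has nonpositive values")
    out = table.intensities.copy()
    out[:, members] = table.intensities[:, members] / denom[:, None]
    if rescale:
        out[:, members] *= np.median(denom)
    return table.with_intensities(out)


def median_normalize(matrix: np.ndarray, batch: np.ndarray) -> np.ndarray:
    """Equalize per-compound batch medians on an additive (glog) scale.

    For each compound and batch, subtract the batch median and add the
    compound's global median, so inter-batch level jumps are removed while
    the global median is preserved.
    """
    matrix = np.asarray(matrix, dtype=float)
    batch = np.asarray(batch)
    if matrix.shape[0] != batch.shape[0]:
        raise NormalizationError("batch label per row required")
    if any(b == "" or b is None for b in batch.tolist()):
        raise FeatureTableError("empty batch label")
    out = matrix.copy()
    global_med = np.median(matrix, axis=0)
    for b in np.unique(batch):
        rows = batch == b
        out[rows] += global_med - np.median(matrix[rows], axis=0)
    return out
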