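"""Precision metrics for QC-based normalization.

The central metric is the per-compound relative standard deviation over a
group of identical QC injections, ``RSD = 100 * sd / mean`` (percent, n-1
denominator). A normalization is judged by how far it pushes the QC RSD
distribution down without training on the samples it is scored on, hence:

* ``cross_validated_rsd`` — k-fold CV over the training QCs: each fold is
  held out, the normalizer trains on the rest and corrects the held-out
  injections; held-out values are pooled and scored.
* ``external_validation_rsd`` — score an independent QC material (e.g., a
  commercial plasma pool) that never enters training.
* coverage at a threshold (30% is the community convention), cumulative RSD
  curves, blinded-replicate correlations, and a paired Wilcoxon signed-rank
  comparison between methods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import injection_order_folds
from .datamodel import FeatureTable, RoleSelection
from .sumnorm import NormalizationError

logger = logging.getLogger("serdakit")


# ----------------------------------------------------------------------
# RSD primitives
# ----------------------------------------------------------------------
def compound_rsd(values) -> float:
    """Percent RSD of one compound's intensities: 100*sd/mean, sd with n-1."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise NormalizationError("RSD needs >= 2 values")
    if not np.isfinite(v).all():
        raise NormalizationError("RSD input must be finite")
    mean = v.mean()
    if mean == 0:
        return np.nan
    return float(100.0 * v.std(ddof=1) / mean)


def compound_rsd_matrix(matrix: np.ndarray) -> np.ndarray:
    """Columnwise percent RSD; zero-mean compounds yield NaN (excluded later)."""
    m = np.asarray(matrix, dtype=float)
    if m.shape[0] < 2:
        raise NormalizationError("RSD needs >= 2 samples")
    mean = m.mean(axis=0)
    sd = m.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = np.where(mean != 0, 100.0 * sd / mean, np.nan)
    return rsd


@dataclass
class RSDReport:
    """Per-compound percent RSDs for one sample group, with summaries."""

    per_compound_rsd: pd.Series
    group: str
    n_samples: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.per_compound_rsd) == 0:
            raise NormalizationError("empty RSD report")
        n_undefined = int(self.per_compound_rsd.isna().sum())
        if n_undefined:
            logger.info(
                "%d compounds with undefined RSD excluded from summaries",
                n_undefined,
            )
            self.provenance["n_undefined_rsd"] = n_undefined

    @property
    def median(self) -> float:
        return float(self.per_compound_rsd.median())

    @property
    def mean(self) -> float:
        return float(self.per_compound_rsd.mean())

    def coverage(self, threshold: float = 30.0) -> float:
        """Fraction of compounds with RSD strictly below ``threshold``."""
        vals = self.per_compound_rsd.dropna()
        if len(vals) == 0:
            raise NormalizationError("no defined RSD values")
        return float((vals < threshold).mean())

    def summary(self, thresholds=(30.0,)) -> dict:
        return {
            "group": self.group,
            "n_samples": self.n_samples,
            "n_compounds": int(self.per_compound_rsd.notna().sum()),
            "median_rsd": self.median,
            "mean_rsd": self.mean,
            **{f"coverage_{t:g}": self.coverage(t) for t in thresholds},
        }


def rsd_report(table: FeatureTable, group: str = "pool_qc") -> RSDReport:
    """Per-compound RSD over all samples of one role."""
    mask = table.role_mask(group)
    if mask.sum() == 0:
        raise NormalizationError(f"no samples with role {group!r}")
    if mask.sum() < 2:
        raise NormalizationError(f"role {group!r} has a single sample")
    rsd = compound_rsd_matrix(table.intensities[mask])
    return RSDReport(
        per_compound_rsd=pd.Series(rsd, index=table.compound_ids),
        group=group,
        n_samples=int(mask.sum()),
    )


def coverage_at_threshold(report: RSDReport, threshold: float = 30.0) -> float:
    return report.coverage(threshold)


# ----------------------------------------------------------------------
# validation protocols
# ----------------------------------------------------------------------
def identity_normalizer(table: FeatureTable, selection: RoleSelection) -> FeatureTable:
    """Raw data pass-through (the 'raw' method in comparisons)."""
    from .datamodel import select_samples

    _, target = select_samples(table, selection)
    return target


identity_normalizer.requires_training = False  # type: ignore[attr-defined]


def cross_validated_rsd(
    table: FeatureTable,
    selection: RoleSelection | None = None,
    method=identity_normalizer,
    k: int = 5,
) -> RSDReport:
    """k-fold CV RSD of the training QCs under ``method``.

    ``method`` is a callable ``(table, RoleSelection) -> FeatureTable``
    returning the corrected target table. Folds interleave over injection
    order so each spans the whole run. Methods flagged
    ``requires_training = False`` (sum norms, raw) are applied once; CV is
    vacuous for them.
    """
    selection = selection or RoleSelection()
    table = table.sorted_by_injection()
    train_mask, _ = selection.masks(table)
    qc_ids = np.asarray(table.sample_ids)[train_mask]
    qc_order = table.samples["injection_order"].to_numpy()[train_mask]
    group = "+".join(sorted(selection.training_roles))

    if not getattr(method, "requires_training", True):
        logger.info("method needs no training; cross-validation is vacuous")
        sel = RoleSelection(
            training_roles=selection.training_roles, target_ids=tuple(qc_ids)
        )
        pooled = method(table, sel).intensities
    else:
        folds = injection_order_folds(qc_order, k)
        held = []
        for f in range(k):
            train_ids = qc_ids[folds != f]
            if len(train_ids) < 2:
                raise NormalizationError(
                    f"fold {f} leaves {len(train_ids)} training QCs; reduce k"
                )
            sel = RoleSelection(
                training_roles=selection.training_roles,
                training_ids=tuple(train_ids),
                target_ids=tuple(qc_ids[folds == f]),
            )
            held.append(method(table, sel).intensities)
        pooled = np.vstack(held)

    rsd = compound_rsd_matrix(pooled)
    return RSDReport(
        per_compound_rsd=pd.Series(rsd, index=table.compound_ids),
        group=group,
        n_samples=pooled.shape[0],
        provenance={"protocol": "cross_validation", "k": k},
    )


def external_validation_rsd(
    table: FeatureTable,
    selection: RoleSelection | None = None,
    method=identity_normalizer,
    validation_role: str = "validation_qc",
) -> RSDReport:
    """Train on the training QCs, score an independent QC role."""
    selection = selection or RoleSelection()
    if validation_role in selection.training_roles:
        raise NormalizationError(
            f"validation role {validation_role!r} overlaps the training roles"
        )
    if not table.role_mask(validation_role).any():
        raise NormalizationError(f"no samples with role {validation_role!r}")
    if selection.training_ids is not None:
        val_ids = set(table.samples.index[table.role_mask(validation_role)])
        if val_ids & set(selection.training_ids):
            raise NormalizationError(
                f"validation role {validation_role!r} overlaps the training ids"
            )
    sel = RoleSelection(
        training_roles=selection.training_roles,
        target_roles=frozenset(selection.target_roles | {validation_role}),
        training_ids=selection.training_ids,
    )
    normalized = method(table, sel)
    return rsd_report(normalized, group=validation_role)


# ----------------------------------------------------------------------
# curves, replicates, paired comparison
# ----------------------------------------------------------------------
def cumulative_rsd_curve(reports: dict) -> pd.DataFrame:
    """Long-format (method, rsd, coverage) empirical CDF table, one curve
    per report; all reports must share the compound axis."""
    if not reports:
        raise NormalizationError("no reports given")
    axes = [tuple(r.per_compound_rsd.index) for r in reports.values()]
    if len(set(axes)) != 1:
        raise NormalizationError("reports have mismatched compound sets")
    rows = []
    for name, rep in reports.items():
        vals = np.sort(rep.per_compound_rsd.dropna().to_numpy())
        cov = np.arange(1, len(vals) + 1) / len(vals)
        for v, c in zip(vals, cov):
            rows.append({"method": name, "rsd": v, "coverage": c})
    return pd.DataFrame(rows)


def replicate_correlation(table: FeatureTable) -> pd.DataFrame:
    """Pearson r (log2 scale, across compounds) for each blinded duplicate
    pair; pairs at injection distance 1 are 'adjacent', else 'nonadjacent'."""
    groups = table.samples["replicate_group"]
    rows = []
    for g in groups.dropna().unique():
        idx = np.where((groups == g).to_numpy())[0]
        if len(idx) != 2:
            logger.warning("replicate group %r has %d members; skipped", g, len(idx))
            continue
        i, j = idx
        a = np.log2(np.maximum(table.intensities[i], 1e-12))
        b = np.log2(np.maximum(table.intensities[j], 1e-12))
        dist = abs(
            int(table.samples["injection_order"].iloc[i])
            - int(table.samples["injection_order"].iloc[j])
        )
        r = float(np.corrcoef(a, b)[0, 1])
        rows.append(
            {
                "replicate_group": g,
                "r": r,
                "distance": dist,
                "class": "adjacent" if dist == 1 else "nonadjacent",
            }
        )
    if not rows:
        raise NormalizationError("no 2-member replicate groups found")
    return pd.DataFrame(rows)


def compare_methods_paired(reportA: RSDReport, reportB: RSDReport) -> dict:
    """Two-sided Wilcoxon signed-rank test on paired per-compound RSDs.

    Exact null distribution for <= 25 informative pairs, normal
    approximation above; all-zero differences degenerate to p = 1.
    """
    if tuple(reportA.per_compound_rsd.index) != tuple(reportB.per_compound_rsd.index):
        raise NormalizationError("reports have mismatched compound axes")
    a = reportA.per_compound_rsd
    b = reportB.per_compound_rsd
    ok = a.notna() & b.notna()
    diffs = (a[ok] - b[ok]).to_numpy()
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return {"statistic": 0.0, "p_value": 1.0, "n_pairs": int(ok.sum())}
    mode = "exact" if nonzero.size <= 25 else "approx"
    res = stats.wilcoxon(nonzero, alternative="two-sided", method=mode)
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "n_pairs": int(nonzero.size),
    }
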