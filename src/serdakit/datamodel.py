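"""Annotated feature-table data model and delimited-text IO.

A :class:`FeatureTable` bundles a samples x compounds intensity matrix with
the sample metadata (injection order, batch, QC role, replicate pairing) and
compound metadata (identified / internal-standard / FAME flags, compound
class, endogenous-to-ISTD mapping) that QC-based normalization needs.

Canonical on-disk dialect (delimiter configurable, comma default)::

    sample_id,injection_order,batch,role,replicate_group,Cmpd1,Cmpd2,...
    #class,,,,,amino acid,sugar,...
    #identified,,,,,1,1,...
    #istd,,,,,0,1,...
    #fame,,,,,0,0,...
    #istd_map,,,,,Cmpd2,,...
    S001,1,B1,pool_qc,,152340,98211,...

Rows whose first cell starts with ``#`` carry per-compound metadata; all
other rows are samples. Injection order is always taken from metadata, never
from file row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_ROLES = frozenset(
    {"study", "pool_qc", "validation_qc", "tertiary_qc", "blank", "replicate"}
)

#: compound-metadata marker rows of the canonical dialect, in write order
_META_ROWS = ("#class", "#identified", "#istd", "#fame", "#istd_map")
_SAMPLE_COLS = ("sample_id", "injection_order", "batch", "role", "replicate_group")


class FeatureTableError(ValueError):
    """Raised for structurally invalid feature tables or files."""


@dataclass
class FeatureTable:
    """Samples x compounds intensity matrix with acquisition metadata.

    Parameters
    ----------
    intensities
        Nonnegative matrix, shape (n_samples, n_compounds), arbitrary
        ion-count units.
    samples
        DataFrame indexed by sample id with columns ``injection_order``
        (unique positive ints), ``batch``, ``role`` (one of
        :data:`VALID_ROLES`) and optional ``replicate_group``.
    compounds
        DataFrame indexed by compound id with boolean columns
        ``is_identified``, ``is_istd``, ``is_fame`` and optional
        ``compound_class``.
    istd_map
        Partial mapping endogenous compound id -> its labeled ISTD id.
    """

    intensities: np.ndarray
    samples: pd.DataFrame
    compounds: pd.DataFrame
    istd_map: dict[str, str] = field(default_factory=dict)
    allow_missing: bool = False

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.validate()

    # ------------------------------------------------------------------
    # validation
    # ------------------------------------------------------------------
    def validate(self) -> None:
        ns, nc = self.intensities.shape if self.intensities.ndim == 2 else (0, 0)
        if self.intensities.ndim != 2 or nc == 0 or ns == 0:
            raise FeatureTableError("intensity matrix must be 2-D and nonempty")
        if len(self.samples) != ns:
            raise FeatureTableError(
                f"{ns} intensity rows but {len(self.samples)} sample metadata rows"
            )
        if len(self.compounds) != nc:
            raise FeatureTableError(
                f"{nc} intensity columns but {len(self.compounds)} compound entries"
            )
        if self.samples.index.duplicated().any():
            dupes = self.samples.index[self.samples.index.duplicated()].tolist()
            raise FeatureTableError(f"duplicate sample ids: {dupes}")
        if self.compounds.index.duplicated().any():
            dupes = self.compounds.index[self.compounds.index.duplicated()].tolist()
            raise FeatureTableError(f"duplicate compound ids: {dupes}")

        order = self.samples["injection_order"]
        if order.isna().any() or (order <= 0).any():
            raise FeatureTableError("injection_order must be positive integers")
        if order.duplicated().any():
            raise FeatureTableError(
                "tied injection_order values: "
                f"{sorted(order[order.duplicated(keep=False)].unique().tolist())}"
            )
        bad_roles = set(self.samples["role"]) - VALID_ROLES
        if bad_roles:
            raise FeatureTableError(f"unknown sample roles: {sorted(bad_roles)}")

        finite = np.isfinite(self.intensities)
        if not finite.all():
            if not self.allow_missing:
                i, j = np.argwhere(~finite)[0]
                raise FeatureTableError(
                    "non-finite intensity at sample "
                    f"{self.samples.index[i]!r}, compound {self.compounds.index[j]!r} "
                    "(missing values need an explicit missing-policy)"
                )
            if np.isinf(self.intensities).any():
                raise FeatureTableError("infinite intensities are never allowed")
        if (self.intensities[finite] < 0).any():
            raise FeatureTableError("intensities must be nonnegative")

        for col in ("is_identified", "is_istd", "is_fame"):
            if col not in self.compounds.columns:
                self.compounds[col] = False
            self.compounds[col] = self.compounds[col].astype(bool)
        for endog, istd in self.istd_map.items():
            if endog not in self.compounds.index:
                raise FeatureTableError(f"istd_map key {endog!r} not a compound")
            if istd not in self.compounds.index:
                raise FeatureTableError(f"istd_map target {istd!r} not a compound")
            if not self.compounds.at[istd, "is_istd"]:
                raise FeatureTableError(
                    f"istd_map target {istd!r} is not flagged is_istd"
                )

    # ------------------------------------------------------------------
    # convenience accessors
    # ------------------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.compounds.index)

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_compounds(self) -> int:
        return self.intensities.shape[1]

    def role_mask(self, roles) -> np.ndarray:
        roles = {roles} if isinstance(roles, str) else set(roles)
        return self.samples["role"].isin(roles).to_numpy()

    def sorted_by_injection(self) -> "FeatureTable":
        """Return a copy with rows sorted by injection order."""
        idx = np.argsort(self.samples["injection_order"].to_numpy(), kind="stable")
        return self.take_samples(idx)

    def take_samples(self, idx) -> "FeatureTable":
        idx = np.asarray(idx)
        return FeatureTable(
            intensities=self.intensities[idx].copy(),
            samples=self.samples.iloc[idx].copy(),
            compounds=self.compounds.copy(),
            istd_map=dict(self.istd_map),
            allow_missing=self.allow_missing,
        )

    def with_intensities(self, intensities: np.ndarray) -> "FeatureTable":
        """Copy of the table with the matrix replaced (shape must match)."""
        if intensities.shape != self.intensities.shape:
            raise FeatureTableError(
                f"replacement shape {intensities.shape} != {self.intensities.shape}"
            )
        return FeatureTable(
            intensities=np.asarray(intensities, dtype=float).copy(),
            samples=self.samples.copy(),
            compounds=self.compounds.copy(),
            istd_map=dict(self.istd_map),
            allow_missing=self.allow_missing,
        )

    def impute_half_minimum(self) -> "FeatureTable":
        """Replace missing cells by half the compound's observed minimum.

        Must be requested explicitly: complete matrices are the expected
        state for curated GC-MS feature tables.
        """
        x = self.intensities.copy()
        for j in range(x.shape[1]):
            col = x[:, j]
            miss = ~np.isfinite(col)
            if miss.any():
                observed = col[~miss]
                if observed.size == 0:
                    raise FeatureTableError(
                        f"compound {self.compounds.index[j]!r} has no observed values"
                    )
                col[miss] = 0.5 * observed.min()
        out = self.with_intensities(x)
        out.allow_missing = False
        return out


@dataclass
class RoleSelection:
    """Which samples train a QC-based normalizer and which are corrected.

    ``training_roles`` defaults to the pooled QCs; ``target_roles`` to every
    non-blank sample (QCs are themselves normalized as targets). Explicit
    ``training_ids`` / ``target_ids`` override the role sets — used by the
    cross-validation machinery to hold out individual QC injections.
    """

    training_roles: frozenset = frozenset({"pool_qc"})
    target_roles: frozenset = frozenset(VALID_ROLES - {"blank"})
    training_ids: tuple | None = None
    target_ids: tuple | None = None

    def __post_init__(self) -> None:
        self.training_roles = frozenset(self.training_roles)
        self.target_roles = frozenset(self.target_roles)
        if not self.training_roles and self.training_ids is None:
            raise FeatureTableError("training selection must be nonempty")

    def masks(self, table: FeatureTable) -> tuple[np.ndarray, np.ndarray]:
        if self.training_ids is not None:
            train = table.samples.index.isin(self.training_ids)
        else:
            missing = self.training_roles - set(table.samples["role"])
            if missing:
                raise FeatureTableError(
                    f"training roles {sorted(missing)} absent from table"
                )
            train = table.role_mask(self.training_roles)
        if self.target_ids is not None:
            target = table.samples.index.isin(self.target_ids)
        else:
            target = table.role_mask(self.target_roles)
        if not train.any():
            raise FeatureTableError("training selection matched no samples")
        if not target.any():
            raise FeatureTableError("target selection matched no samples")
        return np.asarray(train), np.asarray(target)


def select_samples(
    table: FeatureTable, selection: RoleSelection
) -> tuple[FeatureTable, FeatureTable]:
    """Split a table into (training, target) sub-tables.

    Both preserve injection order; the compound axis is shared and never
    reordered. The two selections may overlap.
    """
    table = table.sorted_by_injection()
    train_mask, target_mask = selection.masks(table)
    return table.take_samples(np.where(train_mask)[0]), table.take_samples(
        np.where(target_mask)[0]
    )


# ----------------------------------------------------------------------
# delimited-text IO
# ----------------------------------------------------------------------
def read_feature_table(
    path,
    delimiter: str = ",",
    missing_token: str | None = None,
    missing_policy: str = "reject",
) -> FeatureTable:
    """Read the canonical dialect from ``path``.

    ``missing_policy`` is ``"reject"`` (default: any missing cell is an
    error) or ``"impute-half-minimum"``.
    """
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    if raw.shape[1] < len(_SAMPLE_COLS) + 1:
        raise FeatureTableError(
            f"expected columns {_SAMPLE_COLS} plus at least one compound column"
        )
    for col in _SAMPLE_COLS:
        if col not in raw.columns:
            raise FeatureTableError(f"missing required column {col!r}")
    compound_cols = [c for c in raw.columns if c not in _SAMPLE_COLS]

    meta_mask = raw["sample_id"].str.startswith("#")
    meta = raw[meta_mask].set_index("sample_id")
    body = raw[~meta_mask]
    if body.empty:
        raise FeatureTableError("no sample rows found")

    compounds = pd.DataFrame(index=pd.Index(compound_cols, name="compound_id"))
    compounds["compound_class"] = (
        meta.loc["#class", compound_cols].replace("", None)
        if "#class" in meta.index
        else None
    )
    for row_name, col in (
        ("#identified", "is_identified"),
        ("#istd", "is_istd"),
        ("#fame", "is_fame"),
    ):
        if row_name in meta.index:
            compounds[col] = meta.loc[row_name, compound_cols].isin(
                {"1", "true", "True"}
            )
        else:
            compounds[col] = False
    istd_map: dict[str, str] = {}
    if "#istd_map" in meta.index:
        for cid, target in meta.loc["#istd_map", compound_cols].items():
            if target:
                istd_map[cid] = target

    samples = pd.DataFrame(index=pd.Index(body["sample_id"], name="sample_id"))
    try:
        samples["injection_order"] = body["injection_order"].astype(int).to_numpy()
    except ValueError as exc:
        raise FeatureTableError(f"nonnumeric injection_order: {exc}") from exc
    samples["batch"] = body["batch"].to_numpy()
    if (samples["batch"] == "").any():
        raise FeatureTableError("empty batch label")
    samples["role"] = body["role"].to_numpy()
    samples["replicate_group"] = body["replicate_group"].replace("", None).to_numpy()

    values = np.empty((len(body), len(compound_cols)), dtype=float)
    for j, col in enumerate(compound_cols):
        cells = body[col]
        if missing_token is not None:
            cells = cells.replace(missing_token, "nan")
        cells = cells.replace("", "nan")
        try:
            values[:, j] = cells.astype(float).to_numpy()
        except ValueError:
            for i, cell in enumerate(cells):
                try:
                    float(cell)
                except ValueError:
                    raise FeatureTableError(
                        f"nonnumeric intensity {cell!r} at sample "
                        f"{body['sample_id'].iloc[i]!r}, compound {col!r}"
                    ) from None
            raise

    table = FeatureTable(
        intensities=values,
        samples=samples,
        compounds=compounds,
        istd_map=istd_map,
        allow_missing=missing_policy != "reject",
    )
    if missing_policy == "impute-half-minimum" and not np.isfinite(values).all():
        table = table.impute_half_minimum()
    return table.sorted_by_injection()


def write_feature_table(
    table: FeatureTable, path, delimiter: str = ",", missing_token: str = "NA"
) -> None:
    """Write the canonical dialect; :func:`read_feature_table` inverts it."""
    table.validate()
    cids = table.compound_ids
    cols = list(_SAMPLE_COLS) + cids
    rows: list[list[str]] = []

    def meta_row(name: str, values) -> list[str]:
        return [name, "", "", "", ""] + list(values)

    classes = table.compounds.get("compound_class")
    rows.append(
        meta_row(
            "#class",
            ["" if classes is None or pd.isna(c) else str(c) for c in classes]
            if classes is not None
            else [""] * len(cids),
        )
    )
    for name, col in (
        ("#identified", "is_identified"),
        ("#istd", "is_istd"),
        ("#fame", "is_fame"),
    ):
        rows.append(meta_row(name, ["1" if v else "0" for v in table.compounds[col]]))
    rows.append(meta_row("#istd_map", [table.istd_map.get(c, "") for c in cids]))

    for i, sid in enumerate(table.sample_ids):
        meta = table.samples.iloc[i]
        rg = meta.get("replicate_group")
        cells = [
            str(sid),
            str(int(meta["injection_order"])),
            str(meta["batch"]),
            str(meta["role"]),
            "" if rg is None or pd.isna(rg) else str(rg),
        ]
        for v in table.intensities[i]:
            if not np.isfinite(v):
                cells.append(missing_token)
            elif float(v).is_integer():
                cells.append(str(int(v)))
            else:
                cells.append(repr(float(v)))
        rows.append(cells)

    with open(path, "w") as fh:
        fh.write(delimiter.join(cols) + "\n")
        for row in rows:
            fh.write(delimiter.join(row) + "\n")
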