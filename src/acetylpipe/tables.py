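"""Tabular interchange formats for multiplexed acetylome quantification.

The pipeline moves data around as four kinds of objects:

``FeatureTable``
    Acetyl-site or protein-group reporter-ion intensities, indexed by
    feature and by (plex, channel).  Missing cells are ``NaN``; in linear
    space every observed cell is strictly positive (zeros are masked on
    ingestion because downstream log transforms are undefined at 0).
``PlexDesign``
    The experiment layout: which channel of which plex carries which
    condition/replicate, and which channel is the pooled reference (REF).
``ImpurityMatrix``
    Per-label reporter-ion isotope contamination coefficients, used to
    deconvolve observed intensities back to true label signal.
``DiffResult``
    A DataFrame of per-feature, per-contrast differential-testing results
    (schema in :data:`DIFF_COLUMNS`).

All on-disk formats are plain text: TSV for tables (UTF-8, header row,
empty field = missing), CSV in lot-sheet layout for the impurity matrix.
Decimals are rendered with 6 significant digits so repeated write/read
cycles are byte-stable.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "PlexDesign",
    "ImpurityMatrix",
    "TableDialect",
    "DEFAULT_DIALECT",
    "DIFF_COLUMNS",
    "SchemaError",
    "IntegrityError",
    "DesignError",
    "read_feature_table",
    "write_feature_table",
    "read_design",
    "write_design",
    "read_impurity_matrix",
    "write_impurity_matrix",
    "read_results",
    "write_results",
]


class SchemaError(ValueError):
    """A file is missing mandatory columns or has an incompatible layout."""


class IntegrityError(ValueError):
    """Duplicate keys or internally inconsistent content."""


class DesignError(ValueError):
    """A plex design violates a structural invariant."""


#: Column order of the differential-result table.
DIFF_COLUMNS = [
    "feature_id",
    "contrast",
    "log2fc",
    "t_mod",
    "p",
    "padj",
    "n_used",
    "call",
]

_FLOAT_FMT = "{:.6g}"


def _fmt(x: float) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)) or pd.isna(x):
        return ""
    return _FLOAT_FMT.format(float(x))


# ---------------------------------------------------------------------------
# FeatureTable
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """Feature x (plex, channel) intensity matrix with metadata.

    Parameters
    ----------
    values : DataFrame
        Index = feature_id, columns = MultiIndex of (plex, channel).
        ``NaN`` marks a masked (missing/invalid) cell.
    meta : DataFrame
        Index = feature_id; columns ``protein_group`` and, for site-level
        tables, ``site_position`` and ``multiplicity`` (number of acetyl
        groups on the evidencing peptide, 1-3).
    level : str
        ``"site"`` or ``"protein"``.
    log_space : bool
        True once values are log2-transformed.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    level: str
    log_space: bool = False

    def __post_init__(self) -> None:
        if self.level not in ("site", "protein"):
            raise ValueError(f"level must be 'site' or 'protein', got {self.level!r}")
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise IntegrityError(f"duplicate feature_id {dup!r}")
        if not self.values.index.equals(self.meta.index):
            self.meta = self.meta.reindex(self.values.index)
        if not isinstance(self.values.columns, pd.MultiIndex):
            raise ValueError("values columns must be a (plex, channel) MultiIndex")

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean matrix, True where a cell is missing/invalid."""
        return self.values.isna()

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def plexes(self) -> list:
        return list(dict.fromkeys(self.values.columns.get_level_values(0)))

    def channels(self, plex) -> list:
        return [c for p, c in self.values.columns if p == plex]

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.values.copy(), self.meta.copy(), self.level, self.log_space
        )

    def n_unmasked(self) -> int:
        return int(self.values.notna().to_numpy().sum())


# ---------------------------------------------------------------------------
# PlexDesign
# ---------------------------------------------------------------------------


@dataclass
class PlexDesign:
    """Experiment layout: plex/channel -> condition/replicate assignments.

    ``table`` columns: plex, channel, condition, replicate, is_reference.
    Exactly one reference (REF) channel per plex; the baseline condition
    (contrast denominator, default "wildtype") must appear in every plex.
    """

    table: pd.DataFrame
    baseline_condition: str = "wildtype"

    def __post_init__(self) -> None:
        required = ["plex", "channel", "condition", "replicate", "is_reference"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise SchemaError(f"design is missing column(s): {', '.join(missing)}")
        t = self.table
        dup = t.duplicated(subset=["plex", "channel"])
        if dup.any():
            row = t[dup].iloc[0]
            raise IntegrityError(
                f"duplicate (plex, channel) assignment: ({row['plex']}, {row['channel']})"
            )
        for plex, grp in t.groupby("plex", sort=False):
            n_ref = int(grp["is_reference"].sum())
            if n_ref != 1:
                raise DesignError(
                    f"plex {plex!r} has {n_ref} reference channels (exactly 1 required)"
                )
            if self.baseline_condition not in set(grp["condition"]):
                raise DesignError(
                    f"baseline condition {self.baseline_condition!r} absent from plex {plex!r}"
                )
            nonref = grp[~grp["is_reference"].astype(bool)]
            pair_dup = nonref.duplicated(subset=["condition", "replicate"])
            if pair_dup.any():
                row = nonref[pair_dup].iloc[0]
                raise IntegrityError(
                    f"(condition, replicate) = ({row['condition']}, {row['replicate']}) "
                    f"occurs twice in plex {plex!r}"
                )

    @property
    def plexes(self) -> list:
        return list(dict.fromkeys(self.table["plex"]))

    def channels(self, plex) -> list:
        return list(self.table.loc[self.table["plex"] == plex, "channel"])

    def reference_channel(self, plex) -> str:
        sub = self.table[(self.table["plex"] == plex) & self.table["is_reference"].astype(bool)]
        return sub["channel"].iloc[0]

    @property
    def conditions(self) -> list:
        """Experimental conditions, excluding the REF pool."""
        t = self.table[~self.table["is_reference"].astype(bool)]
        return list(dict.fromkeys(t["condition"]))

    def columns_for(self, condition: str) -> list[tuple]:
        """(plex, channel) replicate columns carrying ``condition``."""
        t = self.table
        sub = t[(t["condition"] == condition) & ~t["is_reference"].astype(bool)]
        if sub.empty:
            raise KeyError(f"condition {condition!r} not in design")
        return list(zip(sub["plex"], sub["channel"]))

    def column_index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_arrays(
            [self.table["plex"], self.table["channel"]], names=["plex", "channel"]
        )


# ---------------------------------------------------------------------------
# ImpurityMatrix
# ---------------------------------------------------------------------------


@dataclass
class ImpurityMatrix:
    """Square isotope-contamination matrix over an ordered label ladder.

    ``coefficients[i, j]`` is the fraction of label j's true signal that is
    observed in channel i.  Columns may sum to < 1 (isotopologues falling
    outside the detected ladder are unaccounted for); the diagonal must
    dominate (> 0.5) for the deconvolution to be well posed.
    """

    labels: list = field(default_factory=list)
    coefficients: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))

    def __post_init__(self) -> None:
        A = np.asarray(self.coefficients, dtype=float)
        n = len(self.labels)
        if A.shape != (n, n):
            raise SchemaError(
                f"impurity matrix shape {A.shape} does not match {n} labels"
            )
        if (A < 0).any():
            raise ValueError("impurity matrix has a negative entry")
        colsums = A.sum(axis=0)
        if (colsums > 1 + 1e-9).any():
            j = int(np.argmax(colsums))
            raise ValueError(
                f"impurity column for label {self.labels[j]!r} sums to "
                f"{colsums[j]:.4f} > 1"
            )
        if n and (np.diag(A) <= 0.5).any():
            j = int(np.argmin(np.diag(A)))
            raise ValueError(
                f"impurity matrix not diagonally dominant: A[{j},{j}] = "
                f"{A[j, j]:.3f} <= 0.5 for label {self.labels[j]!r}"
            )
        self.coefficients = A

    def submatrix(self, channels: list) -> np.ndarray:
        """Restrict to the channels actually used, preserving their order."""
        missing = [c for c in channels if c not in self.labels]
        if missing:
            raise SchemaError(
                f"impurity matrix lacks label(s): {', '.join(map(str, missing))}"
            )
        idx = [self.labels.index(c) for c in channels]
        return self.coefficients[np.ix_(idx, idx)]

    @classmethod
    def identity(cls, labels: list) -> "ImpurityMatrix":
        return cls(list(labels), np.eye(len(labels)))


# ---------------------------------------------------------------------------
# Dialects and feature-table IO
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TableDialect:
    """Column-naming profile for MaxQuant-style intensity tables.

    ``reporter_pattern`` is a regex with named groups ``channel`` and
    ``plex`` matched against each header; all other fields name metadata
    columns.  MaxQuant renames reporter columns between versions, so the
    profile isolates that variance from the reader.
    """

    feature_id: str = "Feature ID"
    protein_group: str = "Protein group"
    site_position: str = "Position"
    multiplicity: str = "Multiplicity"
    reporter_pattern: str = r"^Reporter intensity corrected (?P<channel>\S+) (?P<plex>.+)$"
    reverse: str = "Reverse"
    contaminant: str = "Potential contaminant"
    flag_value: str = "+"


DEFAULT_DIALECT = TableDialect()


def read_feature_table(
    path, level: str, dialect: TableDialect = DEFAULT_DIALECT
) -> FeatureTable:
    """Read a site or protein-group intensity TSV.

    Zeros and non-finite intensities are masked (NaN).  Rows flagged as
    reverse-database hits or potential contaminants are dropped.  A leading
    ``# log_space=...`` comment, as written by :func:`write_feature_table`,
    restores the log-space flag.
    """
    log_space = False
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            m = re.search(r"log_space\s*=\s*(\w+)", first)
            if m:
                log_space = m.group(1).lower() in ("true", "1", "yes")
            body = fh.read()
        else:
            body = first + fh.read()
    df = pd.read_csv(io.StringIO(body), sep="\t", dtype={dialect.feature_id: str})

    if dialect.feature_id not in df.columns:
        raise SchemaError(f"missing mandatory column {dialect.feature_id!r}")
    if dialect.protein_group not in df.columns:
        raise SchemaError(f"missing mandatory column {dialect.protein_group!r}")

    # drop reverse / contaminant rows
    n_flagged = 0
    for flag_col in (dialect.reverse, dialect.contaminant):
        if flag_col in df.columns:
            flagged = df[flag_col].astype(str) == dialect.flag_value
            n_flagged += int(flagged.sum())
            df = df[~flagged]

    rep_cols, col_keys = [], []
    for col in df.columns:
        m = re.match(dialect.reporter_pattern, col)
        if m:
            rep_cols.append(col)
            col_keys.append((m.group("plex"), m.group("channel")))
    if not rep_cols:
        raise SchemaError(
            "no reporter-intensity columns matched pattern "
            f"{dialect.reporter_pattern!r}"
        )

    if df[dialect.feature_id].duplicated().any():
        dup = df[dialect.feature_id][df[dialect.feature_id].duplicated()].iloc[0]
        raise IntegrityError(f"duplicate feature_id {dup!r}")

    values = df[rep_cols].apply(pd.to_numeric, errors="coerce")
    values.columns = pd.MultiIndex.from_tuples(col_keys, names=["plex", "channel"])
    values.index = pd.Index(df[dialect.feature_id], name="feature_id")
    arr = values.to_numpy(dtype=float)
    arr[~np.isfinite(arr)] = np.nan
    if not log_space:
        arr[arr <= 0] = np.nan  # zeros carry no quantitative meaning
    values = pd.DataFrame(arr, index=values.index, columns=values.columns)

    meta_cols = {}
    meta_cols["protein_group"] = df[dialect.protein_group].astype(str).values
    if dialect.site_position in df.columns:
        meta_cols["site_position"] = pd.to_numeric(
            df[dialect.site_position], errors="coerce"
        ).astype("Int64").values
    if dialect.multiplicity in df.columns:
        meta_cols["multiplicity"] = pd.to_numeric(
            df[dialect.multiplicity], errors="coerce"
        ).astype("Int64").values
    meta = pd.DataFrame(meta_cols, index=values.index)

    table = FeatureTable(values, meta, level=level, log_space=log_space)
    if n_flagged:
        warnings.warn(f"dropped {n_flagged} reverse/contaminant row(s)", stacklevel=2)
    return table


def write_feature_table(
    table: FeatureTable, path, dialect: TableDialect = DEFAULT_DIALECT
) -> None:
    """Write a FeatureTable as TSV with a stable column order.

    Masked cells become empty fields; the log-space flag is preserved in a
    leading comment line; floats are rendered with 6 significant digits.
    """
    cols = [dialect.feature_id, dialect.protein_group]
    out = pd.DataFrame(index=table.values.index)
    out[dialect.feature_id] = table.values.index
    out[dialect.protein_group] = table.meta.get(
        "protein_group", pd.Series("", index=table.values.index)
    )
    if "site_position" in table.meta.columns:
        out[dialect.site_position] = table.meta["site_position"]
        cols.append(dialect.site_position)
    if "multiplicity" in table.meta.columns:
        out[dialect.multiplicity] = table.meta["multiplicity"]
        cols.append(dialect.multiplicity)
    for (plex, channel) in table.values.columns:
        name = f"Reporter intensity corrected {channel} {plex}"
        out[name] = table.values[(plex, channel)].map(_fmt)
        cols.append(name)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# log_space={str(table.log_space).lower()}\n")
        out[cols].to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Design IO
# ---------------------------------------------------------------------------

_TRUTHY = {"true", "1", "yes", "+", "t"}


def read_design(path, baseline_condition: str = "wildtype") -> PlexDesign:
    """Read a plex-design TSV (plex, channel, condition, replicate, is_reference)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["plex", "channel", "condition", "replicate", "is_reference"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"design is missing column(s): {', '.join(missing)}")
    df["replicate"] = pd.to_numeric(df["replicate"]).astype(int)
    df["is_reference"] = df["is_reference"].str.strip().str.lower().isin(_TRUTHY)
    return PlexDesign(df.reset_index(drop=True), baseline_condition=baseline_condition)


def write_design(design: PlexDesign, path) -> None:
    df = design.table.copy()
    df["is_reference"] = np.where(df["is_reference"].astype(bool), "true", "false")
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Impurity-matrix IO (manufacturer lot-sheet layout)
# ---------------------------------------------------------------------------


def read_impurity_matrix(path) -> ImpurityMatrix:
    """Read a lot-sheet-style impurity CSV into a square mixing matrix.

    Layout: one row per label in ladder order; columns named by signed
    offsets ("-2", "-1", "+1", "+2") holding percent contamination into the
    neighbouring ladder positions.  The diagonal receives the unassigned
    remainder; offsets pointing outside the ladder are discarded with a
    warning (their mass stays unaccounted, so columns may sum to < 1).
    """
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise SchemaError("impurity file is missing mandatory column 'label'")
    offset_cols = []
    for col in df.columns:
        s = str(col).strip()
        if re.fullmatch(r"[+-]\d+", s):
            offset_cols.append((col, int(s)))
    labels = [str(x) for x in df["label"]]
    n = len(labels)
    A = np.zeros((n, n))
    n_dropped = 0
    for j in range(n):
        total_pct = 0.0
        for col, off in offset_cols:
            pct = float(df.iloc[j][col]) if pd.notna(df.iloc[j][col]) else 0.0
            if pct < 0:
                raise ValueError(
                    f"negative impurity ({pct}%) for label {labels[j]!r} offset {off:+d}"
                )
            total_pct += pct
            i = j + off
            if 0 <= i < n:
                A[i, j] += pct / 100.0
            elif pct > 0:
                n_dropped += 1
        A[j, j] += 1.0 - total_pct / 100.0
    if n_dropped:
        warnings.warn(
            f"{n_dropped} impurity offset(s) point outside the label ladder; "
            "their signal is treated as unobserved",
            stacklevel=2,
        )
    return ImpurityMatrix(labels, A)


def write_impurity_matrix(
    labels: list, offsets: pd.DataFrame, path
) -> None:
    """Write a lot-sheet CSV from per-label percent offsets (columns like '-1', '+1')."""
    out = offsets.copy()
    out.insert(0, "label", list(labels))
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Differential-result IO
# ---------------------------------------------------------------------------


def write_results(results: pd.DataFrame, path) -> None:
    """Write differential results as TSV, ordered by (feature_id, contrast)."""
    missing = [c for c in DIFF_COLUMNS if c not in results.columns]
    if missing:
        raise SchemaError(f"results are missing column(s): {', '.join(missing)}")
    out = results[DIFF_COLUMNS].sort_values(["feature_id", "contrast"], kind="mergesort")
    out = out.reset_index(drop=True)
    for col in ("log2fc", "t_mod", "p", "padj"):
        out[col] = out[col].map(_fmt)
    out.to_csv(path, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str, "contrast": str, "call": str})
    missing = [c for c in DIFF_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"results are missing column(s): {', '.join(missing)}")
    return df
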