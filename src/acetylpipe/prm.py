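"""Targeted (parallel-reaction-monitoring) peptide quantification.

PRM validates shotgun findings on a handful of pre-selected peptides: for
each peptide, three fragment-ion transitions are monitored and their
chromatographic peak areas summed (then summed across charge states) into
a *total peak area*.  Unmodified peptides — not acetylated in any sample —
serve as per-sample loading normalizers; acetylated peptide totals are
scaled by the resulting factors, expressed as fold change over the mock
(untreated) samples, and compared across time-point groups with a
classical one-way ANOVA.

A PRM table is a long-format DataFrame with columns ``peptide_id``,
``charge``, ``transition_id``, ``sample_id``, ``area``, ``is_modified``,
``sample_group``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PRM_COLUMNS",
    "validate_prm_table",
    "total_peak_area",
    "normalization_factors",
    "normalize_modified",
    "anova_mock_vs_treated",
    "quantify_prm",
]

PRM_COLUMNS = [
    "peptide_id",
    "charge",
    "transition_id",
    "sample_id",
    "area",
    "is_modified",
    "sample_group",
]

TRANSITIONS_PER_PEPTIDE = 3


class PRMValidationError(ValueError):
    pass


def validate_prm_table(table: pd.DataFrame, allow_two: bool = False) -> None:
    missing = [c for c in PRM_COLUMNS if c not in table.columns]
    if missing:
        raise PRMValidationError(f"PRM table missing column(s): {', '.join(missing)}")
    areas = table["area"].to_numpy(dtype=float)
    if not np.isfinite(areas).all() or (areas < 0).any():
        raise PRMValidationError("PRM areas must be finite and non-negative")
    counts = table.groupby(["peptide_id", "charge", "sample_id"]).size()
    lo = 2 if allow_two else TRANSITIONS_PER_PEPTIDE
    bad = counts[(counts < lo) | (counts > TRANSITIONS_PER_PEPTIDE)]
    if not bad.empty:
        key = bad.index[0]
        raise PRMValidationError(
            f"peptide/charge/sample {key} has {bad.iloc[0]} transitions "
            f"(expected {TRANSITIONS_PER_PEPTIDE})"
        )
    if allow_two and (counts == 2).any():
        warnings.warn(
            f"{int((counts == 2).sum())} peptide/charge/sample group(s) have only "
            "2 transitions", stacklevel=2,
        )


def total_peak_area(
    table: pd.DataFrame, allow_two: bool = False
) -> tuple[pd.DataFrame, pd.Series]:
    """Sum transition areas per charge state, then across charge states.

    Returns ``(totals, is_modified)``: a peptide x sample matrix of total
    peak areas and the per-peptide modification flag.
    """
    validate_prm_table(table, allow_two=allow_two)
    per_charge = table.groupby(["peptide_id", "charge", "sample_id"])["area"].sum()
    totals = per_charge.groupby(["peptide_id", "sample_id"]).sum().unstack("sample_id")
    is_mod = table.groupby("peptide_id")["is_modified"].first().astype(bool)
    return totals, is_mod.reindex(totals.index)


def normalization_factors(unmod_totals: pd.DataFrame) -> pd.Series:
    """Per-sample loading factors from unmodified-peptide totals.

    Median-of-ratios: each normalizer peptide's across-sample median total
    serves as its pseudo-reference level; the ratio reference/total in a
    sample measures that sample's loading, and the per-sample factor is
    the median of these ratios over normalizer peptides.  The double
    median makes the factor insensitive to a few aberrant peptides or
    runs; multiplying a sample's totals by its factor equalizes
    unmodified-peptide levels across samples.
    """
    if unmod_totals.empty:
        raise PRMValidationError("no unmodified (normalizer) peptides provided")
    vals = unmod_totals.to_numpy(dtype=float)
    if np.isnan(vals).any() or (vals <= 0).any():
        bad = unmod_totals.columns[np.isnan(vals).any(axis=0) | (vals <= 0).any(axis=0)]
        raise PRMValidationError(
            "sample(s) without a positive quantification for every normalizer "
            f"peptide: {', '.join(map(str, bad))}"
        )
    reference = np.median(vals, axis=1)  # per-peptide pseudo-reference level
    ratios = reference[:, None] / vals
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=unmod_totals.columns, name="factor")


def normalize_modified(
    totals: pd.DataFrame,
    factors: pd.Series,
    sample_groups: pd.Series,
    mock_group: str = "mock",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply loading factors and express totals as fold change over mock.

    Returns ``(normalized, fold_change)``; the fold change divides by the
    mean normalized total of the mock-group samples per peptide.
    """
    missing = [s for s in totals.columns if s not in factors.index]
    if missing:
        raise PRMValidationError(
            f"normalization factors missing for sample(s): {', '.join(map(str, missing))}"
        )
    normalized = totals * factors.reindex(totals.columns)
    mock_samples = [s for s in totals.columns if sample_groups.get(s) == mock_group]
    if not mock_samples:
        raise PRMValidationError(f"no samples in mock group {mock_group!r}")
    mock_mean = normalized[mock_samples].mean(axis=1)
    if (mock_mean == 0).any() or mock_mean.isna().any():
        bad = mock_mean.index[(mock_mean == 0) | mock_mean.isna()][0]
        raise PRMValidationError(
            f"mock mean is zero/undefined for peptide {bad!r}; fold change undefined"
        )
    fold = normalized.div(mock_mean, axis=0)
    return normalized, fold


def anova_mock_vs_treated(
    normalized: pd.DataFrame, sample_groups: pd.Series
) -> pd.DataFrame:
    """Classical one-way ANOVA per peptide across sample groups.

    Groups are the mock and each treatment time point; F has (G-1, N-G)
    degrees of freedom.  Every group needs >= 2 replicates (a singleton
    group has no within-group variance).
    """
    groups: dict[str, list] = {}
    for s in normalized.columns:
        g = sample_groups.get(s)
        if g is None:
            raise PRMValidationError(f"sample {s!r} has no group assignment")
        groups.setdefault(g, []).append(s)
    if len(groups) < 2:
        raise PRMValidationError("one-way ANOVA needs at least 2 groups")
    for g, samples in groups.items():
        if len(samples) < 2:
            raise PRMValidationError(
                f"group {g!r} has a single replicate; within-group variance undefined"
            )
    rows = []
    for pep, row in normalized.iterrows():
        arrays = [row[samples].to_numpy(dtype=float) for samples in groups.values()]
        if np.ptp(np.concatenate(arrays)) == 0:  # all values identical
            f_stat, p = 0.0, 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f_stat, p = stats.f_oneway(*arrays)
            if not np.isfinite(f_stat):  # zero within-group variance everywhere
                means = [a.mean() for a in arrays]
                f_stat, p = (0.0, 1.0) if np.ptp(means) == 0 else (np.inf, 0.0)
        rows.append({"peptide_id": pep, "F": float(f_stat), "p": float(p)})
    return pd.DataFrame(rows, columns=["peptide_id", "F", "p"])


def quantify_prm(
    table: pd.DataFrame, mock_group: str = "mock", allow_two: bool = False
) -> dict:
    """Run the full PRM arm; returns totals, factors, fold changes, ANOVA."""
    totals, is_mod = total_peak_area(table, allow_two=allow_two)
    sample_groups = (
        table.groupby("sample_id")["sample_group"].first()
    )
    factors = normalization_factors(totals.loc[~is_mod])
    normalized, fold = normalize_modified(
        totals.loc[is_mod], factors, sample_groups, mock_group=mock_group
    )
    anova = anova_mock_vs_treated(normalized, sample_groups)
    return {
        "totals": totals,
        "is_modified": is_mod,
        "factors": factors,
        "normalized": normalized,
        "fold_change": fold,
        "anova": anova,
    }
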