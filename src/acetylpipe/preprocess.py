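"""Reporter-intensity preprocessing for multiplexed (TMT) experiments.

Three transformers, applied in this order:

1. :class:`IsotopeImpurityCorrector` — linear deconvolution of reporter-ion
   isotope contamination (observed = A @ true, solved per feature and plex).
2. :class:`MedianNormalizer` — within-plex scaling so every channel's log2
   median matches the plex grand median (corrects channel loading).
3. :class:`IRSNormalizer` — between-plex internal reference scaling: each
   feature's reference-channel intensity is aligned to its geometric mean
   across plexes, making intensities comparable across batches.

Each transformer follows the scikit-learn estimator protocol but consumes
and returns :class:`~acetylpipe.tables.FeatureTable` objects; the
module-level functions are thin wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin

from .tables import FeatureTable, ImpurityMatrix, PlexDesign, SchemaError

__all__ = [
    "NormalizationReport",
    "IsotopeImpurityCorrector",
    "MedianNormalizer",
    "IRSNormalizer",
    "correct_isotope_impurities",
    "median_normalize_within_plex",
    "irs_normalize",
    "preprocess_table",
]


@dataclass
class NormalizationReport:
    """Scale factors and masking counts produced by a normalization step."""

    channel_factors: dict = field(default_factory=dict)  # (plex, channel) -> factor
    irs_factors: pd.DataFrame | None = None  # feature x plex
    masked_counts: dict = field(default_factory=dict)  # step name -> n cells/features
    dropped_features: list = field(default_factory=list)


class IsotopeImpurityCorrector(BaseEstimator, TransformerMixin):
    """Deconvolve reporter-ion isotope impurities per (feature, plex).

    For each feature and plex the observed channel vector ``o`` satisfies
    ``o = A t`` where column j of ``A`` distributes label j's true signal
    over the ladder.  The corrector solves for ``t``; when the exact
    solution has negative components (physically impossible intensities) a
    non-negative least-squares solution is substituted, which clamps the
    offending channels to zero.  A vector fully clamped to zero is masked.

    Vectors with any masked channel are left uncorrected (solving a partial
    system is underdetermined) and counted in ``skipped_incomplete_``.

    Parameters
    ----------
    impurity_matrix : ImpurityMatrix
        Label ladder covering every channel in the table, same order.
    cond_limit : float
        Condition-number ceiling above which the matrix is rejected.
    """

    def __init__(self, impurity_matrix: ImpurityMatrix, cond_limit: float = 1e8):
        self.impurity_matrix = impurity_matrix
        self.cond_limit = cond_limit

    def fit(self, X: FeatureTable, y=None):
        if X.log_space:
            raise ValueError("impurity correction requires linear-space intensities")
        self.submatrices_ = {}
        for plex in X.plexes:
            channels = X.channels(plex)
            A = self.impurity_matrix.submatrix(channels)
            # the ladder restriction can only shrink column sums; re-check conditioning
            if np.linalg.cond(A) > self.cond_limit:
                raise np.linalg.LinAlgError(
                    f"impurity matrix for plex {plex!r} is ill conditioned "
                    f"(cond > {self.cond_limit:g})"
                )
            if (np.diag(A) <= 0.5).any():
                raise ValueError(
                    f"impurity matrix for plex {plex!r} lost diagonal dominance"
                )
            self.submatrices_[plex] = A
        return self

    def transform(self, X: FeatureTable) -> FeatureTable:
        if not hasattr(self, "submatrices_"):
            self.fit(X)
        out = X.values.copy()
        skipped = 0
        fully_clamped = 0
        for plex, A in self.submatrices_.items():
            cols = [(plex, c) for c in X.channels(plex)]
            block = X.values[cols].to_numpy(dtype=float)
            complete = ~np.isnan(block).any(axis=1)
            skipped += int((~complete).sum() - np.isnan(block).all(axis=1).sum())
            if complete.any():
                sol = np.linalg.solve(A, block[complete].T).T
                neg = (sol < 0).any(axis=1)
                if neg.any():
                    idx_neg = np.flatnonzero(neg)
                    obs = block[complete]
                    for i in idx_neg:
                        sol[i], _ = nnls(A, obs[i])
                    zeroed = ~(sol[idx_neg] > 0).any(axis=1)
                    if zeroed.any():
                        sol[idx_neg[zeroed]] = np.nan
                        fully_clamped += int(zeroed.sum())
                corrected = block.copy()
                corrected[complete] = sol
                out.loc[:, cols] = corrected
        self.skipped_incomplete_ = skipped
        self.fully_clamped_ = fully_clamped
        return FeatureTable(out, X.meta.copy(), X.level, X.log_space)


class MedianNormalizer(BaseEstimator, TransformerMixin):
    """Within-plex median normalization of channel intensities.

    Each channel is scaled (linearly) so that its log2 median over unmasked
    features equals the grand median of the plex's channel log2 medians.
    This removes per-channel loading differences while leaving the plex's
    overall intensity scale in place.
    """

    MIN_FEATURES = 10

    def __init__(self, design: PlexDesign | None = None):
        self.design = design

    def fit(self, X: FeatureTable, y=None):
        if X.log_space:
            raise ValueError("median normalization expects linear-space intensities")
        factors = {}
        for plex in X.plexes:
            cols = [(plex, c) for c in X.channels(plex)]
            log2 = np.log2(X.values[cols].to_numpy(dtype=float))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                medians = np.nanmedian(log2, axis=0)
            counts = (~np.isnan(log2)).sum(axis=0)
            defined = ~np.isnan(medians)
            if not defined.any():
                for col in cols:
                    factors[col] = np.nan
                continue
            grand = float(np.median(medians[defined]))
            for k, col in enumerate(cols):
                if not defined[k]:
                    factors[col] = np.nan  # fully masked channel stays masked
                    continue
                if counts[k] < self.MIN_FEATURES:
                    warnings.warn(
                        f"channel {col} has only {counts[k]} unmasked features; "
                        "median factor estimated from available data",
                        stacklevel=2,
                    )
                factors[col] = float(2.0 ** (grand - medians[k]))
        self.factors_ = factors
        self.report_ = NormalizationReport(channel_factors=dict(factors))
        return self

    def transform(self, X: FeatureTable) -> FeatureTable:
        out = X.values.copy()
        for col, f in self.factors_.items():
            if col in out.columns and np.isfinite(f):
                out[col] = out[col] * f
        return FeatureTable(out, X.meta.copy(), X.level, X.log_space)


class IRSNormalizer(BaseEstimator, TransformerMixin):
    """Between-plex internal reference scaling (IRS).

    The pooled REF sample is present in every plex, so any per-feature
    plex-to-plex multiplicative offset shows up in its intensities.  For
    each feature the reference intensities are aligned to their geometric
    mean across plexes, and the same factor rescales every channel of that
    plex, removing the batch effect exactly when it is multiplicative.

    Features whose reference is masked in a plex have that plex's cells
    masked (no imputation); features with the reference masked in every
    plex are dropped.  Both are counted in ``report_``.
    """

    def __init__(self, design: PlexDesign = None):
        self.design = design

    def fit(self, X: FeatureTable, y=None):
        if self.design is None:
            raise ValueError("IRSNormalizer requires a PlexDesign")
        plexes = X.plexes
        ref_cols = [(p, self.design.reference_channel(p)) for p in plexes]
        for col in ref_cols:
            if col not in X.values.columns:
                raise SchemaError(f"reference channel column {col} absent from table")
        ref = X.values[ref_cols].to_numpy(dtype=float)  # feature x plex
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            logref = np.log2(ref)
            geomean = 2.0 ** np.nanmean(logref, axis=1)
            factors = geomean[:, None] / ref
        self.irs_factors_ = pd.DataFrame(factors, index=X.feature_ids, columns=plexes)
        self.ref_present_ = pd.DataFrame(
            ~np.isnan(ref), index=X.feature_ids, columns=plexes
        )
        return self

    def transform(self, X: FeatureTable) -> FeatureTable:
        plexes = X.plexes
        factors = self.irs_factors_.reindex(X.feature_ids)
        keep = self.ref_present_.reindex(X.feature_ids).any(axis=1)
        dropped = list(X.feature_ids[~keep])

        values = X.values.loc[keep].copy()
        n_masked_cells = 0
        for plex in plexes:
            cols = [(plex, c) for c in X.channels(plex)]
            f = factors.loc[keep, plex].to_numpy()
            block = values[cols].to_numpy(dtype=float)
            missing_ref = ~np.isfinite(f)
            n_masked_cells += int(np.isfinite(block[missing_ref]).sum())
            block *= np.where(missing_ref, np.nan, f)[:, None]
            values.loc[:, cols] = block
        self.report_ = NormalizationReport(
            irs_factors=factors.loc[keep],
            masked_counts={"ref_missing_cells": n_masked_cells},
            dropped_features=dropped,
        )
        return FeatureTable(values, X.meta.loc[keep].copy(), X.level, X.log_space)


def correct_isotope_impurities(
    table: FeatureTable, impurity_matrix: ImpurityMatrix
) -> FeatureTable:
    return IsotopeImpurityCorrector(impurity_matrix).fit(table).transform(table)


def median_normalize_within_plex(
    table: FeatureTable, design: PlexDesign | None = None
) -> tuple[FeatureTable, NormalizationReport]:
    norm = MedianNormalizer(design).fit(table)
    return norm.transform(table), norm.report_


def irs_normalize(
    table: FeatureTable, design: PlexDesign
) -> tuple[FeatureTable, NormalizationReport]:
    norm = IRSNormalizer(design).fit(table)
    return norm.transform(table), norm.report_


def preprocess_table(
    table: FeatureTable,
    design: PlexDesign,
    impurity_matrix: ImpurityMatrix | None = None,
) -> tuple[FeatureTable, NormalizationReport]:
    """Full preprocessing chain: impurity correction -> median -> IRS."""
    if impurity_matrix is not None:
        table = correct_isotope_impurities(table, impurity_matrix)
    table, med_report = median_normalize_within_plex(table, design)
    table, irs_report = irs_normalize(table, design)
    irs_report.channel_factors = med_report.channel_factors
    return table, irs_report
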