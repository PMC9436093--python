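"""Protein-level normalization and moderated differential testing.

Acetyl-site intensities confound two signals: the stoichiometry of the
modification and the abundance of the carrier protein.  Sites are therefore
expressed as log2(site) - log2(protein) before testing, so a change in
protein abundance alone cancels out.

Testing uses an empirical-Bayes moderated t-statistic: per-feature residual
variances from a one-way layout (one mean per condition) are shrunk toward
a global prior variance ``s0_sq`` with prior degrees of freedom ``d0``,
both estimated by moment matching on the log residual variances (the
scaled-F model, solved by trigamma inversion).  The moderated statistic
gains ``d0`` degrees of freedom over the ordinary t, which matters at n = 3
replicates per condition.

A site is called regulated when |fold change| >= 1.5 versus the baseline
(wildtype) and the Benjamini-Hochberg adjusted p-value is <= 0.05; both
thresholds are inclusive and configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .tables import DIFF_COLUMNS, FeatureTable, PlexDesign, SchemaError

__all__ = [
    "ModeratedFitParams",
    "ContrastSpec",
    "ProteinNormalizer",
    "ModeratedTester",
    "normalize_site_to_protein",
    "fit_moderated_contrasts",
    "estimate_variance_prior",
    "trigamma_inverse",
    "adjust_bh",
    "call_regulated",
]


@dataclass
class ModeratedFitParams:
    """Empirical-Bayes shrinkage parameters of a moderated fit.

    ``s_tilde_sq = (d0 * s0_sq + d * s_sq) / (d0 + d)``; d0 -> 0 recovers
    the per-feature variance, d0 -> inf the common prior variance.
    """

    d0: float
    s0_sq: float
    s_sq: pd.Series  # per-feature residual variance
    df_resid: pd.Series  # per-feature residual df
    s_tilde_sq: pd.Series  # posterior (shrunk) variance


@dataclass(frozen=True)
class ContrastSpec:
    """One condition-vs-baseline comparison with a completeness rule."""

    numerator: str
    denominator: str = "wildtype"
    min_replicates: int = 3

    def __post_init__(self):
        if self.numerator == self.denominator:
            raise ValueError("contrast numerator equals denominator")


# ---------------------------------------------------------------------------
# Site-to-protein normalization
# ---------------------------------------------------------------------------


class ProteinNormalizer(BaseEstimator):
    """Express site intensities relative to parent-protein abundance.

    ``transform`` returns a log2-space table of log2(site) - log2(protein),
    matched cell-wise through the site's protein group.  Sites whose
    protein group is absent from the protein table are routed, in log2
    space, to ``unnormalized_`` and flagged there (their fold changes would
    mix acetylation and abundance changes).
    """

    def __init__(self, proteins: FeatureTable = None):
        self.proteins = proteins

    def fit(self, X: FeatureTable, y=None):
        if self.proteins is None:
            raise ValueError("ProteinNormalizer requires a protein-level FeatureTable")
        if self.proteins.log_space or X.log_space:
            raise ValueError("both tables must be in linear space (post-IRS)")
        if not X.values.columns.equals(self.proteins.values.columns):
            raise SchemaError("site and protein tables have different (plex, channel) axes")
        return self

    def transform(self, X: FeatureTable) -> FeatureTable:
        self.fit(X)
        groups = X.meta["protein_group"].astype(str)
        have = groups.isin(self.proteins.values.index.astype(str))

        matched = X.values.loc[have]
        prot = self.proteins.values.reindex(groups[have].values)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.log2(matched.to_numpy(dtype=float)) - np.log2(
                prot.to_numpy(dtype=float)
            )
        normalized = FeatureTable(
            pd.DataFrame(ratio, index=matched.index, columns=matched.columns),
            X.meta.loc[have].copy(),
            level="site",
            log_space=True,
        )

        orphan = X.values.loc[~have]
        with np.errstate(divide="ignore", invalid="ignore"):
            orphan_log = np.log2(orphan.to_numpy(dtype=float))
        orphan_meta = X.meta.loc[~have].copy()
        orphan_meta["protein_normalized"] = False
        self.unnormalized_ = FeatureTable(
            pd.DataFrame(orphan_log, index=orphan.index, columns=orphan.columns),
            orphan_meta,
            level="site",
            log_space=True,
        )
        return normalized


def normalize_site_to_protein(
    sites: FeatureTable, proteins: FeatureTable
) -> tuple[FeatureTable, FeatureTable]:
    """Return (protein-normalized log2 sites, unmatched log2 sites)."""
    norm = ProteinNormalizer(proteins)
    normalized = norm.fit(sites).transform(sites)
    return normalized, norm.unnormalized_


# ---------------------------------------------------------------------------
# Empirical-Bayes variance shrinkage
# ---------------------------------------------------------------------------


def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration on 1/trigamma."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_variance_prior(
    s_sq: np.ndarray, df: np.ndarray
) -> tuple[float, float]:
    """Estimate prior df ``d0`` and prior variance ``s0_sq`` by moment matching.

    Under the hierarchical model, log s_sq is a shifted log-F variate; the
    excess variance of ``log s_sq - digamma(d/2) + log(d/2)`` over the
    sampling contribution ``trigamma(d/2)`` identifies ``trigamma(d0/2)``.
    Non-positive variances (exactly-fitting features) carry no information
    about the prior and are excluded.  Returns ``(0, 0)`` when fewer than
    two informative variances exist (no moderation possible) and
    ``(inf, s0_sq)`` when the variances are underdispersed relative to pure
    sampling noise (all features share one variance).
    """
    s_sq = np.asarray(s_sq, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s_sq) & (s_sq > 0) & (df > 0)
    if ok.sum() < 2:
        return 0.0, 0.0
    z = np.log(s_sq[ok])
    d = df[ok]
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    ebar = float(np.mean(e))
    n = e.size
    evar = float(np.sum((e - ebar) ** 2) / (n - 1))
    excess = evar - float(np.mean(special.polygamma(1, d / 2.0)))
    if excess <= 0:
        return np.inf, float(np.exp(ebar))
    d0 = 2.0 * trigamma_inverse(excess)
    s0_sq = float(np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def _squeeze_var(s_sq, df, d0, s0_sq):
    s_sq = np.asarray(s_sq, dtype=float)
    df = np.asarray(df, dtype=float)
    if np.isinf(d0):
        return np.full_like(s_sq, s0_sq)
    if d0 == 0:
        return s_sq.copy()
    out = (d0 * s0_sq + df * np.where(df > 0, s_sq, 0.0)) / (d0 + df)
    return out


# ---------------------------------------------------------------------------
# Moderated testing
# ---------------------------------------------------------------------------


class ModeratedTester(BaseEstimator):
    """Moderated condition-vs-baseline testing on a log2 feature table.

    Fits a one-way layout (one mean per experimental condition, replicates
    = plexes) per feature, pools the residual variance across all
    conditions, shrinks it toward the empirical-Bayes prior, and tests the
    requested contrasts with a moderated t on ``d0 + d`` degrees of
    freedom.  Features failing the completeness rule (default: unmasked in
    all three replicates of both arms) are reported with ``call=untested``.

    Parameters
    ----------
    design : PlexDesign
        Experiment layout; the REF channel never enters the model.
    contrasts : list of ContrastSpec, optional
        Defaults to every non-baseline condition versus the baseline.
    min_replicates : int
        Completeness rule: minimum unmasked replicates per arm.
    prior_df : float, optional
        Force ``d0`` instead of estimating it (0 = ordinary t,
        inf = fully pooled variance).  Mostly for validation.
    alpha, fc_threshold : float
        Regulated-site thresholds applied by :func:`call_regulated`.
    """

    def __init__(
        self,
        design: PlexDesign = None,
        contrasts: list[ContrastSpec] | None = None,
        min_replicates: int = 3,
        prior_df: float | None = None,
        fc_threshold: float = 1.5,
        alpha: float = 0.05,
    ):
        self.design = design
        self.contrasts = contrasts
        self.min_replicates = min_replicates
        self.prior_df = prior_df
        self.fc_threshold = fc_threshold
        self.alpha = alpha

    def _resolve_contrasts(self) -> list[ContrastSpec]:
        if self.contrasts is not None:
            return list(self.contrasts)
        base = self.design.baseline_condition
        return [
            ContrastSpec(c, base, self.min_replicates)
            for c in self.design.conditions
            if c != base
        ]

    def fit(self, X: FeatureTable, y=None):
        if not X.log_space:
            raise ValueError("moderated testing requires a log2-space table")
        design = self.design
        conditions = design.conditions
        if len(conditions) < 2:
            raise ValueError("at least 2 experimental conditions required")

        # per-condition replicate blocks (features x replicates)
        cond_blocks = {}
        for cond in conditions:
            cols = [c for c in design.columns_for(cond) if c in X.values.columns]
            cond_blocks[cond] = X.values[[*cols]].to_numpy(dtype=float)

        n_feat = X.values.shape[0]
        rss = np.zeros(n_feat)
        n_used = np.zeros(n_feat)
        g_used = np.zeros(n_feat)
        means = {}
        counts = {}
        for cond, block in cond_blocks.items():
            cnt = (~np.isnan(block)).sum(axis=1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                mu = np.nanmean(block, axis=1)
            means[cond] = mu
            counts[cond] = cnt
            resid = block - mu[:, None]
            rss += np.nansum(resid**2, axis=1)
            n_used += cnt
            g_used += (cnt > 0).astype(int)

        df_resid = n_used - g_used
        with np.errstate(divide="ignore", invalid="ignore"):
            s_sq = np.where(df_resid > 0, rss / np.maximum(df_resid, 1), np.nan)

        if self.prior_df is None:
            d0, s0_sq = estimate_variance_prior(s_sq, df_resid)
        else:
            d0 = float(self.prior_df)
            _, s0_est = estimate_variance_prior(s_sq, df_resid)
            s0_sq = s0_est if np.isfinite(d0) and d0 > 0 or np.isinf(d0) else 0.0
        s_tilde_sq = _squeeze_var(np.nan_to_num(s_sq, nan=0.0), df_resid, d0, s0_sq)

        self.params_ = ModeratedFitParams(
            d0=d0,
            s0_sq=s0_sq,
            s_sq=pd.Series(s_sq, index=X.feature_ids),
            df_resid=pd.Series(df_resid, index=X.feature_ids),
            s_tilde_sq=pd.Series(s_tilde_sq, index=X.feature_ids),
        )

        rows = []
        any_tested = False
        for spec in self._resolve_contrasts():
            for cond in (spec.numerator, spec.denominator):
                if cond not in means:
                    raise KeyError(f"condition {cond!r} not present in design/table")
            n1 = counts[spec.numerator]
            n2 = counts[spec.denominator]
            tested = (n1 >= spec.min_replicates) & (n2 >= spec.min_replicates)
            any_tested |= bool(tested.any())
            fc = means[spec.numerator] - means[spec.denominator]
            df_total = d0 + df_resid if np.isfinite(d0) else np.full(n_feat, np.inf)
            with np.errstate(divide="ignore", invalid="ignore"):
                se = np.sqrt(s_tilde_sq * (1.0 / n1 + 1.0 / n2))
                t = np.where(se > 0, fc / np.where(se > 0, se, 1.0), np.sign(fc) * np.inf)
            t = np.where((se == 0) & (fc == 0), 0.0, t)
            p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df_total, 1e-12))
            p = np.where(np.isinf(t), 0.0, p)
            p = np.where(t == 0, 1.0, p)
            contrast_name = f"{spec.numerator}_vs_{spec.denominator}"
            rows.append(
                pd.DataFrame(
                    {
                        "feature_id": X.feature_ids,
                        "contrast": contrast_name,
                        "log2fc": np.where(tested, fc, np.nan),
                        "t_mod": np.where(tested, t, np.nan),
                        "p": np.where(tested, p, np.nan),
                        "padj": np.nan,
                        "n_used": np.minimum(n1, n2).astype(int),
                        "call": np.where(tested, "ns", "untested"),
                    }
                )
            )
        if not any_tested:
            warnings.warn("no feature passed the completeness rule in any contrast",
                          stacklevel=2)
        results = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
            columns=DIFF_COLUMNS
        )
        results = adjust_bh(results)
        self.results_ = call_regulated(results, self.fc_threshold, self.alpha)
        return self

    def transform(self, X: FeatureTable) -> pd.DataFrame:
        return self.fit(X).results_

    fit_transform = transform


def fit_moderated_contrasts(
    table: FeatureTable,
    design: PlexDesign,
    contrasts: list[ContrastSpec] | None = None,
    **kwargs,
) -> tuple[pd.DataFrame, ModeratedFitParams]:
    tester = ModeratedTester(design, contrasts, **kwargs).fit(table)
    return tester.results_, tester.params_


# ---------------------------------------------------------------------------
# Multiple testing and calling
# ---------------------------------------------------------------------------


def adjust_bh(results: pd.DataFrame) -> pd.DataFrame:
    """Benjamini-Hochberg adjustment, applied within each contrast family.

    NaN p-values (untested features) propagate to NaN adjusted values and
    do not count toward the family size.
    """
    out = results.copy()
    out["padj"] = np.nan
    for contrast, idx in out.groupby("contrast").groups.items():
        p = out.loc[idx, "p"].to_numpy(dtype=float)
        ok = np.isfinite(p)
        if (~ok).any() and ok.any():
            warnings.warn(
                f"{int((~ok).sum())} NaN p-value(s) in contrast {contrast!r} "
                "propagate to NaN padj",
                stacklevel=2,
            )
        if ok.any():
            padj = np.full_like(p, np.nan)
            padj[ok] = multipletests(p[ok], method="fdr_bh")[1]
            out.loc[idx, "padj"] = padj
    return out


def adjust_bh_pvalues(p: np.ndarray) -> np.ndarray:
    """BH step-up on a bare p-value vector (single family)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def call_regulated(
    results: pd.DataFrame, fc_threshold: float = 1.5, alpha: float = 0.05
) -> pd.DataFrame:
    """Set the regulation call: up/down at |FC| >= threshold and padj <= alpha.

    Both thresholds are inclusive.  Rows marked ``untested`` keep that call.
    """
    out = results.copy()
    lfc = np.log2(fc_threshold)
    tested = out["call"] != "untested"
    sig = tested & (out["padj"] <= alpha)
    out.loc[tested, "call"] = "ns"
    out.loc[sig & (out["log2fc"] >= lfc), "call"] = "up"
    out.loc[sig & (out["log2fc"] <= -lfc), "call"] = "down"
    return out
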