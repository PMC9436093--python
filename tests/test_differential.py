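"""Protein normalization, moderated-t oracles, BH, and regulated calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from acetylpipe.differential import (
    ContrastSpec,
    ModeratedTester,
    adjust_bh,
    adjust_bh_pvalues,
    call_regulated,
    estimate_variance_prior,
    normalize_site_to_protein,
)
from conftest import make_design, make_feature_table


def _paired_tables(site_vals, prot_vals, channels=("a", "b"), plexes=("plex1",),
                   protein_groups=None):
    n_sites = np.asarray(site_vals).shape[0]
    protein_groups = protein_groups or [f"P{i}" for i in range(n_sites)]
    sites = make_feature_table(np.asarray(site_vals), list(plexes), list(channels),
                               protein_groups=protein_groups)
    prot = np.asarray(prot_vals)
    proteins = make_feature_table(
        prot, list(plexes), list(channels),
        feature_ids=[f"P{i}" for i in range(prot.shape[0])],
        protein_groups=[f"P{i}" for i in range(prot.shape[0])],
        level="protein",
    )
    return sites, proteins


# ---------------------------------------------------------------------------
# Site-to-protein normalization
# ---------------------------------------------------------------------------


def test_log2_ratio_of_site_over_protein():
    sites, proteins = _paired_tables([[800.0, 100.0]], [[400.0, 400.0]])
    normalized, _ = normalize_site_to_protein(sites, proteins)
    assert normalized.log_space
    np.testing.assert_allclose(normalized.values.to_numpy(), [[1.0, -2.0]])


def test_proportional_site_and_protein_cancel_everywhere():
    rng = np.random.default_rng(0)
    prot = rng.lognormal(10, 1, size=(5, 4))
    sites, proteins = _paired_tables(prot * 0.25, prot,
                                     channels=["a", "b", "c", "d"])
    normalized, _ = normalize_site_to_protein(sites, proteins)
    vals = normalized.values.to_numpy()
    np.testing.assert_allclose(vals, np.full_like(vals, -2.0))


def test_orphan_sites_routed_to_unnormalized_output():
    sites, proteins = _paired_tables(
        [[800.0, 100.0], [10.0, 20.0]], [[400.0, 400.0]],
        protein_groups=["P0", "MISSING"],
    )
    normalized, orphans = normalize_site_to_protein(sites, proteins)
    assert list(normalized.feature_ids) == [sites.feature_ids[0]]
    assert list(orphans.feature_ids) == [sites.feature_ids[1]]
    assert not orphans.meta["protein_normalized"].iloc[0]


def test_masked_protein_cell_masks_the_site_cell():
    sites, proteins = _paired_tables([[800.0, 100.0]], [[400.0, np.nan]])
    normalized, _ = normalize_site_to_protein(sites, proteins)
    assert normalized.values.iloc[0, 0] == 1.0
    assert np.isnan(normalized.values.iloc[0, 1])


# ---------------------------------------------------------------------------
# Moderated testing
# ---------------------------------------------------------------------------


def _three_plex_design(conditions=("wildtype", "ko")):
    channel_conditions = [(f"ch{i}", c) for i, c in enumerate(conditions)]
    channel_conditions.append(("chR", "REF"))
    return make_design(["plex1", "plex2", "plex3"], channel_conditions)


def _log2_table(values, design):
    plexes = design.plexes
    channels = design.channels(plexes[0])
    return make_feature_table(values, plexes, channels, log_space=True)


def test_constant_table_gives_zero_fc_and_p_one():
    design = _three_plex_design()
    vals = np.full((10, 9), 5.0)
    res, params = (
        lambda t: (t.results_, t.params_)
    )(ModeratedTester(design).fit(_log2_table(vals, design)))
    assert np.allclose(res["log2fc"], 0.0)
    assert np.allclose(res["t_mod"], 0.0)
    assert np.allclose(res["p"], 1.0)


def ordinary_t_oracle(table_vals, design):
    """Brute-force per-feature pooled-variance t for condition vs baseline."""
    conds = [c for c in design.conditions]
    plexes = design.plexes
    channels = design.channels(plexes[0])
    col_of = {(p, c): i for i, (p, c) in enumerate(
        [(p, c) for p in plexes for c in channels])}
    out = []
    for row in table_vals:
        groups = {}
        for cond in conds:
            cols = [col_of[pc] for pc in design.columns_for(cond)]
            groups[cond] = np.array([row[i] for i in cols])
        n = sum(len(g) for g in groups.values())
        g = len(groups)
        ss = sum(((x - x.mean()) ** 2).sum() for x in groups.values())
        s2 = ss / (n - g)
        num, den = groups["ko"], groups["wildtype"]
        fc = num.mean() - den.mean()
        t = fc / np.sqrt(s2 * (1 / len(num) + 1 / len(den)))
        p = 2 * stats.t.sf(abs(t), n - g)
        out.append((fc, t, p))
    return np.array(out)


def test_prior_df_zero_equals_ordinary_pooled_t():
    rng = np.random.default_rng(7)
    design = _three_plex_design(("wildtype", "ko", "other"))
    vals = rng.normal(8, 0.5, size=(50, 12))
    res = (
        ModeratedTester(design, contrasts=[ContrastSpec("ko")], prior_df=0)
        .fit(_log2_table(vals, design))
        .results_
    )
    oracle = ordinary_t_oracle(vals, design)
    np.testing.assert_allclose(res["log2fc"], oracle[:, 0], rtol=1e-10)
    np.testing.assert_allclose(res["t_mod"], oracle[:, 1], rtol=1e-10)
    np.testing.assert_allclose(res["p"], oracle[:, 2], rtol=1e-10)


def test_completeness_rule_marks_untested():
    design = _three_plex_design()
    vals = np.random.default_rng(1).normal(5, 0.1, (3, 9))
    vals[0, 0] = np.nan  # wildtype replicate missing in plex1
    res = ModeratedTester(design).fit(_log2_table(vals, design)).results_
    by_feat = res.set_index("feature_id")["call"]
    ids = list(_log2_table(vals, design).feature_ids)
    assert by_feat[ids[0]] == "untested"
    assert (by_feat[ids[1:]] != "untested").all()


def test_shrinkage_interpolates_between_feature_and_prior_variance():
    rng = np.random.default_rng(3)
    design = _three_plex_design(("wildtype", "ko", "x", "y", "z"))
    # heterogeneous per-feature noise so the prior df stays finite
    sd = np.sqrt(4 * 0.04 / stats.chi2.rvs(4, size=300, random_state=rng))
    vals = rng.normal(0, 1, size=(300, 18)) * sd[:, None]
    tester = ModeratedTester(design).fit(_log2_table(vals, design))
    p = tester.params_
    lo = np.minimum(p.s_sq, p.s0_sq)
    hi = np.maximum(p.s_sq, p.s0_sq)
    assert ((p.s_tilde_sq >= lo - 1e-15) & (p.s_tilde_sq <= hi + 1e-15)).all()
    # identity of the posterior variance
    recon = (p.d0 * p.s0_sq + p.df_resid * p.s_sq) / (p.d0 + p.df_resid)
    np.testing.assert_allclose(p.s_tilde_sq, recon, rtol=1e-12)


def test_t_increases_with_effect_and_p_decreases_with_t():
    design = _three_plex_design()
    effects = [0.0, 0.25, 0.5, 1.0, 2.0]
    base = np.zeros((len(effects), 9))
    rep_jitter = [-0.1, 0.0, 0.1]  # identical replicate spread per feature
    for i, e in enumerate(effects):
        for p_idx in range(3):
            base[i, p_idx * 3 + 0] = rep_jitter[p_idx]
            base[i, p_idx * 3 + 1] = e + rep_jitter[p_idx]
    res = (
        ModeratedTester(design).fit(_log2_table(base, design)).results_
        .set_index("feature_id")
    )
    ids = list(_log2_table(base, design).feature_ids)
    tvals = res.loc[ids, "t_mod"].to_numpy()
    pvals = res.loc[ids, "p"].to_numpy()
    assert (np.diff(np.abs(tvals)) > 0).all()
    assert (np.diff(pvals) < 0).all()


def test_variance_prior_recovery_from_scaled_inv_chisq():
    rng = np.random.default_rng(11)
    d0_true, s0_true, d, n = 4.0, 0.04, 16, 10_000
    sigma2 = d0_true * s0_true / stats.chi2.rvs(d0_true, size=n, random_state=rng)
    s2 = sigma2 * stats.chi2.rvs(d, size=n, random_state=rng) / d
    d0_hat, s0_hat = estimate_variance_prior(s2, np.full(n, d))
    assert abs(d0_hat - d0_true) < 1.0
    assert abs(s0_hat - s0_true) / s0_true < 0.2


def _injected_effect_results(effect, seed=13, n_tp=500, n_null=1500):
    """Spike `effect` into 500 features at CV 10%, n = 3/arm; return their rows."""
    rng = np.random.default_rng(seed)
    design = _three_plex_design(("wildtype", "ko"))
    sd = 0.1 / np.log(2)
    vals = rng.normal(0.0, sd, size=(n_tp + n_null, 9))
    for p_idx in range(3):
        vals[:n_tp, p_idx * 3 + 1] += effect
    table = _log2_table(vals, design)
    res = ModeratedTester(design).fit(table).results_.set_index("feature_id")
    return res.loc[list(table.feature_ids)[:n_tp]]


def test_effect_estimate_is_unbiased_at_the_fold_change_threshold():
    effect = np.log2(1.5)
    tp = _injected_effect_results(effect)
    assert abs(tp["log2fc"].mean() - effect) < 0.1
    # the significance component alone is well powered even at the boundary
    assert (tp["padj"] <= 0.05).mean() >= 0.9


def test_sensitivity_at_regulated_call_rule_for_twofold_effects():
    """2-fold effects (the low edge of the regulated regime) at CV 10%."""
    tp = _injected_effect_results(effect=1.0)
    assert (tp["call"] == "up").mean() >= 0.9


# ---------------------------------------------------------------------------
# BH adjustment and calls
# ---------------------------------------------------------------------------


def bh_brute_force(p):
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    padj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        padj[i] = prev
    return padj


def test_bh_matches_brute_force_on_random_vectors():
    rng = np.random.default_rng(5)
    for _ in range(200):
        m = rng.integers(1, 40)
        p = rng.uniform(size=m) ** rng.uniform(0.5, 3)
        np.testing.assert_allclose(
            adjust_bh_pvalues(p), bh_brute_force(p), rtol=1e-12
        )


@pytest.mark.parametrize(
    "p, expected",
    [
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([0.04], [0.04]),
        ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
    ],
)
def test_bh_worked_examples(p, expected):
    np.testing.assert_allclose(adjust_bh_pvalues(p), expected, rtol=1e-12)


def test_bh_adjusts_within_contrast_families_and_propagates_nan():
    df = pd.DataFrame(
        {
            "feature_id": ["a", "b", "a", "b"],
            "contrast": ["c1", "c1", "c2", "c2"],
            "p": [0.01, 0.02, 0.05, np.nan],
        }
    )
    with pytest.warns(UserWarning, match="NaN"):
        out = adjust_bh(df)
    np.testing.assert_allclose(
        out.loc[out["contrast"] == "c1", "padj"], [0.02, 0.02]
    )
    c2 = out[out["contrast"] == "c2"]
    assert c2["padj"].iloc[0] == pytest.approx(0.05)  # m = 1 in its family
    assert np.isnan(c2["padj"].iloc[1])
    assert (out["padj"].dropna() >= out["p"].dropna() - 1e-15).all()


@pytest.mark.parametrize(
    "log2fc, padj, expected",
    [
        (np.log2(1.5), 0.05, "up"),  # thresholds inclusive on both sides
        (0.50, 0.001, "ns"),  # 1.41-fold < 1.5
        (-1.2, 0.004, "down"),
        (np.log2(1.5) - 1e-9, 0.05, "ns"),
        (2.0, 0.051, "ns"),
    ],
)
def test_regulated_call_thresholds(log2fc, padj, expected):
    df = pd.DataFrame(
        {"feature_id": ["x"], "contrast": ["c"], "log2fc": [log2fc],
         "t_mod": [1.0], "p": [padj], "padj": [padj], "n_used": [3],
         "call": ["ns"]}
    )
    assert call_regulated(df)["call"].iloc[0] == expected


def test_untested_rows_keep_their_call():
    df = pd.DataFrame(
        {"feature_id": ["x"], "contrast": ["c"], "log2fc": [np.nan],
         "t_mod": [np.nan], "p": [np.nan], "padj": [np.nan], "n_used": [1],
         "call": ["untested"]}
    )
    assert call_regulated(df)["call"].iloc[0] == "untested"
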