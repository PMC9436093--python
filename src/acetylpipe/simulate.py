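"""Synthetic multiplexed-acetylome and PRM experiments with known truth.

The generator emulates the study design end to end: three biological
replicates, each one TMTpro 16-plex carrying 15 experimental conditions
(wildtype, two MS-275 time points, catalytically-inactive HDAC1/2/3/8
mutants in wildtype and knockout backgrounds, and the straight knockouts)
plus a pooled reference (REF) channel shared across plexes.  Sites on
planted substrate proteins receive class-specific log2 effects (HDAC1/2,
HDAC3 or shared), MS-275 responses mirror the genetic classes with
configurable coverage, and the observed intensities pass through plex
batch effects, channel loading, log-normal noise, reporter-ion isotope
impurity mixing and intensity-dependent missingness — so every pipeline
stage has something real to undo, and the :class:`GroundTruth` record says
exactly what it should recover.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import FeatureTable, ImpurityMatrix, IntegrityError, PlexDesign
from .prm import PRM_COLUMNS

__all__ = [
    "DEFAULT_CHANNEL_CONDITIONS",
    "PRINTED_TWELVEPLEX",
    "SimConfig",
    "PRMSimConfig",
    "GroundTruth",
    "PRMGroundTruth",
    "default_design",
    "printed_twelveplex_design",
    "default_impurity",
    "simulate_experiment",
    "simulate_prm",
    "recovery_metrics",
]

# Full 16-plex assignment: the 12 printed labels of the study plus the four
# KO-background CI clones on the otherwise free N channels (15 experimental
# conditions + REF).
DEFAULT_CHANNEL_CONDITIONS: tuple = (
    ("126C", "wildtype"),
    ("127N", "KO_HDAC1_CI"),
    ("127C", "MS275_6h"),
    ("128N", "KO_HDAC2_CI"),
    ("128C", "MS275_24h"),
    ("129N", "KO_HDAC3_CI"),
    ("129C", "WT_HDAC1_CI"),
    ("130N", "KO_HDAC8_CI"),
    ("130C", "WT_HDAC2_CI"),
    ("131N", "HDAC1_KO"),
    ("131C", "WT_HDAC3_CI"),
    ("132N", "HDAC2_KO"),
    ("132C", "WT_HDAC8_CI"),
    ("133N", "HDAC3_KO"),
    ("133C", "REF"),
    ("134N", "HDAC8_KO"),
)

#: The 12-label assignment exactly as printed in the labeling protocol.
PRINTED_TWELVEPLEX: tuple = (
    ("126C", "wildtype"),
    ("127C", "MS275_6h"),
    ("128C", "MS275_24h"),
    ("129C", "WT_HDAC1_CI"),
    ("130C", "WT_HDAC2_CI"),
    ("131N", "HDAC1_KO"),
    ("131C", "WT_HDAC3_CI"),
    ("132N", "HDAC2_KO"),
    ("132C", "WT_HDAC8_CI"),
    ("133N", "HDAC3_KO"),
    ("133C", "REF"),
    ("134N", "HDAC8_KO"),
)

HDAC12_EFFECT_CONDITIONS = ("WT_HDAC1_CI", "KO_HDAC1_CI", "WT_HDAC2_CI", "KO_HDAC2_CI")
HDAC3_CI_CONDITIONS = ("WT_HDAC3_CI", "KO_HDAC3_CI")


def _design_from(channel_conditions, n_plexes: int, ref_condition="REF") -> PlexDesign:
    rows = []
    for p in range(1, n_plexes + 1):
        plex = f"plex{p}"
        for channel, cond in channel_conditions:
            rows.append(
                {
                    "plex": plex,
                    "channel": channel,
                    "condition": cond,
                    "replicate": p,
                    "is_reference": cond == ref_condition,
                }
            )
    return PlexDesign(pd.DataFrame(rows))


def default_design(n_plexes: int = 3) -> PlexDesign:
    """The 16-channel, 15-condition design, one replicate per plex."""
    return _design_from(DEFAULT_CHANNEL_CONDITIONS, n_plexes)


def printed_twelveplex_design(n_plexes: int = 3) -> PlexDesign:
    """The 12 printed channel assignments (REF on 133C)."""
    return _design_from(PRINTED_TWELVEPLEX, n_plexes)


def default_impurity(labels) -> ImpurityMatrix:
    """Mild lot-sheet-style contamination along the label ladder.

    1% into the -1 neighbour, 3% into +1, 0.1% into +2 for every label —
    the magnitudes typical of TMT reagent certificates.
    """
    labels = list(labels)
    n = len(labels)
    A = np.zeros((n, n))
    offsets = {-1: 0.01, +1: 0.03, +2: 0.001}
    for j in range(n):
        total = sum(offsets.values())
        A[j, j] = 1.0 - total
        for off, frac in offsets.items():
            i = j + off
            if 0 <= i < n:
                A[i, j] = frac
    return ImpurityMatrix(labels, A)


@dataclass
class SimConfig:
    """Parameters of a synthetic multiplexed acetylome experiment.

    Defaults reproduce a desk-scale version of the study: 3 plexes of 16
    channels, ~1,000 proteins carrying ~3,000 acetyl sites, strong planted
    substrate effects (4- to 90-fold), 10% CV measurement noise, moderate
    plex batch and channel loading effects, realistic reporter impurity
    and intensity-dependent missingness.
    """

    seed: int
    n_plexes: int = 3
    channel_conditions: tuple = DEFAULT_CHANNEL_CONDITIONS
    baseline: str = "wildtype"

    n_proteins: int = 1000
    mean_extra_sites: float = 2.0  # sites/protein = 1 + Poisson(this)

    n_hdac12_substrates: int = 40
    n_hdac3_substrates: int = 25
    n_shared_substrates: int = 15
    hdac3_ko_coverage: float = 0.8  # fraction of HDAC3 substrates also up in the KO
    ms275_6h_hdac12_coverage: float = 0.82
    ms275_6h_hdac3_coverage: float = 0.32
    ms275_24h_coverage: float = 1.0
    effect_log2_range: tuple = (2.0, math.log2(90.0))

    n_diff_proteins: int = 50  # protein-abundance (not acetylation) changes
    protein_effect_log2: float = 1.0

    protein_mu: float = 20.0  # log2 intensity scale of protein signal
    protein_sd: float = 1.5
    site_offset_mu: float = -2.0
    site_offset_sd: float = 1.0

    cv: float = 0.1  # measurement coefficient of variation
    plex_batch_sd: float = 0.5  # log2, per (feature, plex)
    channel_loading_sd: float = 0.2  # log2, per (plex, channel)
    missing_midpoint: float = 12.0  # log2 intensity of 50% dropout
    missing_scale: float = 1.0  # logistic width; <= 0 disables missingness
    impurity: str | ImpurityMatrix | None = "default"  # or "identity"/None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("SimConfig.seed is mandatory")
        for name in ("hdac3_ko_coverage", "ms275_6h_hdac12_coverage",
                     "ms275_6h_hdac3_coverage", "ms275_24h_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("cv", "plex_batch_sd", "channel_loading_sd", "protein_sd",
                     "site_offset_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def paper_scale(cls, seed: int, **overrides) -> "SimConfig":
        """Approximate the study's quantified scale (~6,600 proteins, ~13,000 sites)."""
        return cls(seed=seed, n_proteins=6627, mean_extra_sites=1.0, **overrides)

    def with_(self, **overrides) -> "SimConfig":
        return replace(self, **overrides)

    @property
    def noise_sd_log2(self) -> float:
        # first-order lognormal: sd of log2 intensity from the CV
        return self.cv / math.log(2)


@dataclass
class GroundTruth:
    """What the generator planted, for recovery scoring."""

    site_effects: pd.DataFrame  # site x condition, true log2 acetylation effect
    site_class: pd.Series  # site -> HDAC1/2 | HDAC3 | HDAC1/2/3 | none
    protein_effects: pd.DataFrame  # protein x condition, true log2 abundance effect
    protein_hyper: pd.DataFrame  # protein x condition, bool
    channel_loading: dict  # (plex, channel) -> log2 loading offset
    protein_of: pd.Series  # site -> protein_group

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        self.site_effects.to_csv(outdir / "truth_site_effects.tsv", sep="\t",
                                 index_label="feature_id")
        self.site_class.rename("class_label").to_csv(
            outdir / "truth_site_class.tsv", sep="\t", index_label="feature_id"
        )
        self.protein_effects.to_csv(outdir / "truth_protein_effects.tsv", sep="\t",
                                    index_label="protein_group")
        with open(outdir / "truth_channel_loading.json", "w") as fh:
            json.dump({f"{p}|{c}": v for (p, c), v in self.channel_loading.items()}, fh)

    @classmethod
    def read(cls, outdir) -> "GroundTruth":
        outdir = Path(outdir)
        eff = pd.read_csv(outdir / "truth_site_effects.tsv", sep="\t",
                          index_col="feature_id")
        cls_ = pd.read_csv(outdir / "truth_site_class.tsv", sep="\t",
                           index_col="feature_id")["class_label"]
        peff = pd.read_csv(outdir / "truth_protein_effects.tsv", sep="\t",
                           index_col="protein_group")
        with open(outdir / "truth_channel_loading.json") as fh:
            loading = {tuple(k.split("|")): v for k, v in json.load(fh).items()}
        protein_of = pd.Series(
            [f.split("_K")[0].replace("G", "P", 1) for f in eff.index], index=eff.index
        )
        hyper = (eff > 0).groupby(protein_of).any()
        return cls(eff, cls_, peff, hyper, loading, protein_of)


def _exact_subset(rng, items: np.ndarray, fraction: float) -> np.ndarray:
    """A uniformly drawn subset of exactly round(fraction * n) items."""
    k = int(round(fraction * len(items)))
    if k >= len(items):
        return items
    return rng.choice(items, size=k, replace=False)


def simulate_experiment(
    config: SimConfig,
) -> tuple[FeatureTable, FeatureTable, PlexDesign, GroundTruth]:
    """Generate (site table, protein table, design, truth), deterministic in the seed.

    Generative model (all in log2 space until the reporter stage):
    protein abundance ~ N(mu_p, sd_p^2); site signal = protein + site offset
    + acetylation effect + plex batch + channel loading + noise; REF is the
    in-silico pool (log-space mean) of the condition channels of its plex;
    intensities are then linearized, mixed through the impurity matrix per
    (feature, plex), and thinned by logistic intensity-dependent dropout.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    design = _design_from(cfg.channel_conditions, cfg.n_plexes)
    conditions = [c for _, c in cfg.channel_conditions if c != "REF"]

    # --- proteins, sites, classes -----------------------------------------
    protein_ids = np.array([f"P{i:05d}" for i in range(cfg.n_proteins)])
    n_sub = cfg.n_hdac12_substrates + cfg.n_hdac3_substrates + cfg.n_shared_substrates
    if n_sub + cfg.n_diff_proteins > cfg.n_proteins:
        raise ValueError("more substrate/DE proteins requested than proteins")
    perm = rng.permutation(cfg.n_proteins)
    idx12 = perm[: cfg.n_hdac12_substrates]
    idx3 = perm[cfg.n_hdac12_substrates : cfg.n_hdac12_substrates + cfg.n_hdac3_substrates]
    idxsh = perm[cfg.n_hdac12_substrates + cfg.n_hdac3_substrates : n_sub]
    idxde = perm[n_sub : n_sub + cfg.n_diff_proteins]

    protein_class = pd.Series("none", index=protein_ids)
    protein_class.iloc[idx12] = "HDAC1/2"
    protein_class.iloc[idx3] = "HDAC3"
    protein_class.iloc[idxsh] = "HDAC1/2/3"

    n_sites_per = 1 + rng.poisson(cfg.mean_extra_sites, size=cfg.n_proteins)
    site_rows = []
    for i, pid in enumerate(protein_ids):
        positions = np.sort(rng.choice(np.arange(2, 900), size=n_sites_per[i],
                                       replace=False))
        for pos in positions:
            mult = rng.choice([1, 2, 3], p=[0.7, 0.2, 0.1])
            site_rows.append((f"{pid.replace('P', 'G', 1)}_K{pos}_m{mult}", pid,
                              int(pos), int(mult)))
    site_meta = pd.DataFrame(
        site_rows, columns=["feature_id", "protein_group", "site_position",
                            "multiplicity"]
    ).set_index("feature_id")
    site_ids = site_meta.index.to_numpy()
    n_sites = len(site_ids)
    site_protein = site_meta["protein_group"]

    # --- planted effects ---------------------------------------------------
    lo, hi = cfg.effect_log2_range
    site_effects = pd.DataFrame(0.0, index=site_meta.index, columns=conditions)
    site_class = protein_class.reindex(site_protein.values)
    site_class.index = site_meta.index
    magnitude = rng.uniform(lo, hi, size=n_sites)

    def _plant(mask_ids, conds):
        for c in conds:
            site_effects.loc[mask_ids, c] = magnitude[
                site_meta.index.get_indexer(mask_ids)
            ]

    ids12 = site_meta.index[site_class.values == "HDAC1/2"].to_numpy()
    ids3 = site_meta.index[site_class.values == "HDAC3"].to_numpy()
    idssh = site_meta.index[site_class.values == "HDAC1/2/3"].to_numpy()
    _plant(ids12, HDAC12_EFFECT_CONDITIONS)
    _plant(ids3, HDAC3_CI_CONDITIONS)
    _plant(idssh, HDAC12_EFFECT_CONDITIONS + HDAC3_CI_CONDITIONS + ("HDAC3_KO",))

    # KO coverage: an exact-count protein subset of the HDAC3 substrates
    prot3 = protein_ids[idx3]
    prot3_ko = set(_exact_subset(rng, prot3, cfg.hdac3_ko_coverage))
    ids3_ko = ids3[[site_protein[s] in prot3_ko for s in ids3]]
    _plant(ids3_ko, ("HDAC3_KO",))

    # MS-275 mirrors the genetic classes with class-specific coverage
    if "MS275_6h" in conditions:
        p12 = set(_exact_subset(rng, protein_ids[idx12], cfg.ms275_6h_hdac12_coverage))
        p3 = set(_exact_subset(rng, prot3, cfg.ms275_6h_hdac3_coverage))
        psh = set(_exact_subset(rng, protein_ids[idxsh], cfg.ms275_6h_hdac12_coverage))
        ids_6h = site_meta.index[
            [site_protein[s] in (p12 | p3 | psh) for s in site_meta.index]
        ].to_numpy()
        _plant(ids_6h, ("MS275_6h",))
    if "MS275_24h" in conditions:
        all_sub = set(protein_ids[perm[:n_sub]])
        p24 = set(_exact_subset(rng, np.array(sorted(all_sub)), cfg.ms275_24h_coverage))
        ids_24h = site_meta.index[
            [site_protein[s] in p24 for s in site_meta.index]
        ].to_numpy()
        _plant(ids_24h, ("MS275_24h",))

    protein_effects = pd.DataFrame(0.0, index=protein_ids, columns=conditions)
    de_conds = rng.choice([c for c in conditions if c != cfg.baseline],
                          size=len(idxde))
    for i, cond in zip(idxde, de_conds):
        protein_effects.iloc[i, protein_effects.columns.get_loc(cond)] = (
            cfg.protein_effect_log2
        )

    # --- base abundances and nuisance effects ------------------------------
    protein_log2 = rng.normal(cfg.protein_mu, cfg.protein_sd, size=cfg.n_proteins)
    protein_log2 = pd.Series(protein_log2, index=protein_ids)
    site_offset = rng.normal(cfg.site_offset_mu, cfg.site_offset_sd, size=n_sites)

    plexes = design.plexes
    loading = {
        (p, ch): float(rng.normal(0.0, cfg.channel_loading_sd))
        for p in plexes
        for ch, _ in cfg.channel_conditions
    }
    batch_sites = rng.normal(0.0, cfg.plex_batch_sd, size=(n_sites, len(plexes)))
    batch_prot = rng.normal(0.0, cfg.plex_batch_sd, size=(cfg.n_proteins, len(plexes)))

    if cfg.impurity == "default":
        imp = default_impurity([ch for ch, _ in cfg.channel_conditions])
    elif cfg.impurity in ("identity", None):
        imp = ImpurityMatrix.identity([ch for ch, _ in cfg.channel_conditions])
    else:
        imp = cfg.impurity

    sd = cfg.noise_sd_log2

    def _assemble(feature_base, effects, batch, index, rng):
        """Build the observed linear-intensity matrix for one table."""
        channels = [ch for ch, _ in cfg.channel_conditions]
        cond_of = dict(cfg.channel_conditions)
        cols = pd.MultiIndex.from_tuples(
            [(p, ch) for p in plexes for ch in channels], names=["plex", "channel"]
        )
        nf = len(index)
        log2sig = np.empty((nf, len(cols)))
        for pi, p in enumerate(plexes):
            block = np.empty((nf, len(channels)))
            cond_cols = []
            for ci, ch in enumerate(channels):
                cond = cond_of[ch]
                if cond == "REF":
                    block[:, ci] = 0.0  # filled after pooling
                    ref_ci = ci
                    continue
                noise = rng.normal(0.0, sd, size=nf) if sd > 0 else 0.0
                block[:, ci] = (
                    feature_base
                    + effects[cond].to_numpy()
                    + batch[:, pi]
                    + noise
                )
                cond_cols.append(ci)
            block[:, ref_ci] = block[:, cond_cols].mean(axis=1)  # in-silico pool
            for ci, ch in enumerate(channels):
                block[:, ci] += loading[(p, ch)]
            log2sig[:, pi * len(channels) : (pi + 1) * len(channels)] = block
        linear = np.power(2.0, log2sig)
        # reporter-ion impurity mixing, per plex
        for pi, p in enumerate(plexes):
            sl = slice(pi * len(channels), (pi + 1) * len(channels))
            A = imp.submatrix(channels)
            linear[:, sl] = linear[:, sl] @ A.T
        # intensity-dependent dropout
        if cfg.missing_scale > 0:
            with np.errstate(divide="ignore"):
                logv = np.log2(linear)
            p_miss = 1.0 / (1.0 + np.exp((logv - cfg.missing_midpoint) / cfg.missing_scale))
            drop = rng.uniform(size=linear.shape) < p_miss
            linear[drop] = np.nan
        return pd.DataFrame(linear, index=index, columns=cols)

    site_effect_total = site_effects.add(
        protein_effects.reindex(site_protein.values).set_axis(site_meta.index), fill_value=0.0
    )
    site_base = protein_log2.reindex(site_protein.values).to_numpy() + site_offset
    site_values = _assemble(site_base, site_effect_total, batch_sites,
                            site_meta.index, rng)
    prot_values = _assemble(protein_log2.to_numpy(), protein_effects, batch_prot,
                            pd.Index(protein_ids, name="feature_id"), rng)

    sites = FeatureTable(site_values, site_meta, level="site", log_space=False)
    prot_meta = pd.DataFrame(
        {"protein_group": protein_ids}, index=pd.Index(protein_ids, name="feature_id")
    )
    proteins = FeatureTable(prot_values, prot_meta, level="protein", log_space=False)

    hyper = (site_effects > 0).groupby(site_protein).any()
    hyper = hyper.reindex(protein_ids, fill_value=False)
    truth = GroundTruth(
        site_effects=site_effects,
        site_class=site_class,
        protein_effects=protein_effects,
        protein_hyper=hyper,
        channel_loading=loading,
        protein_of=site_protein,
    )
    return sites, proteins, design, truth


# ---------------------------------------------------------------------------
# PRM simulation
# ---------------------------------------------------------------------------


@dataclass
class PRMSimConfig:
    """Synthetic PRM validation experiment: mock plus an MS-275 time course.

    Defaults mirror the validation arm: 34 acetylated histone peptides,
    18 unmodified normalizers, 4 replicate runs per group, responses
    ramping from mild at 2 h to 20-90-fold at 24 h.
    """

    seed: int
    n_modified: int = 34
    n_unmodified: int = 18
    groups: tuple = ("mock", "2h", "6h", "24h")
    n_reps: int = 4
    fold_ranges: dict = field(
        default_factory=lambda: {"2h": (1.2, 2.0), "6h": (4.0, 20.0),
                                 "24h": (20.0, 90.0)}
    )
    cv: float = 0.1
    loading_sd: float = 0.3  # natural-log sd of per-sample loading
    base_area_log10_mu: float = 6.0
    base_area_log10_sd: float = 0.5
    two_charge_fraction: float = 0.4

    def with_(self, **overrides) -> "PRMSimConfig":
        return replace(self, **overrides)


@dataclass
class PRMGroundTruth:
    fold: pd.DataFrame  # peptide x group true fold over mock
    loading: pd.Series  # sample -> multiplicative loading factor
    is_modified: pd.Series


def simulate_prm(config: PRMSimConfig) -> tuple[pd.DataFrame, PRMGroundTruth]:
    """Generate a long-format PRM transition table plus its ground truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    peptides = [f"ac_pep{i:02d}" for i in range(cfg.n_modified)] + [
        f"norm_pep{i:02d}" for i in range(cfg.n_unmodified)
    ]
    is_mod = pd.Series(
        [True] * cfg.n_modified + [False] * cfg.n_unmodified, index=peptides
    )
    samples = [(f"{g}_{r+1}", g) for g in cfg.groups for r in range(cfg.n_reps)]
    loading = pd.Series(
        np.exp(rng.normal(0.0, cfg.loading_sd, size=len(samples))),
        index=[s for s, _ in samples],
    )

    fold = pd.DataFrame(1.0, index=peptides, columns=list(cfg.groups))
    for g in cfg.groups:
        if g in cfg.fold_ranges:
            lo, hi = cfg.fold_ranges[g]
            fold.loc[is_mod, g] = rng.uniform(lo, hi, size=cfg.n_modified)

    base = np.power(10.0, rng.normal(cfg.base_area_log10_mu, cfg.base_area_log10_sd,
                                     size=len(peptides)))
    n_charges = np.where(rng.uniform(size=len(peptides)) < cfg.two_charge_fraction, 2, 1)

    rows = []
    for pi, pep in enumerate(peptides):
        charge_split = rng.dirichlet([5.0] * n_charges[pi])
        trans_splits = [rng.dirichlet([5.0, 5.0, 5.0]) for _ in range(n_charges[pi])]
        for sample_id, group in samples:
            noise = np.exp(rng.normal(0.0, cfg.cv)) if cfg.cv > 0 else 1.0
            total = base[pi] * fold.loc[pep, group] * loading[sample_id] * noise
            for ci in range(n_charges[pi]):
                for ti in range(3):
                    rows.append(
                        {
                            "peptide_id": pep,
                            "charge": 2 + ci,
                            "transition_id": f"y{ti + 3}",
                            "sample_id": sample_id,
                            "area": total * charge_split[ci] * trans_splits[ci][ti],
                            "is_modified": bool(is_mod[pep]),
                            "sample_group": group,
                        }
                    )
    table = pd.DataFrame(rows, columns=PRM_COLUMNS)
    return table, PRMGroundTruth(fold=fold, loading=loading, is_modified=is_mod)


# ---------------------------------------------------------------------------
# Recovery metrics
# ---------------------------------------------------------------------------


def recovery_metrics(
    results: pd.DataFrame,
    truth: GroundTruth,
    classes: pd.DataFrame | None = None,
) -> dict:
    """Score calls and class labels against the planted truth.

    Returns sensitivity/specificity/observed FDR of up-calls (untested
    features count as not called), log2fc bias and RMSE over true
    positives, and — when ``classes`` is given — the class confusion
    matrix and the fraction of planted substrates correctly labelled.
    """
    res = results.copy()
    res["condition"] = res["contrast"].str.rsplit("_vs_", n=1).str[0]
    unknown = set(res["feature_id"]) - set(truth.site_effects.index)
    if unknown:
        raise IntegrityError(
            f"{len(unknown)} result feature(s) absent from ground truth, "
            f"e.g. {sorted(unknown)[0]!r}"
        )
    res = res[res["condition"].isin(truth.site_effects.columns)]
    true_eff = truth.site_effects.stack()
    key = pd.MultiIndex.from_arrays([res["feature_id"], res["condition"]])
    res["true_log2"] = true_eff.reindex(key).to_numpy()

    pos = res["true_log2"] > 0
    called_up = res["call"] == "up"
    tp = int((pos & called_up).sum())
    fp = int((~pos & called_up).sum())
    fn = int((pos & ~called_up).sum())
    tn = int((~pos & ~called_up).sum())
    out = {
        "n_feature_contrasts": len(res),
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "fdr": fp / (tp + fp) if tp + fp else 0.0,
    }
    tested_pos = pos & res["log2fc"].notna()
    if tested_pos.any():
        err = res.loc[tested_pos, "log2fc"] - res.loc[tested_pos, "true_log2"]
        out["log2fc_bias"] = float(err.mean())
        out["log2fc_rmse"] = float(np.sqrt((err**2).mean()))
    if classes is not None:
        merged = classes.set_index("feature_id")["class_label"]
        planted = truth.site_class[truth.site_class != "none"]
        common = planted.index.intersection(merged.index)
        agree = (merged.reindex(common) == planted.reindex(common))
        out["class_accuracy"] = float(agree.mean()) if len(common) else float("nan")
        out["class_confusion"] = (
            pd.crosstab(planted.reindex(common), merged.reindex(common))
            .to_dict()
        )
    return out
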