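"""HDAC substrate summaries built from regulated-site calls.

These operations turn per-contrast up/down calls into the biological
summaries of the study design: which proteins are hyperacetylated in a
condition, which features respond to an HDAC isoform independently of the
genetic background (confident substrates), how strongly inhibitor-treated
profiles overlap genetic inactivation, and whether a feature is an
HDAC1/2-, HDAC3- or shared (HDAC1/2/3) preferential substrate.

Conventions:

* a *hyperacetylated protein* carries at least one significantly up-called
  site in the condition;
* a *confident substrate* of an isoform is up in the catalytically
  inactive (CI) mutant in both the wildtype and the knockout background;
* preferential classes are genotype-driven — inhibitor (MS-275)
  conditions contribute to overlap statistics but never to classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SubstrateCall",
    "ConditionScheme",
    "DEFAULT_SCHEME",
    "up_feature_sets",
    "hyperacetylated_proteins",
    "confident_substrates",
    "overlap_fraction",
    "classify_preferential",
    "export_class_matrix",
]

CLASS_ORDER = ["HDAC1/2", "HDAC3", "HDAC1/2/3"]


@dataclass(frozen=True)
class ConditionScheme:
    """Names the condition groups driving substrate classification."""

    hdac12_conditions: tuple = (
        "WT_HDAC1_CI",
        "KO_HDAC1_CI",
        "WT_HDAC2_CI",
        "KO_HDAC2_CI",
        "HDAC1_KO",
        "HDAC2_KO",
    )
    hdac3_conditions: tuple = ("WT_HDAC3_CI", "KO_HDAC3_CI", "HDAC3_KO")

    def ci_conditions(self, isoform: str) -> tuple[str, str]:
        return (f"WT_{isoform}_CI", f"KO_{isoform}_CI")

    def ko_condition(self, isoform: str) -> str:
        return f"{isoform}_KO"


DEFAULT_SCHEME = ConditionScheme()


@dataclass
class SubstrateCall:
    """Per-feature preferential-substrate classification."""

    feature_id: str
    class_label: str  # HDAC1/2 | HDAC3 | HDAC1/2/3 | none
    supporting_contrasts: set = field(default_factory=set)
    confident: bool = False


def _condition_of(contrast: str) -> str:
    # contrasts are named "<condition>_vs_<baseline>"
    return contrast.rsplit("_vs_", 1)[0]


def up_feature_sets(results: pd.DataFrame) -> dict[str, set]:
    """Condition -> set of feature_ids with call == 'up'."""
    out: dict[str, set] = {}
    for contrast, grp in results.groupby("contrast"):
        cond = _condition_of(contrast)
        out.setdefault(cond, set()).update(
            grp.loc[grp["call"] == "up", "feature_id"]
        )
    return out


def _lift(features: set, protein_of) -> set:
    if protein_of is None:
        return set(features)
    return {protein_of[f] for f in features if f in protein_of}


def hyperacetylated_proteins(
    results: pd.DataFrame, protein_of, conditions=None
) -> dict[str, set]:
    """Per condition, the proteins owning at least one up-called site.

    ``protein_of`` maps feature_id -> protein_group (e.g. the site table's
    meta column).  Raises KeyError for a requested condition absent from
    the results.
    """
    sets = up_feature_sets(results)
    if conditions is None:
        conditions = list(sets)
    out = {}
    for cond in conditions:
        if cond not in sets:
            raise KeyError(f"condition {cond!r} has no results")
        out[cond] = _lift(sets[cond], protein_of)
    return out


def confident_substrates(
    results: pd.DataFrame,
    isoform: str,
    include_ko: bool = False,
    protein_of=None,
    scheme: ConditionScheme = DEFAULT_SCHEME,
) -> set:
    """Features up in the isoform's CI mutant in BOTH genetic backgrounds.

    With ``include_ko`` the intersection is further restricted to features
    also up in the straight knockout (only meaningful for HDAC3, where the
    KO is viable and profiled).  ``protein_of`` lifts the sets to protein
    level before intersecting.
    """
    sets = up_feature_sets(results)
    needed = list(scheme.ci_conditions(isoform))
    if include_ko:
        needed.append(scheme.ko_condition(isoform))
    missing = [c for c in needed if c not in sets]
    if missing:
        raise LookupError(
            f"confident-substrate call for {isoform} needs contrast(s) for "
            f"condition(s): {', '.join(missing)}"
        )
    lifted = [_lift(sets[c], protein_of) for c in needed]
    return set.intersection(*lifted)


def overlap_fraction(
    reference_set: set,
    target_conditions,
    results: pd.DataFrame,
    protein_of=None,
) -> float:
    """Percent of ``reference_set`` covered by the union of up-sets.

    The level (site vs protein) is set by lifting: pass ``protein_of`` to
    compare protein sets, or leave None for site-level sets.  An empty
    reference has no defined fraction.
    """
    if not reference_set:
        raise ValueError("overlap fraction is undefined for an empty reference set")
    sets = up_feature_sets(results)
    union: set = set()
    for cond in target_conditions:
        if cond not in sets:
            raise KeyError(f"condition {cond!r} has no results")
        union |= _lift(sets[cond], protein_of)
    return 100.0 * len(set(reference_set) & union) / len(reference_set)


def classify_preferential(
    results: pd.DataFrame, scheme: ConditionScheme = DEFAULT_SCHEME
) -> pd.DataFrame:
    """Assign each feature an HDAC1/2 vs HDAC3 preferential-substrate class.

    Up in >= 1 HDAC1 or HDAC2 condition and in no HDAC3 condition ->
    "HDAC1/2"; up in >= 1 HDAC3 condition (CI or KO) and no HDAC1/2
    condition -> "HDAC3"; up in both families -> "HDAC1/2/3"; otherwise
    "none".  Every feature receives exactly one label.  The ``confident``
    flag marks features up in both CI clones of at least one isoform.
    """
    sets = up_feature_sets(results)
    set12 = set().union(*(sets.get(c, set()) for c in scheme.hdac12_conditions))
    set3 = set().union(*(sets.get(c, set()) for c in scheme.hdac3_conditions))
    genotype_conds = list(scheme.hdac12_conditions) + list(scheme.hdac3_conditions)

    confident_feats: set = set()
    for isoform in ("HDAC1", "HDAC2", "HDAC3"):
        wt, ko = scheme.ci_conditions(isoform)
        if wt in sets and ko in sets:
            confident_feats |= sets[wt] & sets[ko]

    rows = []
    for fid in sorted(results["feature_id"].unique()):
        in12, in3 = fid in set12, fid in set3
        if in12 and in3:
            label = "HDAC1/2/3"
        elif in12:
            label = "HDAC1/2"
        elif in3:
            label = "HDAC3"
        else:
            label = "none"
        support = {c for c in genotype_conds if fid in sets.get(c, set())}
        rows.append(
            {
                "feature_id": fid,
                "class_label": label,
                "supporting_contrasts": ",".join(sorted(support)),
                "confident": (fid in confident_feats) and label != "none",
            }
        )
    return pd.DataFrame(rows, columns=["feature_id", "class_label",
                                       "supporting_contrasts", "confident"])


def export_class_matrix(results: pd.DataFrame, classes: pd.DataFrame, path) -> None:
    """Write the plotting-ready log2fc matrix of classified substrates.

    One row per classified feature (class != none), one column per
    condition; rows grouped HDAC1/2, HDAC3, HDAC1/2/3 and sorted by
    feature_id within each group.
    """
    keep = classes[classes["class_label"].isin(CLASS_ORDER)]
    wide = results.pivot_table(
        index="feature_id",
        columns="contrast",
        values="log2fc",
        aggfunc="first",
        dropna=False,
    )
    wide.columns = [_condition_of(c) for c in wide.columns]
    rows = []
    for label in CLASS_ORDER:
        ids = sorted(keep.loc[keep["class_label"] == label, "feature_id"])
        for fid in ids:
            row = {"feature_id": fid, "class_label": label}
            if fid in wide.index:
                row.update(wide.loc[fid].to_dict())
            rows.append(row)
    cols = ["feature_id", "class_label"] + list(wide.columns)
    out = pd.DataFrame(rows, columns=cols)
    for c in wide.columns:
        if c in out.columns:
            out[c] = out[c].map(
                lambda x: "" if pd.isna(x) else f"{float(x):.6g}"
            )
    out.to_csv(path, sep="\t", index=False)
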