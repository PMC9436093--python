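"""Shared fixtures: tiny hand-built tables and designs."""

import numpy as np
import pandas as pd
import pytest

from acetylpipe.tables import FeatureTable, PlexDesign


def make_feature_table(values, plexes, channels, feature_ids=None,
                       protein_groups=None, level="site", log_space=False,
                       meta_extra=None):
    """Build a FeatureTable from a 2-D array; columns = plexes x channels."""
    values = np.asarray(values, dtype=float)
    cols = pd.MultiIndex.from_tuples(
        [(p, c) for p in plexes for c in channels], names=["plex", "channel"]
    )
    if feature_ids is None:
        feature_ids = [f"GENE{i}_K{10 + i}_m1" for i in range(values.shape[0])]
    if protein_groups is None:
        protein_groups = [f"P{i}" for i in range(values.shape[0])]
    meta = pd.DataFrame({"protein_group": protein_groups},
                        index=pd.Index(feature_ids, name="feature_id"))
    if level == "site":
        meta["site_position"] = [10 + i for i in range(values.shape[0])]
        meta["multiplicity"] = 1
    if meta_extra:
        for k, v in meta_extra.items():
            meta[k] = v
    vals = pd.DataFrame(values, index=meta.index, columns=cols)
    return FeatureTable(vals, meta, level=level, log_space=log_space)


def make_design(plexes, channel_conditions, ref_condition="REF",
                baseline="wildtype"):
    rows = []
    for k, plex in enumerate(plexes, start=1):
        for channel, cond in channel_conditions:
            rows.append({"plex": plex, "channel": channel, "condition": cond,
                         "replicate": k,
                         "is_reference": cond == ref_condition})
    return PlexDesign(pd.DataFrame(rows), baseline_condition=baseline)


@pytest.fixture
def two_plex_design():
    """2 plexes x 3 channels: wildtype, one treatment, REF."""
    return make_design(
        ["plex1", "plex2"],
        [("126C", "wildtype"), ("127C", "treated"), ("133C", "REF")],
    )


@pytest.fixture
def results_frame():
    """Small differential-result table with known calls."""
    rows = [
        ("s1", "A_vs_wildtype", 1.2, 5.0, 1e-4, 1e-3, 3, "up"),
        ("s2", "A_vs_wildtype", -1.0, -4.0, 1e-3, 4e-3, 3, "down"),
        ("s3", "A_vs_wildtype", 0.1, 0.5, 0.5, 0.7, 3, "ns"),
        ("s1", "B_vs_wildtype", 0.9, 4.2, 2e-4, 2e-3, 3, "up"),
        ("s3", "B_vs_wildtype", 2.0, 6.0, 1e-5, 3e-4, 3, "up"),
    ]
    return pd.DataFrame(
        rows,
        columns=["feature_id", "contrast", "log2fc", "t_mod", "p", "padj",
                 "n_used", "call"],
    )
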