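"""Loaders for the packaged reference tables.

The package ships small CSV tables for the 38 brain-extract metabolites the
pipeline profiles: assignment windows (literature-inspired chemical shifts,
nudged so windows never overlap), Lorentzian peak templates for the
synthetic-spectrum renderer, a log2 effect-size pattern for the five-group
stroke study design (sham, model and three treatment doses), baseline
concentrations, 166-bit structural-key fingerprints and a curated
biochemical-reaction pair list.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .containers import AssignmentTable

GROUPS = ["sham", "model", "TH", "TM", "TL"]
#: effect-table column -> (group, reference) contrast encoded by the design
CONTRASTS = {
    "model_vs_sham": ("model", "sham"),
    "TH_vs_model": ("TH", "model"),
    "TM_vs_model": ("TM", "model"),
    "TL_vs_model": ("TL", "model"),
}


def _path(name: str):
    return resources.files("metanmr.data").joinpath(name)


def load_assignments() -> AssignmentTable:
    """Metabolite chemical-shift windows (38 metabolites, one window each)."""
    with resources.as_file(_path("assignments.csv")) as p:
        return AssignmentTable.from_csv(p)


def load_peak_templates() -> pd.DataFrame:
    """Peak template table: metabolite, center_ppm, weight, hwhm_ppm."""
    with resources.as_file(_path("peak_templates.csv")) as p:
        return pd.read_csv(p)


def load_effect_pattern() -> pd.DataFrame:
    """Per-metabolite log2 fold-change pattern across the four study contrasts."""
    with resources.as_file(_path("effects.csv")) as p:
        return pd.read_csv(p, index_col="metabolite")


def load_baselines() -> pd.Series:
    """Baseline metabolite concentrations (arbitrary units) in the sham group."""
    with resources.as_file(_path("baselines.csv")) as p:
        df = pd.read_csv(p, index_col="metabolite")
    return df["baseline_mean"]


def load_fingerprints() -> pd.DataFrame:
    """Binary structural-key fingerprints, one row per metabolite.

    Returns a DataFrame of 0/1 integers indexed by metabolite (166 columns).
    """
    with resources.as_file(_path("fingerprints.csv")) as p:
        df = pd.read_csv(p, dtype={"bits": str})
    mat = pd.DataFrame(
        [[int(ch) for ch in bits] for bits in df["bits"]],
        index=df["metabolite"].tolist(),
    )
    return mat

def load_reactions() -> list[tuple[str, str]]:
    """Curated directed biochemical-reaction pairs among the 38 metabolites."""
    with resources.as_file(_path("reactions.csv")) as p:
        df = pd.read_csv(p)
    return [(str(a), str(b)) for a, b in zip(df["from"], df["to"])]


def group_effects() -> pd.DataFrame:
    """Absolute log2 effect of each group relative to sham.

    Chains the per-contrast pattern: treatment groups are expressed versus
    the model group, so their sham-relative effect is the sum of the two
    contrasts. Columns ordered as :data:`GROUPS`.
    """
    pat = load_effect_pattern()
    out = pd.DataFrame(0.0, index=pat.index, columns=GROUPS)
    out["model"] = pat["model_vs_sham"]
    for col, (grp, _) in CONTRASTS.items():
        if grp != "model":
            out[grp] = pat["model_vs_sham"] + pat[col]
    return out
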