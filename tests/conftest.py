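import numpy as np
import pandas as pd
import pytest

from metanmr import synth


def make_two_group_config(
    n_per_group=20,
    p=12,
    effects=None,
    noise_cv=0.1,
    seed=0,
    corr_blocks=None,
    prefix="m",
):
    """Two-group SynthConfig with explicit ground truth (groups A, B).

    ``effects`` maps feature name -> log2 effect in group B relative to A.
    """
    feats = [f"{prefix}{i:02d}" for i in range(p)]
    eff = pd.DataFrame(0.0, index=feats, columns=["A", "B"])
    for met, val in (effects or {}).items():
        eff.loc[met, "B"] = float(val)
    return synth.SynthConfig(
        n_per_group=n_per_group,
        groups=["A", "B"],
        effect_table=eff,
        baseline_means=pd.Series(1.0, index=feats),
        noise_cv=noise_cv,
        corr_blocks=corr_blocks or [],
        seed=seed,
    )


@pytest.fixture(scope="session")
def study_cohort():
    """Small five-group cohort on the packaged 38-metabolite design."""
    cfg = synth.SynthConfig(n_per_group=8, noise_cv=0.1, seed=11)
    return synth.simulate_concentrations(cfg)


@pytest.fixture(scope="session")
def rendered_cohort():
    """Concentrations plus rendered spectra for the preprocessing chain."""
    cfg = synth.SynthConfig(n_per_group=3, noise_cv=0.1, seed=5)
    quant = synth.simulate_concentrations(cfg)
    spectra = synth.render_spectra(quant, points=16384, seed=6)
    return quant, spectra


def brute_force_bh(p):
    """Literal step-up definition, used as the independent oracle."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = np.inf
    for rank_pos in range(m - 1, -1, -1):
        idx = order[rank_pos]
        running_min = min(running_min, p[idx] * m / (rank_pos + 1))
        adj[idx] = min(running_min, 1.0)
    return adj


def brute_force_pearson(x, y):
    """Textbook two-pass Pearson formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))
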