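"""Synthetic multi-group metabolite data with known ground truth.

Two layers are generated. :func:`simulate_concentrations` draws a
samples-by-metabolites concentration matrix for a multi-group design with
injected log2 effect sizes, multiplicative log-normal noise and optional
within-group correlation blocks (a Gaussian copula on log concentrations,
so a Cholesky factor delivers the target pairwise correlation exactly in
the latent space). :func:`render_spectra` then turns concentrations into
1D NMR-like traces as sums of concentration-scaled Lorentzian peaks plus a
reference peak at 0.00 ppm, so the whole preprocessing chain can be tested
against exact ground truth.

The default configuration emulates the five-group brain-extract study the
packaged effect table is patterned on: groups sham / model / TH / TM / TL,
38 named metabolites, and sham-relative log2 effects chained from the design's four
between-group contrasts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import datasets
from .containers import QuantMatrix, Spectrum

__all__ = [
    "SynthConfig",
    "PeakTemplate",
    "default_config",
    "default_templates",
    "simulate_concentrations",
    "render_spectra",
]


@dataclass
class SynthConfig:
    """Ground-truth description of a simulated cohort.

    Parameters
    ----------
    n_per_group : int
        Samples drawn per group.
    groups : list of str
        Ordered group labels; the first is the reference only by convention
        of the effect table (effects are absolute log2 shifts per group).
    effect_table : DataFrame
        Metabolite x group log2 effect relative to the reference group.
    baseline_means : Series
        Reference-group expected concentration per metabolite (> 0).
    noise_cv : float
        Coefficient of variation of the multiplicative log-normal noise.
    corr_blocks : list of (group, metabolites, r)
        Within the named group, all listed metabolites get pairwise latent
        correlation ``r``; blocks in the same group must not share members.
    seed : int
        RNG seed; identical config + seed reproduces outputs bit for bit.
    """

    n_per_group: int = 10
    groups: list[str] = field(default_factory=lambda: list(datasets.GROUPS))
    effect_table: pd.DataFrame | None = None
    baseline_means: pd.Series | None = None
    noise_cv: float = 0.1
    corr_blocks: list[tuple[str, list[str], float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_table is None:
            self.effect_table = datasets.group_effects()[self.groups]
        if self.baseline_means is None:
            self.baseline_means = datasets.load_baselines().reindex(
                self.effect_table.index
            )
        self.validate()

    @property
    def metabolites(self) -> list[str]:
        return list(self.effect_table.index)

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if set(self.effect_table.columns) != set(self.groups):
            raise ValueError("effect_table columns must match groups")
        missing = self.effect_table.index.difference(self.baseline_means.index)
        if len(missing):
            raise ValueError(f"baseline_means missing metabolites: {list(missing)}")
        if (self.baseline_means.reindex(self.effect_table.index) <= 0).any():
            raise ValueError("all baseline means must be > 0")
        mets = set(self.metabolites)
        seen: dict[str, set[str]] = {}
        for grp, members, r in self.corr_blocks:
            if grp not in self.groups:
                raise ValueError(f"corr_block names unknown group {grp!r}")
            if not -1 < r < 1:
                raise ValueError(f"corr_block r must lie in (-1, 1), got {r}")
            if len(members) < 2:
                raise ValueError("corr_block needs at least two metabolites")
            unknown = set(members) - mets
            if unknown:
                raise ValueError(f"corr_block names unknown metabolites {unknown}")
            if seen.setdefault(grp, set()) & set(members):
                raise ValueError(f"overlapping corr_blocks in group {grp!r}")
            seen[grp] |= set(members)


@dataclass
class PeakTemplate:
    """Lorentzian peak positions for one metabolite.

    ``peaks`` is a list of (center ppm, relative area weight, HWHM in ppm);
    weights must sum to 1 so total peak area stays proportional to
    concentration.
    """

    metabolite: str
    peaks: list[tuple[float, float, float]]

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("template needs at least one peak")
        wsum = sum(w for _, w, _ in self.peaks)
        if abs(wsum - 1.0) > 1e-6:
            raise ValueError(
                f"{self.metabolite}: peak weights sum to {wsum}, expected 1"
            )
        if any(h <= 0 for _, _, h in self.peaks):
            raise ValueError(f"{self.metabolite}: HWHM must be > 0")


def default_config(**overrides) -> SynthConfig:
    """The packaged five-group study design and its default effect pattern."""
    return SynthConfig(**overrides)


def default_templates() -> list[PeakTemplate]:
    """Packaged one/two-peak Lorentzian templates for the 38 metabolites."""
    df = datasets.load_peak_templates()
    out = []
    for met, sub in df.groupby("metabolite", sort=False):
        out.append(
            PeakTemplate(
                metabolite=str(met),
                peaks=[
                    (float(r.center_ppm), float(r.weight), float(r.hwhm_ppm))
                    for r in sub.itertuples()
                ],
            )
        )
    return out


def _group_chol(config: SynthConfig, group: str, mets: list[str]) -> np.ndarray:
    """Cholesky factor of the latent correlation matrix for one group."""
    p = len(mets)
    corr = np.eye(p)
    idx = {m: i for i, m in enumerate(mets)}
    for grp, members, r in config.corr_blocks:
        if grp != group:
            continue
        ii = [idx[m] for m in members]
        for a in ii:
            for b in ii:
                if a != b:
                    corr[a, b] = r
    return np.linalg.cholesky(corr)


def simulate_concentrations(config: SynthConfig) -> QuantMatrix:
    """Draw a concentration matrix with the configured ground truth.

    Group ``g``, metabolite ``m`` has expected value
    ``baseline[m] * 2**effect[m, g]``: the log-normal noise carries the
    mean-preserving ``-sigma^2/2`` offset so arithmetic group means recover
    the injected log2 fold changes without bias.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    mets = config.metabolites
    base = config.baseline_means.reindex(mets).to_numpy()
    sigma = math.sqrt(math.log(1.0 + config.noise_cv**2))

    sample_ids: list[str] = []
    groups: list[str] = []
    rows = []
    for g in config.groups:
        mu = np.log(base) + config.effect_table[g].to_numpy() * math.log(2.0)
        L = _group_chol(config, g, mets)
        z = rng.standard_normal((config.n_per_group, len(mets))) @ L.T
        rows.append(np.exp(mu + sigma * z - 0.5 * sigma**2))
        sample_ids += [f"{g}_{i + 1:02d}" for i in range(config.n_per_group)]
        groups += [g] * config.n_per_group

    return QuantMatrix(
        sample_ids=sample_ids,
        groups=groups,
        feature_names=mets,
        values=np.vstack(rows),
        feature_kind="metabolite",
        normalization="none",
    )


def _lorentzian(x: np.ndarray, center: float, hwhm: float) -> np.ndarray:
    """Unit-area Lorentzian line shape."""
    return (hwhm / math.pi) / ((x - center) ** 2 + hwhm**2)


def render_spectra(
    quant: QuantMatrix,
    templates: list[PeakTemplate] | None = None,
    window: tuple[float, float] = (10.0, -2.0),
    points: int = 32768,
    seed: int = 0,
    noise_sd: float = 0.0,
    tsp_area: float = 1.0,
    tsp_hwhm: float = 0.003,
) -> list[Spectrum]:
    """Render each sample of ``quant`` as a 1D spectrum.

    Each spectrum is the sum over metabolites of concentration-scaled
    Lorentzian peaks, plus a reference peak of area ``tsp_area`` at
    0.00 ppm and optional additive Gaussian baseline noise of standard
    deviation ``noise_sd``. The integrated area of a metabolite's peaks is
    proportional to (in fact equal to, up to window truncation) its
    concentration.
    """
    if templates is None:
        templates = default_templates()
    if points < 1024:
        raise ValueError("points must be >= 1024")
    hi, lo = (window[0], window[1]) if window[0] > window[1] else (window[1], window[0])
    tmap = {t.metabolite: t for t in templates}
    missing = [m for m in quant.feature_names if m not in tmap]
    if missing:
        raise KeyError(f"templates missing metabolites: {missing}")
    for t in tmap.values():
        for c, _, _ in t.peaks:
            if not lo <= c <= hi:
                raise ValueError(
                    f"{t.metabolite}: peak at {c} ppm outside window ({hi}, {lo})"
                )
    if not lo <= 0.0 <= hi:
        raise ValueError("window must contain 0.00 ppm for the reference peak")

    ppm = np.linspace(hi, lo, points)  # descending
    # basis: one rendered unit-concentration trace per metabolite
    basis = np.empty((len(quant.feature_names), points))
    for j, met in enumerate(quant.feature_names):
        trace = np.zeros(points)
        for c, w, h in tmap[met].peaks:
            trace += w * _lorentzian(ppm, c, h)
        basis[j] = trace
    tsp = tsp_area * _lorentzian(ppm, 0.0, tsp_hwhm)

    rng = np.random.default_rng(seed)
    out = []
    for i, sid in enumerate(quant.sample_ids):
        inten = quant.values[i] @ basis + tsp
        if noise_sd > 0:
            inten = inten + rng.normal(0.0, noise_sd, points)
        out.append(
            Spectrum(sample_id=sid, group=quant.groups[i], ppm=ppm, intensity=inten)
        )
    return out
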