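"""Spectral preprocessing: referencing, binning, normalization, integration.

The chain mirrors standard 1H-NMR metabolomics practice: each spectrum is
referenced so the TSP standard sits at 0.00 ppm, integrated into fixed-width
chemical-shift bins (trapezoidal, with linear interpolation at bin edges so
binning conserves total signal exactly), normalized per sample, and finally
collapsed onto named metabolites via an assignment table of chemical-shift
windows.

Conventions: bins are half-open intervals [hi, lo) walking down the
descending ppm axis; a bin's label is its ppm midpoint rounded to three
decimals. Default bin width is 0.04 ppm and the residual-water region
4.70-4.90 ppm is excluded by default; both are configurable.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .containers import AssignmentTable, QuantMatrix, Spectrum

__all__ = [
    "ReferencingError",
    "reference_to_tsp",
    "bin_spectrum",
    "bin_spectra",
    "normalize",
    "integrate_metabolites",
    "DEFAULT_BIN_WIDTH",
    "DEFAULT_BIN_RANGE",
    "DEFAULT_EXCLUSIONS",
]

DEFAULT_BIN_WIDTH = 0.04
DEFAULT_BIN_RANGE = (9.5, 0.5)
DEFAULT_EXCLUSIONS = [(4.90, 4.70)]  # residual water


class ReferencingError(RuntimeError):
    """Raised when no reference peak can be located for a sample."""


def reference_to_tsp(
    s: Spectrum,
    search_window: tuple[float, float] = (0.2, -0.2),
    min_prominence: float = 1e-6,
) -> Spectrum:
    """Shift the ppm axis so the tallest peak in ``search_window`` sits at 0.00.

    Intensities are untouched; only the axis moves. Raises
    :class:`ReferencingError` if the window contains no local maximum of at
    least ``min_prominence`` (e.g. a flat or empty region).
    """
    hi, lo = max(search_window), min(search_window)
    mask = (s.ppm <= hi) & (s.ppm >= lo)
    if mask.sum() < 3:
        raise ReferencingError(
            f"{s.sample_id}: search window ({hi}, {lo}) outside spectrum support"
        )
    seg = s.intensity[mask]
    peaks, props = find_peaks(seg, prominence=min_prominence)
    if len(peaks) == 0:
        raise ReferencingError(
            f"{s.sample_id}: no reference peak above prominence "
            f"{min_prominence} in ({hi}, {lo}) ppm"
        )
    apex = peaks[np.argmax(seg[peaks])]
    delta = s.ppm[np.flatnonzero(mask)[apex]]
    return s.shifted(-delta)


def _cumulative_integral(x: np.ndarray, y: np.ndarray):
    """Return F with F(e) = integral of the piecewise-linear y from x[0] to e."""
    F = np.concatenate([[0.0], np.cumsum(0.5 * (y[1:] + y[:-1]) * np.diff(x))])

    def at(e: np.ndarray) -> np.ndarray:
        e = np.asarray(e, dtype=float)
        k = np.clip(np.searchsorted(x, e, side="right") - 1, 0, len(x) - 2)
        ye = y[k] + (y[k + 1] - y[k]) * (e - x[k]) / (x[k + 1] - x[k])
        return F[k] + 0.5 * (y[k] + ye) * (e - x[k])

    return at


def bin_spectrum(
    s: Spectrum,
    bin_width: float = DEFAULT_BIN_WIDTH,
    ppm_range: tuple[float, float] = DEFAULT_BIN_RANGE,
    exclusions: list[tuple[float, float]] | None = None,
) -> pd.Series:
    """Integrate a spectrum into half-open [hi, lo) bins down the ppm axis.

    Returns a Series indexed by bin-midpoint labels (3 decimals, descending
    ppm). Each value is the trapezoidal integral of intensity over the bin,
    with intensities linearly interpolated at bin edges — so the sum of all
    bins equals the integral over the binned range exactly. Bins whose
    midpoint falls inside an exclusion interval are dropped.
    """
    if exclusions is None:
        exclusions = DEFAULT_EXCLUSIONS
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    hi, lo = max(ppm_range), min(ppm_range)
    if bin_width > hi - lo:
        raise ValueError("bin_width larger than the binned range")
    if hi > s.ppm[0] + 1e-9 or lo < s.ppm[-1] - 1e-9:
        raise ValueError(
            f"range ({hi}, {lo}) outside spectrum support "
            f"({s.ppm[0]:.3f}, {s.ppm[-1]:.3f})"
        )
    n_bins = int(np.floor((hi - lo) / bin_width + 1e-9))
    edges = hi - bin_width * np.arange(n_bins + 1)  # descending

    x = s.ppm[::-1]
    y = s.intensity[::-1]
    F = _cumulative_integral(x, y)
    vals = F(edges[:-1]) - F(edges[1:])  # integral over [hi_k, lo_k]

    mids = 0.5 * (edges[:-1] + edges[1:])
    keep = np.ones(n_bins, dtype=bool)
    for e_hi, e_lo in [(max(e), min(e)) for e in exclusions]:
        keep &= ~((mids >= e_lo) & (mids <= e_hi))
    labels = [f"{m:.3f}" for m in mids[keep]]
    return pd.Series(vals[keep], index=labels, name=s.sample_id)


def bin_spectra(
    spectra: list[Spectrum],
    bin_width: float = DEFAULT_BIN_WIDTH,
    ppm_range: tuple[float, float] = DEFAULT_BIN_RANGE,
    exclusions: list[tuple[float, float]] | None = None,
) -> QuantMatrix:
    """Bin a cohort of spectra into one bin-feature QuantMatrix."""
    if not spectra:
        raise ValueError("no spectra given")
    series = [bin_spectrum(s, bin_width, ppm_range, exclusions) for s in spectra]
    ref = list(series[0].index)
    for s in series[1:]:
        if list(s.index) != ref:
            raise ValueError("spectra produced inconsistent bin grids")
    return QuantMatrix(
        sample_ids=[s.sample_id for s in spectra],
        groups=[s.group for s in spectra],
        feature_names=ref,
        values=np.vstack([sr.to_numpy() for sr in series]),
        feature_kind="bin",
        normalization="none",
    )


def normalize(
    m: QuantMatrix, method: str = "total_area", target: float = 100.0
) -> QuantMatrix:
    """Per-sample normalization.

    ``total_area`` scales each row so its sum equals ``target``. ``pqn``
    (probabilistic quotient) first total-area scales, then divides each row
    by the median of its feature-wise quotients versus the median reference
    spectrum — robust against single metabolites dominating total area.
    """
    row_sums = m.values.sum(axis=1)
    bad = np.flatnonzero(row_sums <= 0)
    if bad.size:
        raise ValueError(
            f"non-positive row sum for sample(s): {[m.sample_ids[i] for i in bad]}"
        )
    X = m.values * (target / row_sums)[:, None]
    if method == "total_area":
        tag = f"total_area[{target:g}]"
    elif method == "pqn":
        ref = np.median(X, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.where(ref > 0, X / ref, np.nan)
        quotients = np.nanmedian(q, axis=1)
        if np.any(~np.isfinite(quotients)) or np.any(quotients <= 0):
            raise ValueError("PQN quotient undefined for some sample")
        X = X / quotients[:, None]
        tag = f"pqn[{target:g}]"
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return QuantMatrix(
        sample_ids=list(m.sample_ids),
        groups=list(m.groups),
        feature_names=list(m.feature_names),
        values=X,
        feature_kind=m.feature_kind,
        normalization=tag,
    )


def integrate_metabolites(m: QuantMatrix, table: AssignmentTable) -> QuantMatrix:
    """Collapse a bin matrix onto named metabolites.

    Each metabolite's value is the sum of the bins whose midpoint falls in
    one of its half-open [hi, lo) windows. Metabolites whose windows capture
    no bin are excluded with a warning. Output columns follow table order.
    """
    if m.feature_kind != "bin":
        raise ValueError("integrate_metabolites expects a bin-kind QuantMatrix")
    mids = np.array([float(f) for f in m.feature_names])
    cols, names = [], []
    for met in table.metabolites:
        mask = np.zeros(len(mids), dtype=bool)
        for hi, lo in table.windows[met]:
            mask |= (mids <= hi) & (mids > lo)  # half-open [hi, lo)
        if not mask.any():
            warnings.warn(
                f"metabolite {met!r}: assignment windows capture no bins; excluded",
                stacklevel=2,
            )
            continue
        cols.append(m.values[:, mask].sum(axis=1))
        names.append(met)
    if not names:
        raise ValueError("no metabolite window captured any bin")
    return QuantMatrix(
        sample_ids=list(m.sample_ids),
        groups=list(m.groups),
        feature_names=names,
        values=np.column_stack(cols),
        feature_kind="metabolite",
        normalization=m.normalization,
    )
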