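"""Core in-memory containers: spectra, quantification matrices, assignment tables.

A :class:`Spectrum` is one sample's 1D trace on a strictly descending ppm
axis (the plotting convention in NMR). A :class:`QuantMatrix` is the
samples-by-features abundance table that every downstream stage consumes;
features are either spectral bins (labelled by ppm midpoint) or named
metabolites. An :class:`AssignmentTable` maps metabolite names to the
chemical-shift windows their signals integrate over.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["Spectrum", "QuantMatrix", "AssignmentTable"]


@dataclass
class Spectrum:
    """One sample's 1D NMR trace.

    Parameters
    ----------
    sample_id : str
        Sample label.
    group : str
        Experimental group label (may be empty before a design table is joined).
    ppm : ndarray
        Strictly descending chemical-shift axis in ppm.
    intensity : ndarray
        Intensities, same length as ``ppm``, all finite.
    """

    sample_id: str
    group: str
    ppm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.ppm.shape != self.intensity.shape:
            raise ValueError("ppm and intensity must be 1-D and equally long")
        if self.ppm.size < 2:
            raise ValueError("spectrum needs at least two points")
        if not np.all(np.diff(self.ppm) < 0):
            raise ValueError("ppm axis must be strictly descending")
        if not (np.all(np.isfinite(self.ppm)) and np.all(np.isfinite(self.intensity))):
            raise ValueError("non-finite values in spectrum")

    def shifted(self, delta_ppm: float) -> "Spectrum":
        """Return a copy with the ppm axis shifted by ``delta_ppm``."""
        return replace(self, ppm=self.ppm + delta_ppm, intensity=self.intensity.copy())

    def write(self, path) -> None:
        """Write two-column ASCII (ppm, intensity), ppm descending."""
        with open(path, "w") as fh:
            for p, v in zip(self.ppm, self.intensity):
                fh.write(f"{p:.6f}\t{v:.8e}\n")

    @classmethod
    def read(cls, path, sample_id: str | None = None, group: str = "") -> "Spectrum":
        """Read a two-column whitespace- or comma-delimited ASCII spectrum.

        A single non-numeric header line is tolerated and skipped. The ppm
        column is sorted to descending order if the file stores it ascending.
        """
        with open(path) as fh:
            text = fh.read()
        text = text.replace(",", " ")
        lines = [ln for ln in text.splitlines() if ln.strip()]
        start = 0
        try:
            float(lines[0].split()[0])
        except (ValueError, IndexError):
            start = 1
        data = np.loadtxt(_io.StringIO("\n".join(lines[start:])))
        if data.ndim != 2 or data.shape[1] < 2:
            raise ValueError(f"{path}: expected two columns (ppm, intensity)")
        ppm, inten = data[:, 0], data[:, 1]
        if ppm[0] < ppm[-1]:
            ppm, inten = ppm[::-1], inten[::-1]
        if sample_id is None:
            import os

            sample_id = os.path.splitext(os.path.basename(str(path)))[0]
        return cls(sample_id=sample_id, group=group, ppm=ppm, intensity=inten)


@dataclass
class QuantMatrix:
    """Samples x features abundance table with group labels.

    ``feature_kind`` is ``"bin"`` (features labelled by ppm midpoint) or
    ``"metabolite"``; ``normalization`` records the method applied so far.
    """

    sample_ids: list[str]
    groups: list[str]
    feature_names: list[str]
    values: np.ndarray
    feature_kind: str = "metabolite"
    normalization: str = "none"

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.groups = list(self.groups)
        self.feature_names = [str(f) for f in self.feature_names]
        self.values = np.asarray(self.values, dtype=float)
        n, p = len(self.sample_ids), len(self.feature_names)
        if self.values.shape != (n, p):
            raise ValueError(f"values shape {self.values.shape} != ({n}, {p})")
        if len(self.groups) != n:
            raise ValueError("groups length must match sample_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("QuantMatrix contains missing/non-finite values")
        if self.feature_kind not in ("bin", "metabolite"):
            raise ValueError(f"unknown feature_kind {self.feature_kind!r}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "group", self.groups)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def select_groups(self, groups) -> "QuantMatrix":
        groups = list(groups)
        unknown = set(groups) - set(self.groups)
        if unknown:
            raise KeyError(f"unknown group(s): {sorted(unknown)}")
        mask = np.array([g in groups for g in self.groups])
        return QuantMatrix(
            sample_ids=[s for s, m in zip(self.sample_ids, mask) if m],
            groups=[g for g, m in zip(self.groups, mask) if m],
            feature_names=list(self.feature_names),
            values=self.values[mask],
            feature_kind=self.feature_kind,
            normalization=self.normalization,
        )

    def group_values(self, group: str) -> np.ndarray:
        """Rows belonging to one group."""
        mask = np.array([g == group for g in self.groups])
        if not mask.any():
            raise KeyError(f"unknown group {group!r}")
        return self.values[mask]

    def to_csv(self, path, header_lines: list[str] | None = None) -> None:
        """Write as CSV (sample_id, group, features...), optional '#' header."""
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            fh.write(f"# feature_kind: {self.feature_kind}\n")
            fh.write(f"# normalization: {self.normalization}\n")
            self.to_frame().to_csv(fh, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path) -> "QuantMatrix":
        kind, norm = "metabolite", "none"
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                body = line[1:].strip()
                if body.startswith("feature_kind:"):
                    kind = body.split(":", 1)[1].strip()
                elif body.startswith("normalization:"):
                    norm = body.split(":", 1)[1].strip()
        df = pd.read_csv(path, comment="#")
        return cls(
            sample_ids=df["sample_id"].astype(str).tolist(),
            groups=df["group"].astype(str).tolist(),
            feature_names=list(df.columns[2:]),
            values=df.iloc[:, 2:].to_numpy(dtype=float),
            feature_kind=kind,
            normalization=norm,
        )


@dataclass
class AssignmentTable:
    """Metabolite -> list of half-open ppm windows [hi, lo).

    Window order fixes the output order of integrated metabolite tables.
    """

    windows: dict[str, list[tuple[float, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for met, wins in self.windows.items():
            for hi, lo in wins:
                if not hi > lo:
                    raise ValueError(f"{met}: window hi must exceed lo ({hi}, {lo})")
            wins_sorted = sorted(wins, key=lambda w: -w[0])
            for (hi1, lo1), (hi2, lo2) in zip(wins_sorted, wins_sorted[1:]):
                if lo1 < hi2:  # next window starts above previous window's floor
                    raise ValueError(f"{met}: overlapping windows")

    @property
    def metabolites(self) -> list[str]:
        return list(self.windows)

    @classmethod
    def from_csv(cls, path) -> "AssignmentTable":
        df = pd.read_csv(path)
        wins: dict[str, list[tuple[float, float]]] = {}
        for _, row in df.iterrows():
            wins.setdefault(str(row["metabolite"]), []).append(
                (float(row["window_hi_ppm"]), float(row["window_lo_ppm"]))
            )
        return cls(windows=wins)

    def to_csv(self, path) -> None:
        rows = [
            {"metabolite": m, "window_hi_ppm": hi, "window_lo_ppm": lo}
            for m, wins in self.windows.items()
            for hi, lo in wins
        ]
        pd.DataFrame(rows).to_csv(path, index=False)
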