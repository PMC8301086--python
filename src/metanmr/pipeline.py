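"""End-to-end pipeline: spectra on disk -> tables and networks on disk.

:class:`RunConfig` gathers every path and tuning parameter of the chain;
:func:`run_pipeline` executes referencing, binning, normalization,
metabolite integration, OSC-PLSDA per comparison, the univariate stats
table and the differential networks, writing each artifact as CSV/TSV or
GraphML. Outputs are deterministic for a fixed config and seed, and every
delimited output carries a provenance header (config hash, seed, package
version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import __version__, chemometrics, datasets, network, preprocess, stats
from .containers import AssignmentTable, QuantMatrix, Spectrum

__all__ = ["RunConfig", "run_pipeline", "simulate_cohort"]

_SPECTRUM_EXTS = (".txt", ".tsv", ".asc", ".csv", ".dat")


@dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    spectra_dir: str = ""
    design_csv: str = ""
    assignment_csv: str | None = None  # None -> packaged 38-metabolite table
    fingerprints_csv: str | None = None
    reactions_csv: str | None = None
    output_dir: str = "results"
    # preprocessing
    reference: bool = True
    bin_width: float = preprocess.DEFAULT_BIN_WIDTH
    bin_range: tuple[float, float] = preprocess.DEFAULT_BIN_RANGE
    exclusions: list[tuple[float, float]] = field(
        default_factory=lambda: list(preprocess.DEFAULT_EXCLUSIONS)
    )
    normalization: str = "total_area"
    norm_target: float = 100.0
    # model
    n_osc: int = 1
    n_pls: int = 2
    cv_folds: int = 7
    scaling: str = "uv"
    # stats
    comparisons: list[tuple[str, str]] = field(
        default_factory=lambda: [list(c) for c in datasets.CONTRASTS.values()]
    )
    alpha_normality: float = 0.05
    t_variant: str = "welch"
    # network
    network_mode: str = "delta_r"
    network_threshold: float = 0.65
    network_alpha: float = 0.05
    tanimoto_cutoff: float = 0.7
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bin_range"] = list(self.bin_range)
        d["exclusions"] = [list(e) for e in self.exclusions]
        d["comparisons"] = [list(c) for c in self.comparisons]
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("output_dir", None)  # destination does not identify the analysis
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for label, path in [
            ("spectra_dir", self.spectra_dir),
            ("design_csv", self.design_csv),
            ("assignment_csv", self.assignment_csv),
            ("fingerprints_csv", self.fingerprints_csv),
            ("reactions_csv", self.reactions_csv),
        ]:
            if path and not os.path.exists(path):
                raise FileNotFoundError(f"{label}: no such path {path!r}")


def _read_design(path) -> list[tuple[str, str]]:
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    if not {"sample_id", "group"} <= set(df.columns):
        raise ValueError(f"{path}: design table needs sample_id and group columns")
    return [(str(s), str(g)) for s, g in zip(df["sample_id"], df["group"])]


def _find_spectrum_file(spectra_dir: str, sample_id: str) -> str:
    for ext in _SPECTRUM_EXTS:
        cand = os.path.join(spectra_dir, sample_id + ext)
        if os.path.exists(cand):
            return cand
    raise FileNotFoundError(
        f"no spectrum file for sample {sample_id!r} in {spectra_dir!r}"
    )


def run_pipeline(config: RunConfig, log=print) -> dict:
    """Run the full chain; returns the in-memory artifacts.

    Artifacts written to ``config.output_dir``: the binned and metabolite
    matrices, the long and wide stats tables, per-comparison model tables
    (scores incl. projected groups, loadings, S-plot) and networks
    (GraphML + TSV edge list).
    """
    config.validate()
    os.makedirs(config.output_dir, exist_ok=True)
    header = [
        f"metanmr {__version__}",
        f"config_hash: {config.config_hash()}",
        f"seed: {config.seed}",
    ]

    design = _read_design(config.design_csv)
    spectra: list[Spectrum] = []
    for sid, grp in design:
        path = _find_spectrum_file(config.spectra_dir, sid)
        s = Spectrum.read(path, sample_id=sid, group=grp)
        if config.reference:
            try:
                s = preprocess.reference_to_tsp(s)
            except preprocess.ReferencingError as err:
                raise preprocess.ReferencingError(
                    f"stage=reference sample={sid}: {err}"
                ) from err
        spectra.append(s)
    log(f"read {len(spectra)} spectra from {config.spectra_dir}")

    bins = preprocess.bin_spectra(
        spectra, config.bin_width, tuple(config.bin_range),
        [tuple(e) for e in config.exclusions],
    )
    bins = preprocess.normalize(bins, config.normalization, config.norm_target)
    bins.to_csv(os.path.join(config.output_dir, "binned_matrix.csv"), header)

    table = (
        AssignmentTable.from_csv(config.assignment_csv)
        if config.assignment_csv
        else datasets.load_assignments()
    )
    mets = preprocess.integrate_metabolites(bins, table)
    mets.to_csv(os.path.join(config.output_dir, "metabolite_matrix.csv"), header)
    log(f"integrated {mets.n_features} metabolites over {bins.n_features} bins")

    comparisons = [tuple(c) for c in config.comparisons]
    st = stats.stats_table(
        mets, comparisons, config.alpha_normality, config.t_variant
    )
    _write_df(st, os.path.join(config.output_dir, "stats_table.csv"), header)
    _write_df(
        stats.wide_table(st).reset_index(names="metabolite"),
        os.path.join(config.output_dir, "stats_table_wide.csv"),
        header,
    )

    if config.fingerprints_csv:
        import pandas as pd

        fpdf = pd.read_csv(config.fingerprints_csv, dtype={"bits": str})
        fps = pd.DataFrame(
            [[int(ch) for ch in b] for b in fpdf["bits"]],
            index=fpdf["metabolite"].tolist(),
        )
    else:
        fps = datasets.load_fingerprints()
    reactions = (
        [
            (str(a), str(b))
            for a, b in __import__("pandas")
            .read_csv(config.reactions_csv)[["from", "to"]]
            .itertuples(index=False)
        ]
        if config.reactions_csv
        else datasets.load_reactions()
    )

    models, networks = {}, {}
    for ga, gb in comparisons:
        tag = f"{ga}_vs_{gb}"
        model = chemometrics.fit_plsda(
            mets,
            (ga, gb),
            n_pls=config.n_pls,
            n_osc=config.n_osc,
            cv_folds=config.cv_folds,
            seed=config.seed,
            scaling=config.scaling,
        )
        models[tag] = model
        log(
            f"model {tag}: R2Y={model.r2y[-1]:.3f} Q2={model.q2:.3f} "
            f"n_osc={model.n_osc}"
        )
        scores = model.scores_frame(mets)  # all groups projected
        _write_df(scores, os.path.join(config.output_dir, f"model_{tag}_scores.csv"), header)
        pair = mets.select_groups([ga, gb])
        _write_df(
            chemometrics.s_plot(model, pair),
            os.path.join(config.output_dir, f"model_{tag}_splot.csv"),
            header,
        )
        _write_df(
            chemometrics.coefficient_loadings(model, pair),
            os.path.join(config.output_dir, f"model_{tag}_loadings.csv"),
            header,
        )

        net = network.differential_network(
            mets,
            (ga, gb),
            stats=st,
            mode=config.network_mode,
            threshold=config.network_threshold,
            alpha=config.network_alpha,
        )
        net = network.reaction_overlay(
            net, reactions, fingerprints=fps, tanimoto_cutoff=config.tanimoto_cutoff
        )
        networks[tag] = net
        net.write_graphml(os.path.join(config.output_dir, f"network_{tag}.graphml"))
        net.write_edges_tsv(
            os.path.join(config.output_dir, f"network_{tag}_edges.tsv"),
            header + [f"network_mode: {config.network_mode}"],
        )
        log(
            f"network {tag}: {len(net.edges[net.edges['type'] == 'diff_corr'])} "
            f"differential edges (mode={config.network_mode})"
        )

    return {
        "bins": bins,
        "metabolites": mets,
        "stats": st,
        "models": models,
        "networks": networks,
    }


def _write_df(df, path, header_lines) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def simulate_cohort(
    out_dir: str,
    n_per_group: int = 10,
    noise_cv: float = 0.1,
    seed: int = 0,
    points: int = 16384,
    window: tuple[float, float] = (10.0, -2.0),
    spectral_noise_sd: float = 0.0,
    corr_blocks: list | None = None,
) -> QuantMatrix:
    """Write a synthetic cohort (spectra + design + ground truth) to disk.

    Uses the packaged five-group study design. Returns the ground-truth
    concentration matrix (also written as ``true_concentrations.csv``).
    """
    from . import synth

    os.makedirs(out_dir, exist_ok=True)
    spectra_dir = os.path.join(out_dir, "spectra")
    os.makedirs(spectra_dir, exist_ok=True)
    cfg = synth.SynthConfig(
        n_per_group=n_per_group,
        noise_cv=noise_cv,
        seed=seed,
        corr_blocks=corr_blocks or [],
    )
    quant = synth.simulate_concentrations(cfg)
    spectra = synth.render_spectra(
        quant, window=window, points=points, seed=seed + 1, noise_sd=spectral_noise_sd
    )
    for s in spectra:
        s.write(os.path.join(spectra_dir, f"{s.sample_id}.txt"))
    with open(os.path.join(out_dir, "design.csv"), "w") as fh:
        fh.write("sample_id,group\n")
        for sid, grp in zip(quant.sample_ids, quant.groups):
            fh.write(f"{sid},{grp}\n")
    quant.to_csv(os.path.join(out_dir, "true_concentrations.csv"), [f"seed: {seed}"])
    return quant
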