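"""Differential Pearson-correlation networks with structural grouping.

Edges mark metabolite pairs whose correlation differs between two
experimental groups. Two edge rules are provided and recorded on the
result:

- ``delta_r`` (default): link a pair when ``|r_A - r_B|`` exceeds the
  threshold *and* a Fisher-z test for the difference of two independent
  correlations is significant at ``alpha``;
- ``per_pair_r``: link when ``|r_A|`` exceeds the threshold with its own
  correlation p-value below ``alpha``.

Nodes carry a direction color (increased / decreased / ns) taken from the
univariate stats table for the same comparison, plus a structural group id
from single-linkage clustering of pairwise Tanimoto fingerprint similarity
(strictly above the cutoff). Curated biochemical-reaction pairs can be
overlaid as a third, directed edge type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import QuantMatrix

__all__ = [
    "group_correlations",
    "differential_network",
    "tanimoto",
    "structural_groups",
    "reaction_overlay",
    "pair_scatter",
    "DiffNetwork",
]


def group_correlations(m: QuantMatrix, group: str):
    """Pearson correlation matrix (and p-values) among metabolites in a group.

    p-values come from the t-distribution transform of r at n-2 degrees of
    freedom. Zero-variance metabolites yield NaN rows/columns (flagged).
    Returns (r DataFrame, p DataFrame).
    """
    X = m.group_values(group)
    n = X.shape[0]
    if n < 4:
        raise ValueError(f"group {group!r} needs at least 4 samples, has {n}")
    sd = X.std(axis=0, ddof=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"zero-variance metabolite(s) in group {group!r}: "
            f"{[f for f, z in zip(m.feature_names, flat) if z]}",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r = np.asarray(r, dtype=float)
    np.fill_diagonal(r, 1.0)
    r[flat, :] = np.nan
    r[:, flat] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        rc = np.clip(r, -0.9999999999, 0.9999999999)
        tstat = rc * np.sqrt((n - 2) / (1.0 - rc**2))
        p = 2.0 * sps.t.sf(np.abs(tstat), df=n - 2)
    np.fill_diagonal(p, 0.0)
    p[np.isnan(r)] = np.nan
    names = m.feature_names
    return (
        pd.DataFrame(r, index=names, columns=names),
        pd.DataFrame(p, index=names, columns=names),
    )


def _fisher_z_p(r_a: float, r_b: float, n_a: int, n_b: int) -> float:
    """Two-sided test for equality of two independent correlations."""
    za, zb = np.arctanh(np.clip(r_a, -0.9999999999, 0.9999999999)), np.arctanh(
        np.clip(r_b, -0.9999999999, 0.9999999999)
    )
    se = np.sqrt(1.0 / (n_a - 3) + 1.0 / (n_b - 3))
    return float(2.0 * sps.norm.sf(abs(za - zb) / se))


@dataclass
class DiffNetwork:
    """Typed metabolite graph: nodes + diff_corr/structural/reaction edges."""

    comparison: tuple[str, str]
    mode: str
    threshold: float
    alpha: float
    nodes: pd.DataFrame  # metabolite, direction, structural_group
    edges: pd.DataFrame  # source, target, type, r_a, r_b, delta_r, sign, width, p
    meta: dict = field(default_factory=dict)

    def edge_pairs(self, kind: str | None = None) -> set[tuple[str, str]]:
        e = self.edges if kind is None else self.edges[self.edges["type"] == kind]
        return set(zip(e["source"], e["target"]))

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph(
            comparison=f"{self.comparison[0]}_vs_{self.comparison[1]}",
            mode=self.mode,
            threshold=self.threshold,
            alpha=self.alpha,
        )
        for row in self.nodes.itertuples():
            g.add_node(
                row.metabolite,
                direction=row.direction,
                structural_group=int(row.structural_group),
            )
        for row in self.edges.itertuples():
            g.add_edge(
                row.source,
                row.target,
                type=row.type,
                r_a=_nansafe(row.r_a),
                r_b=_nansafe(row.r_b),
                delta_r=_nansafe(row.delta_r),
                sign=int(row.sign),
                width=_nansafe(row.width),
                p=_nansafe(row.p),
            )
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def write_edges_tsv(self, path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            self.edges.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def _nansafe(v):
    return 0.0 if (isinstance(v, float) and np.isnan(v)) else float(v)


def differential_network(
    m: QuantMatrix,
    comparison: tuple[str, str],
    stats: pd.DataFrame | None = None,
    mode: str = "delta_r",
    threshold: float = 0.65,
    alpha: float = 0.05,
) -> DiffNetwork:
    """Build the differential correlation network between two groups.

    ``stats`` is the long-form stats table; its rows for this comparison
    color the nodes (significantly increased / decreased / ns). Edge rule
    depends on ``mode`` (see module docstring); edge sign and width follow
    the differential coefficient (or ``r_A`` in ``per_pair_r`` mode).
    """
    if mode not in ("delta_r", "per_pair_r"):
        raise ValueError(f"unknown mode {mode!r}")
    if not 0 < threshold <= 2:
        raise ValueError("threshold must lie in (0, 2]")
    ga, gb = comparison
    r_a, p_a = group_correlations(m, ga)
    r_b, _ = group_correlations(m, gb)
    n_a = m.group_values(ga).shape[0]
    n_b = m.group_values(gb).shape[0]
    names = m.feature_names

    direction = {met: "ns" for met in names}
    if stats is not None and not stats.empty:
        comp_label = f"{ga}_vs_{gb}"
        sub = stats[stats["comparison"] == comp_label]
        for row in sub.itertuples():
            if row.p_adj < 0.05:
                direction[row.metabolite] = (
                    "increased" if row.log2fc > 0 else "decreased"
                )

    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            ra = float(r_a.iat[i, j])
            rb = float(r_b.iat[i, j])
            if np.isnan(ra) or np.isnan(rb):
                continue
            delta = ra - rb
            if mode == "delta_r":
                if abs(delta) <= threshold:
                    continue
                p = _fisher_z_p(ra, rb, n_a, n_b)
                if p >= alpha:
                    continue
                sign, width = int(np.sign(delta)), abs(delta)
            else:
                if abs(ra) <= threshold or float(p_a.iat[i, j]) >= alpha:
                    continue
                p = float(p_a.iat[i, j])
                sign, width = int(np.sign(ra)), abs(ra)
            rows.append(
                {
                    "source": names[i],
                    "target": names[j],
                    "type": "diff_corr",
                    "r_a": ra,
                    "r_b": rb,
                    "delta_r": delta,
                    "sign": sign,
                    "width": width,
                    "p": p,
                }
            )
    nodes = pd.DataFrame(
        {
            "metabolite": names,
            "direction": [direction[met] for met in names],
            "structural_group": [-1] * len(names),
        }
    )
    edges = pd.DataFrame(
        rows,
        columns=[
            "source", "target", "type", "r_a", "r_b", "delta_r", "sign", "width", "p",
        ],
    )
    return DiffNetwork(
        comparison=comparison,
        mode=mode,
        threshold=threshold,
        alpha=alpha,
        nodes=nodes,
        edges=edges,
        meta={"n_a": n_a, "n_b": n_b},
    )


def tanimoto(f1, f2) -> float:
    """|intersection| / |union| of two equal-length binary fingerprints."""
    a = np.asarray(f1, dtype=bool)
    b = np.asarray(f2, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("fingerprint length mismatch")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValueError("both fingerprints all-zero; similarity undefined")
    return float(np.logical_and(a, b).sum() / union)


def structural_groups(fingerprints: pd.DataFrame, cutoff: float = 0.7):
    """Single-linkage structural groups from pairwise Tanimoto similarity.

    Metabolite pairs strictly above ``cutoff`` are linked; connected
    components form the groups. Group ids are assigned in order of each
    component's first member in the fingerprint table. Returns
    (group id Series, list of linked pairs with their similarity).
    """
    names = list(fingerprints.index)
    bits = fingerprints.to_numpy(dtype=bool)
    g = nx.Graph()
    g.add_nodes_from(names)
    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            sim = tanimoto(bits[i], bits[j])
            if sim > cutoff:  # strictly over
                g.add_edge(names[i], names[j])
                pairs.append((names[i], names[j], sim))
    comps = sorted(
        (sorted(c, key=names.index) for c in nx.connected_components(g)),
        key=lambda c: names.index(c[0]),
    )
    gid = pd.Series(-1, index=names, dtype=int, name="structural_group")
    for k, comp in enumerate(comps):
        gid[comp] = k
    return gid, pairs


def reaction_overlay(
    net: DiffNetwork,
    reactions: list[tuple[str, str]],
    fingerprints: pd.DataFrame | None = None,
    tanimoto_cutoff: float = 0.7,
) -> DiffNetwork:
    """Annotate a network with structural groups/edges and reaction edges.

    Reaction pairs are added as directed ``reaction`` edges (deduplicated);
    pairs naming metabolites absent from the network are skipped with a
    warning. If ``fingerprints`` are supplied, structural groups are
    computed and pairs over the Tanimoto cutoff become ``structural`` edges.
    Existing diff_corr edges are never altered.
    """
    nodes = net.nodes.copy()
    known = set(nodes["metabolite"])
    new_rows = []

    if fingerprints is not None:
        fp = fingerprints.loc[[n for n in nodes["metabolite"] if n in fingerprints.index]]
        gid, pairs = structural_groups(fp, tanimoto_cutoff)
        nodes["structural_group"] = [
            int(gid.get(met, -1)) for met in nodes["metabolite"]
        ]
        for a, b, sim in pairs:
            new_rows.append(
                {
                    "source": a,
                    "target": b,
                    "type": "structural",
                    "r_a": np.nan,
                    "r_b": np.nan,
                    "delta_r": np.nan,
                    "sign": 0,
                    "width": sim,
                    "p": np.nan,
                }
            )

    seen: set[tuple[str, str]] = set(
        zip(
            net.edges.loc[net.edges["type"] == "reaction", "source"],
            net.edges.loc[net.edges["type"] == "reaction", "target"],
        )
    )
    for a, b in reactions:
        if a not in known or b not in known:
            warnings.warn(f"reaction pair ({a}, {b}) names unknown metabolite; skipped",
                          stacklevel=2)
            continue
        if (a, b) in seen:
            continue
        seen.add((a, b))
        new_rows.append(
            {
                "source": a,
                "target": b,
                "type": "reaction",
                "r_a": np.nan,
                "r_b": np.nan,
                "delta_r": np.nan,
                "sign": 0,
                "width": 1.0,
                "p": np.nan,
            }
        )
    edges = pd.concat([net.edges, pd.DataFrame(new_rows, columns=net.edges.columns)],
                      ignore_index=True) if new_rows else net.edges.copy()
    return DiffNetwork(
        comparison=net.comparison,
        mode=net.mode,
        threshold=net.threshold,
        alpha=net.alpha,
        nodes=nodes,
        edges=edges,
        meta=dict(net.meta),
    )


def pair_scatter(m: QuantMatrix, pair: tuple[str, str], groups: list[str]) -> dict:
    """Per-group sample value pairs and Pearson r for one metabolite pair.

    The per-group r values match the corresponding
    :func:`group_correlations` entries exactly. Degenerate (constant)
    metabolites yield ``r = None`` with a flag.
    """
    m1, m2 = pair
    for met in pair:
        if met not in m.feature_names:
            raise KeyError(f"unknown metabolite {met!r}")
    i, j = m.feature_names.index(m1), m.feature_names.index(m2)
    out = {}
    for g in groups:
        X = m.group_values(g)
        x, y = X[:, i], X[:, j]
        if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
            out[g] = {"x": x, "y": y, "r": None, "p": None, "degenerate": True}
            continue
        # same estimator and p transform as group_correlations, entry for entry
        r = float(np.corrcoef(x, y)[0, 1])
        rc = float(np.clip(r, -0.9999999999, 0.9999999999))
        tstat = rc * np.sqrt((len(x) - 2) / (1.0 - rc**2))
        p = float(2.0 * sps.t.sf(abs(tstat), df=len(x) - 2))
        out[g] = {"x": x, "y": y, "r": r, "p": p, "degenerate": False}
    return out
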