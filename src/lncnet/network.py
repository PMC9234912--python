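"""Cross-layer Pearson correlation and thresholded bipartite networks.

The cascade's core: correlate Z-scored features of two layers across the same
samples, keep pairs passing |r| (or signed r) and p thresholds as bipartite
edges, drop isolated nodes, optionally restrict one side to a curated node set,
and rank nodes by the median absolute correlation to every opposite-side node.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import Layer, OmicsMatrix

__all__ = [
    "CorrelationMatrix",
    "BipartiteCorrelationNetwork",
    "cross_layer_correlation",
    "build_network",
    "restrict_network",
    "median_importance",
    "otu_coabundance",
    "otu_sign_consistency",
]


@dataclass
class CorrelationMatrix:
    """Pearson r and two-sided p between all pairs of two feature layers."""

    r: pd.DataFrame          # rows = layer A features, cols = layer B features
    p: pd.DataFrame
    n: int                   # samples used (identical for every cell)
    layer_a: Layer
    layer_b: Layer

    def __post_init__(self) -> None:
        if self.r.shape != self.p.shape:
            raise ValueError("r and p matrices must have identical shape")
        if (np.abs(self.r.to_numpy()) > 1 + 1e-12).any():
            raise ValueError("|r| must be ≤ 1")

    def restrict(self, row_ids=None, col_ids=None) -> "CorrelationMatrix":
        r, p = self.r, self.p
        if row_ids is not None:
            r, p = r.loc[list(row_ids)], p.loc[list(row_ids)]
        if col_ids is not None:
            r, p = r[list(col_ids)], p[list(col_ids)]
        return CorrelationMatrix(r, p, self.n, self.layer_a, self.layer_b)


@dataclass
class BipartiteCorrelationNetwork:
    """Thresholded cross-layer edges; every retained node has degree ≥ 1."""

    edges: pd.DataFrame      # source_id, source_layer, target_id, target_layer, pearson_r, p_value
    layer_a: Layer
    layer_b: Layer
    r_min: float
    p_max: float | None
    mode: str = "absolute"   # or "signed"

    @property
    def side_a(self) -> list[str]:
        return sorted(self.edges["source_id"].unique())

    @property
    def side_b(self) -> list[str]:
        return sorted(self.edges["target_id"].unique())

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __post_init__(self) -> None:
        if self.mode not in ("absolute", "signed"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if len(self.edges):
            r = self.edges["pearson_r"].to_numpy()
            passing = (np.abs(r) if self.mode == "absolute" else r) > self.r_min
            if self.p_max is not None:
                passing &= self.edges["p_value"].to_numpy() < self.p_max
            if not passing.all():
                raise ValueError("network contains edges violating its thresholds")


def _empty_edges() -> pd.DataFrame:
    return pd.DataFrame({
        "source_id": pd.Series(dtype=str),
        "source_layer": pd.Series(dtype=str),
        "target_id": pd.Series(dtype=str),
        "target_layer": pd.Series(dtype=str),
        "pearson_r": pd.Series(dtype=float),
        "p_value": pd.Series(dtype=float),
    })


def correlation_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for a Pearson r at sample size n via t = r√(n−2)/√(1−r²)."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df) / np.sqrt(1.0 - r ** 2)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def cross_layer_correlation(a: OmicsMatrix, b: OmicsMatrix) -> CorrelationMatrix:
    """All-pairs Pearson correlation between features of two layers.

    Both matrices must share identical sample IDs in identical order, with
    n ≥ 4 samples.  Computed as a matrix product of row-standardized values.
    """
    if a.sample_ids != b.sample_ids:
        raise ValueError("sample IDs must match in identical order")
    n = a.n_samples
    if n < 4:
        raise ValueError("need at least 4 shared samples for correlation")

    def _standardize(x: np.ndarray) -> np.ndarray:
        xc = x - x.mean(axis=1, keepdims=True)
        norm = np.sqrt((xc ** 2).sum(axis=1, keepdims=True))
        if (norm == 0).any():
            raise ValueError("zero-variance feature in correlation input")
        return xc / norm

    r = _standardize(a.values) @ _standardize(b.values).T
    r = np.clip(r, -1.0, 1.0)
    p = correlation_p(r, n)
    rdf = pd.DataFrame(r, index=a.feature_ids, columns=b.feature_ids)
    pdf = pd.DataFrame(p, index=a.feature_ids, columns=b.feature_ids)
    return CorrelationMatrix(rdf, pdf, n, a.layer, b.layer)


def build_network(c: CorrelationMatrix, r_min: float,
                  p_max: float | None = 0.05,
                  mode: str = "absolute") -> BipartiteCorrelationNetwork:
    """Threshold a correlation matrix into a bipartite network.

    Edge iff (absolute mode: |r| > r_min; signed mode: r > r_min) and, when a
    p ceiling is set, p < p_max — both strict.  Nodes with no passing edge are
    dropped from both sides.
    """
    if not 0 < r_min < 1:
        raise ValueError("r_min must be in (0, 1)")
    r = c.r.to_numpy()
    crit = np.abs(r) if mode == "absolute" else r
    mask = crit > r_min
    if p_max is not None:
        mask &= c.p.to_numpy() < p_max
    ii, jj = np.nonzero(mask)
    if len(ii) == 0:
        edges = _empty_edges()
    else:
        edges = pd.DataFrame({
            "source_id": np.asarray(c.r.index, dtype=object)[ii],
            "source_layer": c.layer_a.value,
            "target_id": np.asarray(c.r.columns, dtype=object)[jj],
            "target_layer": c.layer_b.value,
            "pearson_r": r[ii, jj],
            "p_value": c.p.to_numpy()[ii, jj],
        })
        edges = edges.sort_values(["source_id", "target_id"],
                                  kind="mergesort").reset_index(drop=True)
    return BipartiteCorrelationNetwork(edges, c.layer_a, c.layer_b,
                                       r_min, p_max, mode)


def restrict_network(net: BipartiteCorrelationNetwork,
                     keep_b) -> BipartiteCorrelationNetwork:
    """Drop side-b nodes outside ``keep_b``; side-a nodes left isolated fall too."""
    keep_b = [str(x) for x in keep_b]
    extras = sorted(set(keep_b) - set(net.side_b))
    if extras:
        warnings.warn(f"{len(extras)} keep_b ids not in network (ignored)")
    keep = set(keep_b)
    edges = net.edges[net.edges["target_id"].isin(keep)].reset_index(drop=True)
    return BipartiteCorrelationNetwork(edges, net.layer_a, net.layer_b,
                                       net.r_min, net.p_max, net.mode)


def median_importance(c: CorrelationMatrix, axis: str = "a") -> pd.DataFrame:
    """Rank nodes by median |r| to ALL opposite-side nodes.

    ``c`` should already be restricted to the network's node sets; the median
    runs over every opposite-side node, including sub-threshold pairs (the
    full correlation heatmap, not only passing edges).  Sorted descending,
    ties broken lexicographically by node ID.
    """
    absr = c.r.abs()
    if axis == "a":
        med = absr.median(axis=1)
    elif axis == "b":
        med = absr.median(axis=0)
    else:
        raise ValueError("axis must be 'a' or 'b'")
    out = pd.DataFrame({"node_id": med.index.astype(str),
                        "median_abs_r": med.to_numpy()})
    out = out.sort_values(["median_abs_r", "node_id"],
                          ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)
    return out


def otu_coabundance(lnc_subset: OmicsMatrix, otu: OmicsMatrix,
                    r_min: float = 0.5,
                    p_max: float = 0.05) -> BipartiteCorrelationNetwork:
    """lncRNA:OTU co-abundance network at |r| > r_min, p < p_max."""
    c = cross_layer_correlation(lnc_subset, otu)
    return build_network(c, r_min=r_min, p_max=p_max, mode="absolute")


def otu_sign_consistency(net: BipartiteCorrelationNetwork) -> pd.DataFrame:
    """Per-OTU edge-sign summary: all-positive, all-negative, or mixed."""
    rows = []
    for otu_id, sub in net.edges.groupby("target_id", sort=True):
        r = sub["pearson_r"].to_numpy()
        if (r > 0).all():
            consistency = "all_positive"
        elif (r < 0).all():
            consistency = "all_negative"
        else:
            consistency = "mixed"
        rows.append({"otu_id": otu_id, "n_partners": len(r),
                     "median_r": float(np.median(r)),
                     "sign_consistency": consistency})
    return pd.DataFrame(rows, columns=["otu_id", "n_partners",
                                       "median_r", "sign_consistency"])
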