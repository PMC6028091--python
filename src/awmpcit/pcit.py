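"""Partial Correlation with Information Theory (PCIT) network filtering.

For every trio of variables (x, y, z) the first-order partial correlations

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))

(and its rotations) define a local information-theoretic tolerance

    eps_xyz = (1/3) (r_xy.z / r_xy + r_xz.y / r_xz + r_yz.x / r_yz).

The x-y association is declared non-significant if some z exists with
|r_xy| < |eps_xyz r_xz| and |r_xy| < |eps_xyz r_yz| -- i.e. the direct
correlation is small relative to both correlations with the third variable
after local rescaling.  Surviving edges are significant.

Guards: correlations with |r| > 1 - 1e-9 are clamped to that magnitude;
ratio terms whose direct correlation is below 1e-12 in magnitude are
skipped and eps averages the remaining terms; a trio with no valid term is
skipped entirely.  Edges with r exactly 0 are recorded but never
significant.

``pcit_filter`` is a vectorized per-third-variable sweep;
``pcit_filter_reference`` is the naive O(n^3) loop kept as the correctness
oracle.  Both implement the identical arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

_CLAMP = 1.0 - 1e-9
_RTOL = 1e-12


@dataclass
class PcitNetwork:
    """Undirected co-association network over AWM rows."""

    labels: list[str]
    corr: np.ndarray          # clamped row-correlation matrix
    significant: np.ndarray   # boolean, symmetric, False on diagonal

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def edges_frame(self, significant_only: bool = False) -> pd.DataFrame:
        n = self.n_nodes
        iu, ju = np.triu_indices(n, k=1)
        df = pd.DataFrame({
            "node_a": np.asarray(self.labels, dtype=object)[iu],
            "node_b": np.asarray(self.labels, dtype=object)[ju],
            "r": self.corr[iu, ju],
            "significant": self.significant[iu, ju],
        })
        return df[df["significant"]].reset_index(drop=True) if significant_only else df

    def to_networkx(self, significant_only: bool = True) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.labels)
        mask = self.significant if significant_only else np.ones_like(self.significant)
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        for i, j in zip(iu, ju):
            if mask[i, j]:
                g.add_edge(self.labels[i], self.labels[j], r=float(self.corr[i, j]))
        return g


def row_correlations(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation between every pair of AWM rows over trait columns.

    Constant rows are dropped with a warning list returned alongside.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 trait columns for row correlations")
    arr = matrix.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    dropped = list(matrix.index[sd == 0])
    kept = matrix.loc[sd > 0]
    c = np.corrcoef(kept.to_numpy(dtype=float))
    if c.ndim == 0:  # single row
        c = np.ones((1, 1))
    return pd.DataFrame(c, index=kept.index, columns=kept.index), dropped


def _clamp(corr: np.ndarray) -> np.ndarray:
    c = np.array(corr, dtype=float, copy=True)
    c[c > _CLAMP] = _CLAMP
    c[c < -_CLAMP] = -_CLAMP
    np.fill_diagonal(c, 1.0)
    return c


def pcit_filter_reference(corr: np.ndarray) -> np.ndarray:
    """Naive triple-loop PCIT; the correctness oracle.

    Returns the boolean significance matrix (symmetric, False diagonal).
    """
    corr = np.asarray(corr, dtype=float)
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    n = corr.shape[0]
    c = _clamp(corr)
    rejected = np.zeros((n, n), dtype=bool)
    for x in range(n):
        for y in range(x + 1, n):
            rxy = c[x, y]
            for z in range(n):
                if z == x or z == y:
                    continue
                rxz, ryz = c[x, z], c[y, z]
                pxy = (rxy - rxz * ryz) / math.sqrt((1 - rxz**2) * (1 - ryz**2))
                pxz = (rxz - rxy * ryz) / math.sqrt((1 - rxy**2) * (1 - ryz**2))
                pyz = (ryz - rxy * rxz) / math.sqrt((1 - rxy**2) * (1 - rxz**2))
                s = 0.0
                k = 0
                if abs(rxy) >= _RTOL:
                    s += pxy / rxy
                    k += 1
                if abs(rxz) >= _RTOL:
                    s += pxz / rxz
                    k += 1
                if abs(ryz) >= _RTOL:
                    s += pyz / ryz
                    k += 1
                if k == 0:
                    continue
                eps = s / k
                if abs(rxy) < abs(eps * rxz) and abs(rxy) < abs(eps * ryz):
                    rejected[x, y] = rejected[y, x] = True
                    break
    sig = ~rejected & (c != 0.0)
    np.fill_diagonal(sig, False)
    return sig


def pcit_filter(
    corr: np.ndarray | pd.DataFrame,
    labels: list[str] | None = None,
    max_nodes: int = 3000,
    force: bool = False,
) -> PcitNetwork:
    """Vectorized PCIT filter; identical edge set to the naive reference.

    Refuses above ``max_nodes`` nodes unless ``force`` (trio enumeration is
    cubic).
    """
    if isinstance(corr, pd.DataFrame):
        labels = labels or [str(x) for x in corr.index]
        corr = corr.to_numpy(dtype=float)
    corr = np.asarray(corr, dtype=float)
    n = corr.shape[0]
    if labels is None:
        labels = [f"n{i}" for i in range(n)]
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if n > max_nodes and not force:
        raise ValueError(
            f"{n} nodes exceeds max_nodes={max_nodes}; pass force=True to run anyway"
        )

    c = _clamp(corr)
    rejected = np.zeros((n, n), dtype=bool)
    if n >= 3:
        one_minus_sq = 1.0 - c**2
        np.fill_diagonal(one_minus_sq, 1.0)  # unused at x==y, keep finite
        denom_xy = np.sqrt(one_minus_sq)     # sqrt(1 - r_xy^2) grid
        for z in range(n):
            rxz = c[:, z][:, None]            # broadcast over y
            ryz = c[z, :][None, :]            # broadcast over x
            t_xy = np.abs(c) >= _RTOL
            t_xz = np.abs(rxz) >= _RTOL
            t_yz = np.abs(ryz) >= _RTOL
            with np.errstate(divide="ignore", invalid="ignore"):
                # the z-th row/column contains degenerate self-trios; they
                # are masked out below, so inf/nan there are expected
                sxz = np.sqrt(1.0 - rxz**2)
                syz = np.sqrt(1.0 - ryz**2)
                pxy = (c - rxz * ryz) / (sxz * syz)
                pxz = (rxz - c * ryz) / (denom_xy * syz)
                pyz = (ryz - c * rxz) / (denom_xy * sxz)
                s = (
                    np.where(t_xy, pxy / np.where(t_xy, c, 1.0), 0.0)
                    + np.where(t_xz, pxz / np.where(t_xz, rxz, 1.0), 0.0)
                    + np.where(t_yz, pyz / np.where(t_yz, ryz, 1.0), 0.0)
                )
            k = t_xy.astype(int) + t_xz.astype(int) + t_yz.astype(int)
            valid = k > 0
            with np.errstate(invalid="ignore"):
                eps = np.where(valid, s / np.where(valid, k, 1), np.nan)
                rej = (valid & (np.abs(c) < np.abs(eps * rxz))
                       & (np.abs(c) < np.abs(eps * ryz)))
            rej[:, z] = False
            rej[z, :] = False
            rejected |= rej
    rejected |= rejected.T
    sig = ~rejected & (c != 0.0)
    np.fill_diagonal(sig, False)
    return PcitNetwork(labels=list(labels), corr=c, significant=sig)


def network_summary(net: PcitNetwork) -> dict:
    """Node/edge counts, degree distribution and connected components of the
    significant subgraph."""
    g = net.to_networkx(significant_only=True)
    degrees = sorted((d for _, d in g.degree()), reverse=True)
    components = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
    n_edges = g.number_of_edges()
    return {
        "n_nodes": net.n_nodes,
        "n_edges_total": int(net.n_nodes * (net.n_nodes - 1) // 2),
        "n_edges_significant": int(n_edges),
        "max_degree": int(degrees[0]) if degrees else 0,
        "mean_degree": float(np.mean(degrees)) if degrees else 0.0,
        "n_components": len(components),
        "component_sizes": components[:20],
        "n_isolated": int(sum(1 for d in degrees if d == 0)),
    }
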