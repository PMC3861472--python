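"""Hierarchical clustering of fold-change profiles with Cluster-3.0-style output.

Differentially expressed unitags are clustered on their signed fold changes
across contrasts.  A unitag absent from a contrast has a *missing* value —
never zero, since |FC| >= 1 by construction — and similarities are computed
pairwise-complete over the columns both rows share.  The default similarity
is the uncentered correlation with average linkage, matching the conventions
of the Cluster 3.0 / TreeView tool family, whose CDT/GTR files this module
writes (and re-reads).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SIMILARITIES = ("uncentered_correlation", "pearson", "euclidean")
LINKAGES = ("average", "complete", "single", "centroid")


def validate_fc_matrix(m: pd.DataFrame) -> pd.DataFrame:
    """Check an FC matrix: float values, |v| >= 1 where present, no empty column."""
    m = m.astype(float)
    values = m.to_numpy()
    present = ~np.isnan(values)
    if not present.any(axis=0).all():
        raise ValueError("FC matrix has a fully missing column")
    if np.any(np.abs(values[present]) < 1):
        raise ValueError("fold changes must satisfy |FC| >= 1 where present")
    return m


def _pair_distance(a: np.ndarray, b: np.ndarray, similarity: str) -> float:
    shared = ~np.isnan(a) & ~np.isnan(b)
    if not shared.any():
        warnings.warn("row pair shares no columns; similarity defined as 0")
        return 1.0
    x, y = a[shared], b[shared]
    if similarity == "uncentered_correlation":
        denom = np.sqrt((x * x).sum() * (y * y).sum())
        r = 0.0 if denom == 0 else float((x * y).sum() / denom)
        return 1.0 - r
    if similarity == "pearson":
        if len(x) < 2 or x.std() == 0 or y.std() == 0:
            return 1.0
        return 1.0 - float(np.corrcoef(x, y)[0, 1])
    if similarity == "euclidean":
        return float(((x - y) ** 2).mean())
    raise ValueError(f"unknown similarity: {similarity!r}")


def distance_matrix(m: pd.DataFrame, similarity: str = "uncentered_correlation") -> np.ndarray:
    """Pairwise-complete distance matrix between the rows of an FC matrix."""
    values = m.to_numpy(dtype=float)
    n = len(values)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _pair_distance(values[i], values[j], similarity)
    return d


@dataclass
class Dendrogram:
    """Agglomerative merge tree: scipy-style node ids (leaves 0..n-1, internal n..2n-2)."""

    merges: list[tuple[int, int, float]]
    leaf_order: list[int]
    row_ids: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.row_ids)

    def cut(self, height: float) -> dict[str, int]:
        """Flat cluster assignment from cutting the tree at *height*."""
        n = self.n_leaves
        parent = list(range(2 * n - 1))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for k, (a, b, h) in enumerate(self.merges):
            if h <= height:
                node = n + k
                parent[find(a)] = node
                parent[find(b)] = node
        roots: dict[int, int] = {}
        out = {}
        for leaf in self.leaf_order:
            root = find(leaf)
            if root not in roots:
                roots[root] = len(roots)
            out[self.row_ids[leaf]] = roots[root]
        return out

    def cophenetic(self) -> np.ndarray:
        """Cophenetic distance matrix (merge height joining each leaf pair)."""
        n = self.n_leaves
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        coph = np.zeros((n, n))
        for k, (a, b, h) in enumerate(self.merges):
            for i in members[a]:
                for j in members[b]:
                    coph[i, j] = coph[j, i] = h
            members[n + k] = members.pop(a) + members.pop(b)
        return coph


def cluster_rows(
    m: pd.DataFrame,
    similarity: str = "uncentered_correlation",
    linkage: str = "average",
) -> Dendrogram:
    """Agglomeratively cluster FC-matrix rows.

    Ties in the minimum pairwise distance break toward the smaller (i, j)
    node-id pair, making the tree deterministic.  Average linkage follows the
    Lance–Williams update (UPGMA) and therefore agrees with standard
    agglomerative implementations on the same distance matrix.
    """
    if similarity not in SIMILARITIES:
        raise ValueError(f"unknown similarity: {similarity!r}")
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage: {linkage!r}")
    m = validate_fc_matrix(m)
    n = len(m)
    if n < 2:
        raise ValueError("clustering needs at least two rows")
    values = m.to_numpy(dtype=float)
    d = distance_matrix(m, similarity)

    # active cluster state keyed by node id
    active: dict[int, dict] = {i: {"size": 1, "leaves": [i]} for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): d[i, j] for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        (a, b), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        ca, cb = active.pop(a), active.pop(b)
        merges.append((a, b, h))
        new = {"size": ca["size"] + cb["size"], "leaves": ca["leaves"] + cb["leaves"]}
        new_dist = {}
        for k in active:
            dak = dist[(min(a, k), max(a, k))]
            dbk = dist[(min(b, k), max(b, k))]
            if linkage == "average":
                nd = (ca["size"] * dak + cb["size"] * dbk) / new["size"]
            elif linkage == "complete":
                nd = max(dak, dbk)
            elif linkage == "single":
                nd = min(dak, dbk)
            else:  # centroid: distance between nan-mean member profiles
                pa = np.nanmean(values[new["leaves"]], axis=0)
                pk = np.nanmean(values[active[k]["leaves"]], axis=0)
                nd = _pair_distance(pa, pk, similarity)
            new_dist[(min(k, next_id), max(k, next_id))] = nd
        dist = {key: v for key, v in dist.items() if a not in key and b not in key}
        dist.update(new_dist)
        active[next_id] = new
        next_id += 1
    leaf_order = active[next_id - 1]["leaves"]
    return Dendrogram(merges=merges, leaf_order=leaf_order, row_ids=list(m.index))


def _gid(i: int) -> str:
    return f"GENE{i}X"


def _nid(k: int) -> str:
    return f"NODE{k}X"


def write_cdt_gtr(
    m: pd.DataFrame,
    dendrogram: Dendrogram,
    basename: str | Path,
) -> tuple[Path, Path]:
    """Write TreeView-compatible ``<basename>.cdt`` and ``<basename>.gtr`` files.

    The CDT carries GID/UNIQID/NAME/GWEIGHT columns and an EWEIGHT row, with
    data rows in dendrogram leaf order and missing values as empty fields; the
    GTR lists each merge as (node id, child id, child id, correlation), where
    correlation is 1 minus the merge height.
    """
    m = validate_fc_matrix(m)
    if sorted(dendrogram.row_ids) != sorted(m.index):
        raise ValueError("dendrogram leaves do not match matrix rows")
    base = Path(basename)
    cdt_path = base.with_suffix(".cdt")
    gtr_path = base.with_suffix(".gtr")

    n = dendrogram.n_leaves

    def node_name(node: int) -> str:
        return _gid(node) if node < n else _nid(node - n + 1)

    with open(gtr_path, "w") as fh:
        for k, (a, b, h) in enumerate(dendrogram.merges):
            fh.write(
                f"{_nid(k + 1)}\t{node_name(a)}\t{node_name(b)}\t{1.0 - h:.6f}\n"
            )

    cols = list(m.columns)
    with open(cdt_path, "w") as fh:
        fh.write("GID\tUNIQID\tNAME\tGWEIGHT\t" + "\t".join(map(str, cols)) + "\n")
        fh.write("EWEIGHT\t\t\t\t" + "\t".join("1" for _ in cols) + "\n")
        for leaf in dendrogram.leaf_order:
            rid = dendrogram.row_ids[leaf]
            vals = m.loc[rid]
            fields = ["" if pd.isna(v) else f"{v:.6g}" for v in vals]
            fh.write(f"{_gid(leaf)}\t{rid}\t{rid}\t1\t" + "\t".join(fields) + "\n")
    return cdt_path, gtr_path


def read_cdt(path: str | Path) -> pd.DataFrame:
    """Read a CDT file back into an FC matrix (rows in file order, NaN for blanks)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df = df[df["GID"] != "EWEIGHT"]
    data_cols = [c for c in df.columns if c not in ("GID", "UNIQID", "NAME", "GWEIGHT")]
    out = df.set_index("UNIQID")[data_cols].replace("", np.nan).astype(float)
    out.index.name = None
    return out


def cluster_assignments_tsv(
    dendrogram: Dendrogram, height: float, path: str | Path
) -> pd.DataFrame:
    """Write (and return) flat cluster membership from a tree cut."""
    assignment = dendrogram.cut(height)
    df = pd.DataFrame(
        [(rid, cl) for rid, cl in assignment.items()], columns=["tag", "cluster"]
    )
    df.to_csv(path, sep="\t", index=False)
    return df


def plot_heatmap(
    m: pd.DataFrame,
    dendrogram: Dendrogram,
    path: str | Path | None = None,
    vmax: float | None = None,
):
    """Optional red/black/green heat map of the clustered FC matrix.

    Missing cells render gray.  Requires matplotlib (the ``plot`` extra); the
    contractual outputs remain the CDT/GTR files.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    ordered = m.loc[[dendrogram.row_ids[i] for i in dendrogram.leaf_order]]
    values = ordered.to_numpy(dtype=float)
    cmap = LinearSegmentedColormap.from_list("rg", ["green", "black", "red"])
    cmap.set_bad("gray")
    lim = vmax if vmax is not None else np.nanmax(np.abs(values))
    fig, ax = plt.subplots(
        figsize=(1 + 0.5 * values.shape[1], 1 + 0.2 * values.shape[0])
    )
    ax.imshow(np.ma.masked_invalid(values), cmap=cmap, vmin=-lim, vmax=lim,
              aspect="auto", interpolation="nearest")
    ax.set_xticks(range(values.shape[1]), labels=ordered.columns, rotation=45,
                  ha="right", fontsize=7)
    ax.set_yticks(range(values.shape[0]), labels=ordered.index, fontsize=5)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
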