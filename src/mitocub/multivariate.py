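"""Correspondence analysis of RSCU matrices and hierarchical clustering.

CA is the standard chi-square decomposition: with P the table divided by
its grand total and r, c the marginals, the SVD of
``D_r^{-1/2} (P - r c^T) D_c^{-1/2}`` yields principal coordinates (scaled
by singular values) and per-dimension inertias (squared singular values).
Axis signs are fixed by forcing the largest-|loading| column positive on
each dimension, so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from mitocub.cub_metrics import RSCUVector

_SINGULAR_TOL = 1e-12

_DISTANCES = {"euclidean": "euclidean", "manhattan": "cityblock", "correlation": "correlation"}
_LINKAGES = ("average", "complete", "ward")


@dataclass
class CAResult:
    row_coords: pd.DataFrame  # rows x dims, principal coordinates
    col_coords: pd.DataFrame
    eigenvalues: np.ndarray  # per-dimension inertia
    pct_inertia: np.ndarray
    row_contrib: pd.DataFrame  # contribution fractions, columns sum to 1
    col_contrib: pd.DataFrame
    total_inertia: float
    dropped_columns: list[str] = field(default_factory=list)


@dataclass
class Dendrogram:
    leaves: list[str]
    heights: np.ndarray  # merge heights, one per internal node
    linkage: str
    distance: str
    newick: str
    linkage_matrix: np.ndarray = field(repr=False, default=None)


def build_rscu_matrix(
    rscu_vectors: list[RSCUVector], fill: float = 0.0
) -> pd.DataFrame:
    """Stack RSCU vectors into a rows x codons table; NA cells become ``fill``.

    Column order is the sorted union of codons present in the vectors,
    which is fixed for a given code and family policy.
    """
    if not rscu_vectors:
        raise ValueError("no RSCU vectors supplied")
    policies = {(v.code_id, v.family_policy) for v in rscu_vectors}
    if len(policies) > 1:
        raise ValueError("RSCU vectors mix genetic codes or family policies")
    columns = sorted({c for v in rscu_vectors for c in v.values})
    data = np.full((len(rscu_vectors), len(columns)), fill, dtype=float)
    col_idx = {c: j for j, c in enumerate(columns)}
    for i, v in enumerate(rscu_vectors):
        for codon, val in v.values.items():
            if val is not None:
                data[i, col_idx[codon]] = val
    index = [v.owner_id for v in rscu_vectors]
    return pd.DataFrame(data, index=index, columns=columns)


def correspondence_analysis(matrix: pd.DataFrame) -> CAResult:
    """Correspondence analysis of a non-negative table.

    All-zero columns are dropped (and recorded); all-zero rows are an error.
    When the table has no variation (identical rows) all coordinates are
    zero and total inertia is 0.
    """
    X = np.asarray(matrix, dtype=float)
    if (X < 0).any():
        raise ValueError("correspondence analysis requires non-negative entries")
    grand = X.sum()
    if grand <= 0:
        raise ValueError("grand total of the table is zero")
    if matrix.shape[0] < 2 or np.unique(X, axis=0).shape[0] < 2:
        raise ValueError("correspondence analysis needs at least 2 distinct rows")
    row_mass_raw = X.sum(axis=1)
    if (row_mass_raw == 0).any():
        bad = list(matrix.index[row_mass_raw == 0])
        raise ValueError(f"all-zero rows not allowed: {bad}")
    keep = X.sum(axis=0) > 0
    dropped = [str(c) for c in matrix.columns[~keep]]
    X = X[:, keep]
    columns = list(matrix.columns[keep])

    P = X / grand
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    keep_d = sv > _SINGULAR_TOL
    U, sv, Vt = U[:, keep_d], sv[keep_d], Vt[keep_d, :]
    n_dims = sv.size

    if n_dims == 0:  # no variation at all
        dims = ["dim1"]
        zero_rows = pd.DataFrame(0.0, index=matrix.index, columns=dims)
        zero_cols = pd.DataFrame(0.0, index=columns, columns=dims)
        return CAResult(
            row_coords=zero_rows,
            col_coords=zero_cols,
            eigenvalues=np.zeros(1),
            pct_inertia=np.zeros(1),
            row_contrib=zero_rows.copy(),
            col_contrib=zero_cols.copy(),
            total_inertia=0.0,
            dropped_columns=dropped,
        )

    row_coords = (U / np.sqrt(r)[:, None]) * sv[None, :]
    col_coords = (Vt.T / np.sqrt(c)[:, None]) * sv[None, :]
    # deterministic axis signs: largest-|loading| column positive per dim
    for d in range(n_dims):
        j = int(np.argmax(np.abs(col_coords[:, d])))
        if col_coords[j, d] < 0:
            col_coords[:, d] *= -1
            row_coords[:, d] *= -1

    eig = sv ** 2
    total = float(eig.sum())
    row_contrib = r[:, None] * row_coords ** 2 / eig[None, :]
    col_contrib = c[:, None] * col_coords ** 2 / eig[None, :]

    dims = [f"dim{i + 1}" for i in range(n_dims)]
    return CAResult(
        row_coords=pd.DataFrame(row_coords, index=matrix.index, columns=dims),
        col_coords=pd.DataFrame(col_coords, index=columns, columns=dims),
        eigenvalues=eig,
        pct_inertia=100.0 * eig / total,
        row_contrib=pd.DataFrame(row_contrib, index=matrix.index, columns=dims),
        col_contrib=pd.DataFrame(col_contrib, index=columns, columns=dims),
        total_inertia=total,
        dropped_columns=dropped,
    )


def _to_newick(node, leaves: list[str], parent_height: float) -> str:
    length = parent_height - node.dist
    if node.is_leaf():
        return f"{leaves[node.id]}:{length:.6g}"
    left = _to_newick(node.get_left(), leaves, node.dist)
    right = _to_newick(node.get_right(), leaves, node.dist)
    return f"({left},{right}):{length:.6g}"


def hierarchical_cluster(
    profiles: list[RSCUVector] | pd.DataFrame,
    distance: str = "euclidean",
    linkage: str = "average",
) -> Dendrogram:
    """Agglomerative clustering of genome-level codon usage profiles.

    Rows are sorted by id before clustering so equal-distance ties break
    lexicographically.  Branch lengths in the Newick string are differences
    of merge heights.
    """
    if distance not in _DISTANCES:
        raise ValueError(f"distance must be one of {sorted(_DISTANCES)}")
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {sorted(_LINKAGES)}")
    if isinstance(profiles, pd.DataFrame):
        matrix = profiles
    else:
        matrix = build_rscu_matrix(profiles)
    if matrix.shape[0] < 2:
        raise ValueError("clustering needs at least 2 profiles")
    ids = [str(i) for i in matrix.index]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate profile ids")
    if matrix.isna().any().any():
        raise ValueError("NA cells in profile matrix; fill before clustering")
    matrix = matrix.loc[sorted(ids)]
    ids = [str(i) for i in matrix.index]
    if linkage == "ward" and distance != "euclidean":
        raise ValueError("ward linkage requires euclidean distance")
    d = pdist(np.asarray(matrix, dtype=float), metric=_DISTANCES[distance])
    Z = hierarchy.linkage(d, method=linkage)
    root = hierarchy.to_tree(Z)
    newick = "(" + ",".join(
        _to_newick(child, ids, root.dist) for child in (root.get_left(), root.get_right())
    ) + ");"
    return Dendrogram(
        leaves=ids,
        heights=Z[:, 2].copy(),
        linkage=linkage,
        distance=distance,
        newick=newick,
        linkage_matrix=Z,
    )
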