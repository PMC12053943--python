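"""Celiac-toxic-motif (CTM) mapping and abundance summation.

An identified peptide "contains" a T-cell epitope when it totally
encompasses a CD-active motif, i.e. the motif is a contiguous substring
of the peptide (equality counts).  Per motif and sample, the normalized
abundances of all encompassing peptides are summed; overlapping or
nested motifs each receive the peptide's full abundance (no
apportioning).

Matching is on unmodified stripped sequences.  ``equate_eq=True``
relaxes E to match Q (for search engines that report deamidated
residues as E); off by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .curation import ReplicateDesign
from .quantify import peptide_sample_abundance
from .seqio import MotifRecord


@dataclass(frozen=True)
class MotifHit:
    """One (motif, peptide) encompassment in one sample."""

    motif_id: str
    peptide: str
    parents: frozenset[str]
    sample_id: str
    summed_normalized_abundance: float


def find_encompassing(
    peptides: Iterable[str],
    motifs: Sequence[MotifRecord],
    equate_eq: bool = False,
) -> list[tuple[str, str]]:
    """All (motif_id, peptide) pairs where the motif is a substring.

    A peptide may hit several motifs and a motif several peptides; a
    peptide equal to the motif is a hit; a motif extending past either
    peptide end is not.
    """

    def norm(s: str) -> str:
        return s.replace("E", "Q") if equate_eq else s

    pairs = []
    peps = sorted(set(peptides))
    for m in motifs:
        mseq = norm(m.sequence)
        for pep in peps:
            if mseq in norm(pep):
                pairs.append((m.motif_id, pep))
    return pairs


def motif_abundance(
    pairs: Sequence[tuple[str, str]],
    obs: pd.DataFrame,
    design: ReplicateDesign,
) -> pd.DataFrame:
    """Motif x sample matrix of summed normalized abundances.

    ``cell(m, s)`` sums, over the peptides encompassing motif ``m``, each
    peptide's sample-level normalized abundance (mean over the sample's
    runs where observed).  Motifs with no observed encompassing peptide
    are omitted.
    """
    if "normalized_abundance" not in obs.columns:
        raise ValueError("observations must be normalized first")
    pep_sample = peptide_sample_abundance(obs, design)
    rows: dict[str, pd.Series] = {}
    for motif_id, pep in pairs:
        if pep not in pep_sample.index:
            continue
        contrib = pep_sample.loc[pep].fillna(0.0)
        if motif_id in rows:
            rows[motif_id] = rows[motif_id] + contrib
        else:
            rows[motif_id] = contrib.copy()
    if not rows:
        return pd.DataFrame(columns=pep_sample.columns)
    mat = pd.DataFrame(rows).T.sort_index()
    mat.index.name = "motif_id"
    return mat


def autoscale_features(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each feature row: (x - mean) / sample SD (ddof=1).

    Constant rows are dropped with a warning.  Requires >= 2 samples.
    """
    if matrix.shape[1] < 2:
        raise ValueError("auto-scaling requires at least 2 samples")
    means = matrix.mean(axis=1)
    sds = matrix.std(axis=1, ddof=1)
    constant = sds == 0
    if constant.any():
        warnings.warn(
            f"dropping {int(constant.sum())} constant feature row(s): "
            f"{list(matrix.index[constant])}"
        )
    kept = matrix.loc[~constant]
    return kept.sub(means[~constant], axis=0).div(sds[~constant], axis=0)


@dataclass
class ClusterResult:
    """Agglomerative clustering of an abundance matrix (rows and columns)."""

    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list
    col_order: list

    def row_newick(self, matrix_index: Sequence) -> str:
        return linkage_to_newick(self.row_linkage, [str(x) for x in matrix_index])

    def col_newick(self, matrix_columns: Sequence) -> str:
        return linkage_to_newick(self.col_linkage, [str(x) for x in matrix_columns])


def cluster(
    matrix: pd.DataFrame,
    distance: str = "euclidean",
    linkage: str = "ward",
) -> ClusterResult:
    """Deterministic hierarchical clustering of rows and columns.

    Euclidean distance with Ward linkage by default (``average`` and
    ``complete`` also accepted).  NaN cells are an error: impute or drop
    upstream.
    """
    if distance != "euclidean":
        raise ValueError(f"unsupported distance {distance!r}")
    if linkage not in {"ward", "average", "complete"}:
        raise ValueError(f"unsupported linkage {linkage!r}")
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("clustering requires at least 2 rows and 2 columns")
    if matrix.isna().any().any():
        raise ValueError("matrix contains NaN cells; impute or drop upstream")
    vals = matrix.to_numpy(dtype=float)
    row_link = hierarchy.linkage(pdist(vals, metric=distance), method=linkage)
    col_link = hierarchy.linkage(pdist(vals.T, metric=distance), method=linkage)
    row_order = [matrix.index[i] for i in hierarchy.leaves_list(row_link)]
    col_order = [matrix.columns[i] for i in hierarchy.leaves_list(col_link)]
    return ClusterResult(row_link, col_link, row_order, col_order)


def linkage_to_newick(linkage_matrix: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string."""
    tree = hierarchy.to_tree(linkage_matrix)

    def _render(node, parent_dist: float) -> str:
        length = parent_dist - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = _render(node.left, node.dist)
        right = _render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return _render(tree, tree.dist) + ";"
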