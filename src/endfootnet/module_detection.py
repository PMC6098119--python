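"""Module detection on TOM dissimilarity: clustering, eigengenes, hub scores.

Average-linkage hierarchical clustering of the TOM dissimilarity is cut at a
fixed height (static tree cut, default 0.90 of the dendrogram range); the
static cut is fully reproducible, which is why it is preferred here over
dynamic branch-cutting heuristics. The default sits below the top decile of
merge heights, where unclustered background genes attach to genuine
co-expression branches in TOM dissimilarity. Branches smaller than the
minimum module size (default 30) become label 0 ("unassigned") and are
excluded from eigengene computation and the downstream screen.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from endfootnet.data_io import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class ModulePartition:
    """Gene -> module labels with per-module eigengenes and hub scores.

    Labels are integers renumbered by decreasing module size; 0 means
    unassigned. ``eigengenes`` is modules x subjects (unit-norm rows,
    sign-oriented); ``kme`` is genes x modules Pearson correlations;
    ``kwithin`` is each gene's summed adjacency to same-module genes.
    """

    gene_ids: list[str]
    labels: np.ndarray
    min_module_size: int
    eigengenes: pd.DataFrame | None = None
    kme: pd.DataFrame | None = None
    kwithin: pd.Series | None = None
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.labels):
            raise ValueError("labels and gene_ids length mismatch")

    @property
    def module_labels(self) -> list[int]:
        """Non-zero module labels, ascending (1 is the largest module)."""
        return sorted(set(self.labels.tolist()) - {0})

    def members(self, label: int) -> list[str]:
        return [g for g, l in zip(self.gene_ids, self.labels) if l == label]

    def label_of(self, gene_id: str) -> int:
        return int(self.labels[self.gene_ids.index(gene_id)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": self.gene_ids, "module": self.labels.astype(int)})


def cluster_modules(
    dissimilarity: np.ndarray,
    gene_ids: list[str],
    min_module_size: int = 30,
    cut_height_frac: float = 0.90,
    linkage_method: str = "average",
) -> ModulePartition:
    """Static-height tree cut of the TOM dissimilarity into modules.

    The dendrogram is cut at ``cut_height_frac`` of its maximum merge
    height; branches below ``min_module_size`` members are pooled into
    label 0, and surviving modules are renumbered by decreasing size
    (ties broken by first gene position, for determinism).
    """
    d = np.asarray(dissimilarity, dtype=float)
    n = d.shape[0]
    if n != len(gene_ids):
        raise ValueError("dissimilarity size does not match gene_ids")
    if n < min_module_size:
        log.warning("fewer genes (%d) than min module size (%d); all unassigned", n, min_module_size)
        return ModulePartition(gene_ids, np.zeros(n, dtype=int), min_module_size)
    sym = 0.5 * (d + d.T)
    np.fill_diagonal(sym, 0.0)
    z = linkage(squareform(sym, checks=False), method=linkage_method)
    cut = cut_height_frac * z[:, 2].max()
    raw = fcluster(z, t=cut, criterion="distance")
    labels = _renumber(raw, min_module_size)
    return ModulePartition(gene_ids, labels, min_module_size)


def _renumber(raw: np.ndarray, min_module_size: int) -> np.ndarray:
    """Drop small branches to 0 and renumber the rest by decreasing size."""
    labels = np.zeros(raw.size, dtype=int)
    sizes: list[tuple[int, int, int]] = []  # (-size, first_pos, raw_label)
    for lab in np.unique(raw):
        pos = np.flatnonzero(raw == lab)
        if pos.size >= min_module_size:
            sizes.append((-pos.size, int(pos[0]), int(lab)))
    for new, (_, _, lab) in enumerate(sorted(sizes), start=1):
        labels[raw == lab] = new
    return labels


def module_eigengene(expr: ExpressionMatrix, member_genes: list[str]) -> np.ndarray:
    """First principal component of the standardized member-gene expression.

    Genes are z-scored across subjects before the SVD; the unit-norm
    subject-indexed component is sign-oriented so that its mean correlation
    with member expression is non-negative.
    """
    sub = expr.values.loc[member_genes].to_numpy(dtype=float)
    sd = sub.std(axis=1, ddof=0)
    # relative tolerance: a gene is constant if its spread is at rounding level
    keep = sd > 1e-12 * np.maximum(1.0, np.abs(sub).max(axis=1))
    if keep.sum() < 2:
        raise ValueError("need at least 2 non-constant member genes")
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} constant genes dropped from eigengene")
        sub = sub[keep]
        sd = sd[keep]
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    # first right singular vector = first PC over subjects
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    e = vt[0]
    cors = (z @ e) / (np.linalg.norm(z, axis=1) * np.linalg.norm(e))
    if cors.mean() < 0:
        e = -e
    return e


def compute_eigengenes(expr: ExpressionMatrix, partition: ModulePartition) -> ModulePartition:
    """Fill in eigengenes for every non-zero module; returns the partition."""
    rows = {}
    for lab in partition.module_labels:
        rows[lab] = module_eigengene(expr, partition.members(lab))
    partition.eigengenes = pd.DataFrame.from_dict(rows, orient="index", columns=expr.sample_ids)
    partition.eigengenes.index.name = "module"
    partition.sample_ids = expr.sample_ids
    return partition


def module_membership(expr: ExpressionMatrix, partition: ModulePartition) -> pd.DataFrame:
    """kME: Pearson correlation of every gene with every module eigengene.

    Constant genes get NaN. The result (genes x modules) is stored on the
    partition; hub ranking within a module is own-module kME descending.
    """
    if partition.eigengenes is None:
        compute_eigengenes(expr, partition)
    x = expr.values.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(xc, axis=1)
    e = partition.eigengenes.to_numpy(dtype=float)
    ec = e - e.mean(axis=1, keepdims=True)
    en = np.linalg.norm(ec, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        kme = (xc @ ec.T) / np.outer(xn, en)
    kme[xn == 0, :] = np.nan
    frame = pd.DataFrame(kme, index=expr.gene_ids, columns=partition.eigengenes.index)
    partition.kme = frame
    return frame


def own_module_kme(partition: ModulePartition) -> pd.Series:
    """Each assigned gene's kME with its own module eigengene."""
    if partition.kme is None:
        raise ValueError("compute module_membership first")
    out = {}
    for g, lab in zip(partition.gene_ids, partition.labels):
        if lab != 0:
            out[g] = float(partition.kme.loc[g, lab])
    return pd.Series(out, name="kme_own")


def intramodular_connectivity(adjacency: np.ndarray, partition: ModulePartition) -> pd.Series:
    """kWithin_i: summed adjacency of gene i to the other genes of its module."""
    a = np.asarray(adjacency, dtype=float)
    labels = partition.labels
    k = np.zeros(len(labels))
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        block = a[np.ix_(idx, idx)]
        k[idx] = block.sum(axis=1) - np.diag(block)
    s = pd.Series(k, index=partition.gene_ids, name="kwithin")
    partition.kwithin = s
    return s
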