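"""Weighted co-expression network construction.

The chain is: biweight midcorrelation between gene pairs -> soft-threshold
power chosen by scale-free topology fit -> unsigned adjacency a_ij = |r|^beta
-> topological overlap matrix (TOM) -> dissimilarity 1 - TOM. A consensus
network across subject groups is the component-wise minimum of their TOMs.

Matrices are dense numpy arrays; at the gene counts this pipeline targets
(<= ~7,000 after filtering) the O(n^2) memory and BLAS-backed O(n^3) TOM
product are comfortable on a single CPU.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from endfootnet.data_io import ExpressionMatrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# biweight midcorrelation


def _bicor_prepare(x: np.ndarray) -> np.ndarray:
    """Median-centred, biweight-weighted, unit-norm version of ``x``.

    The correlation of two vectors is the dot product of their prepared
    forms. Weights follow the standard biweight definition
    u_i = (x_i - med) / (9 MAD), w_i = (1 - u_i^2)^2 1[|u_i| < 1].
    MAD = 0 (or a constant vector) falls back to Pearson weighting.
    """
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0.0:
        if np.ptp(x) == 0.0:
            warnings.warn("constant vector in bicor; correlation set to 0")
            return np.zeros_like(x)
        warnings.warn("MAD = 0 in bicor; falling back to Pearson weighting")
        dev = x - x.mean()
        return dev / np.linalg.norm(dev)
    u = (x - med) / (9.0 * mad)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    g = (x - med) * w
    norm = np.linalg.norm(g)
    if norm == 0.0:  # cannot happen for mad > 0: the median itself has weight 1
        raise AssertionError("degenerate biweight norm")
    return g / norm


def biweight_midcorrelation(x: np.ndarray, y: np.ndarray) -> float:
    """Biweight midcorrelation of two equal-length vectors, in [-1, 1].

    Computed as <gx, gy> / sqrt(<gx, gx> <gy, gy>) on the weighted deviations,
    so (anti)identical vectors give exactly +/-1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    gx = _bicor_prepare(x)
    gy = _bicor_prepare(y)
    den = np.sqrt((gx @ gx) * (gy @ gy))
    if den == 0.0:
        return 0.0
    r = float((gx @ gy) / den)
    return float(np.clip(r, -1.0, 1.0))


def bicor_matrix(expr: ExpressionMatrix | pd.DataFrame | np.ndarray) -> np.ndarray:
    """Gene x gene biweight midcorrelation matrix (rows = genes)."""
    if isinstance(expr, ExpressionMatrix):
        data = expr.values.to_numpy(dtype=float)
    elif isinstance(expr, pd.DataFrame):
        data = expr.to_numpy(dtype=float)
    else:
        data = np.asarray(expr, dtype=float)
    if data.shape[1] < 4:
        raise ValueError("need at least 4 samples")
    prepared = np.empty_like(data)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(data.shape[0]):
            prepared[i] = _bicor_prepare(data[i])
    r = prepared @ prepared.T
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return r


# ---------------------------------------------------------------------------
# soft threshold


def _scale_free_fit(k: np.ndarray, n_bins: int) -> tuple[float, float]:
    """(signed R^2, slope) of the log-log connectivity-distribution fit.

    Connectivities are split into equal-occupancy bins; the log10 density
    (count / bin width) is regressed on the log10 mean connectivity per bin.
    Signed R^2 is -sign(slope) * R^2, so a scale-free (decreasing) density
    scores positively.
    """
    k = k[k > 0]
    if k.size < n_bins or np.ptp(k) == 0.0:
        return np.nan, np.nan
    edges = np.unique(np.quantile(k, np.linspace(0, 1, n_bins + 1)))
    if edges.size < 3:
        return np.nan, np.nan
    counts, _ = np.histogram(k, bins=edges)
    widths = np.diff(edges)
    mids = np.array(
        [k[(k >= lo) & (k <= hi)].mean() for lo, hi in zip(edges[:-1], edges[1:])]
    )
    ok = counts > 0
    x = np.log10(mids[ok])
    y = np.log10(counts[ok] / widths[ok])
    if x.size < 3 or np.ptp(x) == 0.0:
        return np.nan, np.nan
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0.0:
        return np.nan, slope
    r2 = 1.0 - np.sum(resid**2) / ss_tot
    return float(-np.sign(slope) * r2), float(slope)


def pick_soft_threshold(
    cor_matrix: np.ndarray,
    candidate_powers: tuple[int, ...] = tuple(range(1, 13)),
    r2_target: float = 0.8,
    n_bins: int = 10,
    power_bounds: tuple[int, int] = (4, 7),
    override: int | None = None,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft-threshold power by scale-free topology fit.

    The chosen beta is the smallest candidate whose signed R^2 reaches
    ``r2_target``, clamped into ``power_bounds``; if no candidate reaches the
    target the best-fitting power inside the bounds is used with a warning.
    ``override`` short-circuits the rule (reproduces a manual choice). The
    full profile (power, signed R^2, slope, mean connectivity) is always
    returned for inspection.
    """
    absr = np.abs(np.asarray(cor_matrix, dtype=float))
    rows = []
    for beta in candidate_powers:
        a = absr**beta
        k = a.sum(axis=1) - 1.0  # exclude self (|r_ii| = 1)
        r2, slope = _scale_free_fit(k, n_bins)
        if np.isnan(r2):
            log.warning("degenerate connectivity distribution at power %d; skipped", beta)
        rows.append(
            {"power": beta, "signed_r2": r2, "slope": slope, "mean_k": float(k.mean())}
        )
    profile = pd.DataFrame(rows)
    if override is not None:
        return int(override), profile
    lo, hi = power_bounds
    qualifying = profile[profile["signed_r2"] >= r2_target]
    if len(qualifying):
        beta = int(qualifying["power"].iloc[0])
        return int(np.clip(beta, lo, hi)), profile
    in_bounds = profile[(profile["power"] >= lo) & (profile["power"] <= hi)]
    log.warning(
        "no candidate power reached scale-free R^2 >= %.2f; "
        "falling back to best fit within [%d, %d]",
        r2_target,
        lo,
        hi,
    )
    if in_bounds["signed_r2"].isna().all():
        return lo, profile
    return int(in_bounds.loc[in_bounds["signed_r2"].idxmax(), "power"]), profile


# ---------------------------------------------------------------------------
# adjacency / TOM


def adjacency(cor_matrix: np.ndarray, beta: int) -> np.ndarray:
    """Unsigned soft-threshold adjacency a_ij = |r_ij|^beta, unit diagonal."""
    if beta < 1 or int(beta) != beta:
        raise ValueError(f"beta must be a positive integer, got {beta}")
    a = np.abs(np.asarray(cor_matrix, dtype=float)) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def topological_overlap(adj: np.ndarray) -> np.ndarray:
    """Unsigned topological overlap matrix.

    t_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j, where
    L_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_{u != i} a_iu; t_ii = 1.
    """
    a = np.asarray(adj, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1.0 + 1e-12:
        raise ValueError("adjacency values must lie in [0, 1]")
    if not np.allclose(np.diag(a), 1.0):
        raise ValueError("adjacency diagonal must be 1")
    k = a.sum(axis=1) - 1.0
    # (A @ A)_ij includes u = i and u = j, each contributing a_ij; remove both
    numer = a @ a - 2.0 * a + a  # = L + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    np.fill_diagonal(denom, 1.0)  # diagonal is overwritten below
    assert (denom > 0).all(), "TOM denominator must be positive for valid adjacency"
    t = numer / denom
    np.fill_diagonal(t, 1.0)
    np.clip(t, 0.0, 1.0, out=t)
    return t


def consensus_tom(tom_list: list[np.ndarray], gene_ids: list[list[str]] | None = None) -> np.ndarray:
    """Component-wise minimum of >= 2 TOMs over identical gene sets."""
    if len(tom_list) < 2:
        raise ValueError("consensus requires at least 2 TOMs")
    if gene_ids is not None:
        first = gene_ids[0]
        for ids in gene_ids[1:]:
            if list(ids) != list(first):
                raise ValueError("gene sets differ between TOMs")
    shape = tom_list[0].shape
    for t in tom_list[1:]:
        if t.shape != shape:
            raise ValueError("TOM shapes differ")
    return np.minimum.reduce([np.asarray(t, dtype=float) for t in tom_list])


# ---------------------------------------------------------------------------
# container


@dataclass
class GeneNetwork:
    """All matrices for one region's co-expression network."""

    gene_ids: list[str]
    correlation: np.ndarray
    soft_power: int
    adjacency: np.ndarray
    tom: np.ndarray
    scale_free_profile: pd.DataFrame = field(repr=False)

    @property
    def dissimilarity(self) -> np.ndarray:
        return 1.0 - self.tom


def build_network(
    expr: ExpressionMatrix,
    power: int | None = None,
    candidate_powers: tuple[int, ...] = tuple(range(1, 13)),
    r2_target: float = 0.8,
    n_bins: int = 10,
) -> GeneNetwork:
    """Full correlation -> power -> adjacency -> TOM chain for one region."""
    cor = bicor_matrix(expr)
    beta, profile = pick_soft_threshold(
        cor, candidate_powers, r2_target=r2_target, n_bins=n_bins, override=power
    )
    adj = adjacency(cor, beta)
    tom = topological_overlap(adj)
    return GeneNetwork(
        gene_ids=expr.gene_ids,
        correlation=cor,
        soft_power=beta,
        adjacency=adj,
        tom=tom,
        scale_free_profile=profile,
    )
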