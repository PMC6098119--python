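"""Endfoot-enriched cluster identification and the candidate-gene cascade.

The five established perivascular endfoot genes — AQP4 (the astroglial water
channel) and the dystrophin-associated complex members SNTA1, DTNA, DAG1 and
DMD — serve as bait: the module containing the greatest number of them in a
region is that region's "endfoot-enriched" cluster. Candidate genes are the
other members of those clusters that (a) derive >= 50% of their total
expression from astrocytes, and (b) show Pearson r above a conservative
threshold (default 0.65) with at least ``min_dac`` of the bait genes in at
least ``min_regions`` of the analyzed gray-matter regions.

The screen deliberately uses Pearson correlation (not the biweight
midcorrelation used for network construction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from endfootnet.data_io import ExpressionMatrix
from endfootnet.module_detection import ModulePartition, own_module_kme

log = logging.getLogger(__name__)

#: Established endfoot genes, symbol -> Entrez ID.
ESTABLISHED_ENDFOOT_GENES = {
    "AQP4": "361",
    "SNTA1": "6640",
    "DTNA": "1837",
    "DAG1": "1605",
    "DMD": "1756",
}

#: Maximum number of distinct assigned modules the bait genes may occupy
#: before a region's clustering is called incoherent.
INCOHERENT_MODULE_SPREAD = 4


@dataclass
class EndfootClusterResult:
    """Outcome of locating the endfoot-enriched cluster in one region."""

    region: str
    label: int  # 0 when incoherent
    established_modules: dict[str, int]  # bait gene -> module label
    n_established_in_cluster: int
    coherent: bool
    tie_broken: bool = False


def find_endfoot_cluster(
    partition: ModulePartition,
    established_ids: list[str] | None = None,
    region: str = "",
) -> EndfootClusterResult:
    """Locate the module with the most established endfoot genes.

    Ties are broken by the higher mean own-module kME of the bait genes,
    then by larger module size. A region is flagged incoherent (no endfoot
    cluster) when no bait gene lands in an assigned module, or the bait
    genes scatter across >= 4 distinct assigned modules.
    """
    if established_ids is None:
        established_ids = list(ESTABLISHED_ENDFOOT_GENES.values())
    present = [g for g in established_ids if g in partition.gene_ids]
    modules = {g: partition.label_of(g) for g in present}
    assigned = {g: m for g, m in modules.items() if m != 0}
    distinct = set(assigned.values())
    if not assigned or len(distinct) >= INCOHERENT_MODULE_SPREAD:
        log.warning("region %s: incoherent clustering of established endfoot genes", region)
        return EndfootClusterResult(region, 0, modules, 0, coherent=False)
    counts: dict[int, int] = {}
    for m in assigned.values():
        counts[m] = counts.get(m, 0) + 1
    best = max(counts.values())
    tied = sorted(lab for lab, c in counts.items() if c == best)
    tie_broken = False
    if len(tied) > 1:
        tie_broken = True
        if partition.kme is None:
            raise ValueError("kME required to break an endfoot-cluster tie")
        kme = own_module_kme(partition)

        def tie_key(lab: int) -> tuple[float, int, int]:
            genes = [g for g, m in assigned.items() if m == lab]
            mean_kme = float(np.mean([kme.get(g, np.nan) for g in genes]))
            return (mean_kme, len(partition.members(lab)), -lab)

        label = max(tied, key=tie_key)
        log.info("region %s: endfoot-cluster tie among %s broken to %d", region, tied, label)
    else:
        label = tied[0]
    return EndfootClusterResult(
        region=region,
        label=int(label),
        established_modules=modules,
        n_established_in_cluster=best,
        coherent=True,
        tie_broken=tie_broken,
    )


def dac_coclustering_report(
    partitions: dict[str, ModulePartition],
    established_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-region table of where each established endfoot gene assembled.

    One row per (region, bait gene): its module, the region's endfoot-cluster
    label, whether the gene sits in it, the region's coherence flag, and the
    cluster's top hub genes by own-module kME.
    """
    if established_ids is None:
        established_ids = list(ESTABLISHED_ENDFOOT_GENES.values())
    rows = []
    for region, part in partitions.items():
        res = find_endfoot_cluster(part, established_ids, region=region)
        hubs = ""
        if res.coherent and part.kme is not None:
            kme = own_module_kme(part)
            members = [g for g in part.members(res.label) if g in kme.index]
            top = kme.loc[members].sort_values(ascending=False).head(5)
            hubs = ",".join(top.index)
        for g in established_ids:
            rows.append(
                {
                    "region": region,
                    "gene_id": g,
                    "module": res.established_modules.get(g, -1),
                    "endfoot_label": res.label,
                    "in_endfoot_cluster": res.established_modules.get(g) == res.label
                    and res.coherent,
                    "coherent": res.coherent,
                    "endfoot_hub_genes": hubs,
                }
            )
    return pd.DataFrame(rows)


def _pearson_to_baits(
    expr: ExpressionMatrix, genes: list[str], baits: list[str]
) -> pd.DataFrame:
    """Pearson r across subjects between each gene and each bait (NaN if absent)."""
    out = pd.DataFrame(np.nan, index=genes, columns=baits)
    present_baits = [b for b in baits if b in expr.values.index]
    present_genes = [g for g in genes if g in expr.values.index]
    if not present_baits or not present_genes:
        return out
    x = expr.values.loc[present_genes].to_numpy(dtype=float)
    y = expr.values.loc[present_baits].to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(xc, axis=1)
    yn = np.linalg.norm(yc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc.T) / np.outer(xn, yn)
    out.loc[present_genes, present_baits] = r
    return out


def correlation_p_value(r: float, n: int) -> float:
    """Nominal two-sided p for a Pearson correlation (t distribution, n-2 df)."""
    if not np.isfinite(r) or n < 3 or abs(r) >= 1:
        return 0.0 if abs(r) >= 1 else np.nan
    t = r * np.sqrt((n - 2) / (1 - r**2))
    return float(2 * stats.t.sf(abs(t), n - 2))


def candidate_screen(
    exprs: dict[str, ExpressionMatrix],
    partitions: dict[str, ModulePartition],
    astro_fractions: pd.Series,
    r_threshold: float = 0.65,
    min_dac: int = 2,
    min_regions: int = 2,
    astro_threshold: float = 0.5,
    established_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run the full candidate cascade over the coherent gray-matter regions.

    Returns a per-gene report frame (one row per endfoot-cluster gene across
    the union of regions, bait genes excluded) and a summary dict with the
    union counts: genes in the cluster in >= 1 region, in > 1 region, and
    the number of passing candidates. ``pass`` requires astrocyte fraction
    >= ``astro_threshold`` and r > ``r_threshold`` with >= ``min_dac`` bait
    genes in >= ``min_regions`` regions.
    """
    if not 0 < r_threshold < 1:
        raise ValueError(f"r_threshold must lie in (0, 1), got {r_threshold}")
    if established_ids is None:
        established_ids = list(ESTABLISHED_ENDFOOT_GENES.values())
    results = {
        region: find_endfoot_cluster(partitions[region], established_ids, region=region)
        for region in partitions
    }
    coherent = {r: res for r, res in results.items() if res.coherent}
    if len(coherent) < 2:
        raise ValueError(
            f"need >= 2 regions with coherent endfoot clusters, got {len(coherent)}"
        )
    membership: dict[str, set[str]] = {}
    for region, res in coherent.items():
        membership[region] = set(partitions[region].members(res.label)) - set(established_ids)
    universe = sorted(set().union(*membership.values()))
    n_in_any = len(universe)
    n_in_multiple = sum(
        1 for g in universe if sum(g in mem for mem in membership.values()) > 1
    )

    regions = sorted(coherent)
    r_tables = {
        region: _pearson_to_baits(exprs[region], universe, established_ids)
        for region in regions
    }
    kme_mean = pd.Series(
        {
            g: np.nanmean(
                [
                    partitions[r].kme.loc[g, coherent[r].label]
                    for r in regions
                    if g in membership[r] and partitions[r].kme is not None
                ]
                or [np.nan]
            )
            for g in universe
        }
    )

    rows = []
    for g in universe:
        row: dict = {"gene_id": g}
        n_supported = 0
        for region in regions:
            r_vals = r_tables[region].loc[g]
            n_dac = int((r_vals > r_threshold).sum())
            supported = n_dac >= min_dac
            n_supported += supported
            row[f"in_cluster_{region}"] = g in membership[region]
            row[f"n_dac_correlated_{region}"] = n_dac
            for bait_sym, bait_id in _bait_names(established_ids).items():
                row[f"r_{bait_sym}_{region}"] = r_vals[bait_id]
        frac = astro_fractions.get(g, np.nan)
        n_in_cluster = sum(g in membership[r] for r in regions)
        row["n_regions_in_cluster"] = n_in_cluster
        row["astro_fraction"] = frac
        row["n_regions_supported"] = n_supported
        row["pass"] = bool(
            np.isfinite(frac)
            and frac >= astro_threshold
            and n_supported >= min_regions
            and n_in_cluster >= 1
        )
        row["mean_kme"] = kme_mean[g]
        rows.append(row)
    report = pd.DataFrame(rows)
    if len(report):
        report = report.sort_values(
            ["pass", "mean_kme"], ascending=[False, False], kind="mergesort"
        ).reset_index(drop=True)
        report["hub_rank"] = (
            report["mean_kme"].rank(ascending=False, method="first").astype(int)
        )
    assert not set(established_ids) & set(report.get("gene_id", [])), (
        "bait genes must not appear in the candidate list"
    )
    summary = {
        "regions_analyzed": regions,
        "endfoot_labels": {r: coherent[r].label for r in regions},
        "n_in_cluster_any_region": n_in_any,
        "n_in_cluster_multiple_regions": n_in_multiple,
        "n_candidates_pass": int(report["pass"].sum()) if len(report) else 0,
    }
    return report, summary


def _bait_names(established_ids: list[str]) -> dict[str, str]:
    """Readable column names for bait genes (symbol where known, else the ID)."""
    id_to_sym = {v: k for k, v in ESTABLISHED_ENDFOOT_GENES.items()}
    return {id_to_sym.get(b, b): b for b in established_ids}
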