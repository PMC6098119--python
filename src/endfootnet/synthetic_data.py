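"""Synthetic cohorts with the statistical structure the pipeline assumes.

Expression follows a latent factor model: each module m has a per-region
eigengene E_m (standard normal over subjects, correlated 0.6 across regions),
and a member gene g has latent value z_g = lambda_g * E_m + eps with
eps ~ N(0, noise_sd). Latent values are exponentiated onto an FPKM-like
log-normal scale, so marginals are right-skewed and the low-expression
filter stays meaningful. Background genes are independent noise; a block of
deliberately low-expressed genes exercises the FPKM filter.

The endfoot module contains the five established endfoot genes (AQP4 and
the dystrophin-associated complex), a set of planted candidate genes with
astrocyte fraction drawn >= 0.5, and decoy members with equally strong
loadings but astrocyte fraction < 0.5 — so the screen's specificity gate is
testable. Dementia status is Bernoulli under a logistic model of designated
hippocampal genes; temporal-cortex P-tau is log-linear in the endfoot
eigengene; Braak / neuritic plaque / CAA ordinals are monotone in that same
latent pathology.

Randomness is one seed split into named substreams (structure, expression,
covariates, pathology, celltype), so e.g. adding genes does not perturb the
covariate draw.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from endfootnet.data_io import (
    AGE_CLASSES,
    CellTypeFractionTable,
    ExpressionMatrix,
    PathologyPanel,
    SubjectRecord,
)
from endfootnet.endfoot_screen import ESTABLISHED_ENDFOOT_GENES

#: Planted candidate genes, symbol -> Entrez ID (astrocytic endfoot candidates).
PLANTED_CANDIDATE_GENES = {
    "ACSS1": "84532",
    "AMOT": "154796",
    "BMPR1B": "658",
    "FGFR3": "2261",
    "FXYD1": "5348",
    "GLUD1": "2746",
    "MLC1": "23209",
    "NDRG2": "57447",
    "PBXIP1": "57326",
    "PPAP2B": "8613",
    "SLC1A3": "6507",
}

CELL_TYPES = ("astrocyte", "neuron", "oligodendrocyte", "microglia", "endothelial")

#: Validation-cohort genes of interest (AQP4, DTNA, MLC1, FXYD1).
VALIDATION_GENES = ("361", "1837", "23209", "5348")


class ConfigError(ValueError):
    """Infeasible simulation configuration."""


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator; ``seed`` is mandatory."""

    seed: int
    n_subjects: int = 100
    regions: tuple[str, ...] = ("TCX", "HIP", "PCX")
    n_genes: int = 2000
    n_modules: int = 6
    module_size_range: tuple[int, int] = (40, 120)
    endfoot_module_size: int = 60
    n_planted_candidates: int = 11
    loading_range: tuple[float, float] = (0.4, 0.95)
    endfoot_loading_range: tuple[float, float] = (0.8, 0.95)
    noise_sd: float = 0.4
    inter_region_cor: float = 0.6
    log_expression_scale: float = 0.5
    base_log_fpkm: tuple[float, float] = (3.4, 0.5)  # mean, sd of per-gene log level
    n_low_expression_genes: int = 100
    dementia_logit_intercept: float = 0.0
    dementia_logit_coefs: Mapping[str, float] = field(
        default_factory=lambda: {"361": 1.0, "1837": 1.0}  # HIP AQP4, DTNA
    )
    ptau_link_coef: float = 0.8
    pathology_lognormal_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "ab_ihc": (-1.5, 1.0),
            "ab40_pg_mg": (5.3, 0.8),
            "ab42_pg_mg": (6.0, 0.8),
            "at8_ihc": (-2.0, 1.0),
            "ptau_ng_mg": (1.6, 0.6),
            "tau_total_ng_mg": (4.6, 0.5),
        }
    )
    astro_fraction_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "established": (0.55, 0.95),
            "dmd": (0.2, 0.45),  # DMD is the non-astrocytic bait
            "candidate": (0.6, 0.95),
            "decoy": (0.05, 0.45),
            "background": (0.0, 1.0),
        }
    )
    sex_male_rate: float = 0.55
    apoe4_rate: float = 0.19
    tbi_rate: float = 0.5
    age_class_probs: tuple[float, ...] = (0.05, 0.15, 0.25, 0.25, 0.30)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        planted = len(ESTABLISHED_ENDFOOT_GENES) + self.n_planted_candidates
        if self.endfoot_module_size < planted:
            raise ConfigError(
                f"endfoot module size {self.endfoot_module_size} cannot hold "
                f"{planted} established + planted genes"
            )
        max_total = self.endfoot_module_size + (self.n_modules - 1) * self.module_size_range[1]
        if self.endfoot_module_size + (self.n_modules - 1) * self.module_size_range[0] > self.n_genes:
            raise ConfigError("module sizes exceed gene count")
        del max_total
        for lo, hi in (self.loading_range, self.endfoot_loading_range):
            if not 0 < lo <= hi < 1:
                raise ConfigError("loading ranges must satisfy 0 < lo <= hi < 1")
        if not 0 <= self.inter_region_cor < 1:
            raise ConfigError("inter_region_cor must lie in [0, 1)")
        if abs(sum(self.age_class_probs) - 1) > 1e-9 or len(self.age_class_probs) != len(AGE_CLASSES):
            raise ConfigError("age_class_probs must sum to 1 over the age classes")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    gene_to_module: dict[str, int]
    established_genes: list[str]
    planted_candidates: list[str]
    decoy_genes: list[str]
    loadings: pd.Series
    eigengenes: dict[str, pd.DataFrame]  # region -> module x subject
    dementia_coefs: dict[str, float]
    ptau_link_coef: float

    def module_members(self, module: int) -> list[str]:
        return [g for g, m in self.gene_to_module.items() if m == module]


@dataclass
class Cohort:
    expressions: dict[str, ExpressionMatrix]
    subjects: list[SubjectRecord]
    pathology: dict[str, PathologyPanel]
    celltype: CellTypeFractionTable
    truth: GroundTruth
    config: SimulationConfig


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named substream: stable across runs and across other substreams."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


def _draw(rng: np.random.Generator, lo_hi: tuple[float, float], size: int) -> np.ndarray:
    lo, hi = lo_hi
    return rng.uniform(lo, hi, size)


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Generate one multi-region cohort with ground truth."""
    cfg = config
    rng_struct = _rng(cfg.seed, "structure")
    rng_expr = _rng(cfg.seed, "expression")
    rng_cov = _rng(cfg.seed, "covariates")
    rng_path = _rng(cfg.seed, "pathology")
    rng_cell = _rng(cfg.seed, "celltype")

    # --- gene roster and module assignment (module 1 = endfoot) -------------
    established = list(ESTABLISHED_ENDFOOT_GENES.values())
    candidates = list(PLANTED_CANDIDATE_GENES.values())[: cfg.n_planted_candidates]
    n_decoys = cfg.endfoot_module_size - len(established) - len(candidates)
    sizes = [cfg.endfoot_module_size] + [
        int(rng_struct.integers(cfg.module_size_range[0], cfg.module_size_range[1] + 1))
        for _ in range(cfg.n_modules - 1)
    ]
    if sum(sizes) > cfg.n_genes:
        raise ConfigError("module sizes exceed gene count")
    n_filler = cfg.n_genes - sum(sizes)
    synth_ids = [str(100000 + i) for i in range(cfg.n_genes)]
    decoys = synth_ids[:n_decoys]
    other = synth_ids[n_decoys:]
    gene_ids: list[str] = established + candidates + decoys
    gene_to_module: dict[str, int] = {g: 1 for g in gene_ids}
    cursor = 0
    for m, size in enumerate(sizes[1:], start=2):
        members = other[cursor : cursor + size]
        cursor += size
        gene_ids.extend(members)
        gene_to_module.update({g: m for g in members})
    background = other[cursor : cursor + n_filler]
    gene_ids.extend(background)
    gene_to_module.update({g: 0 for g in background})
    # last n_low_expression_genes of the background are near-silent
    low_expr = set(background[-cfg.n_low_expression_genes :]) if cfg.n_low_expression_genes else set()
    order = rng_struct.permutation(len(gene_ids))
    gene_ids = [gene_ids[i] for i in order]

    loadings = pd.Series(0.0, index=gene_ids)
    endfoot_members = [g for g in gene_ids if gene_to_module[g] == 1]
    loadings[endfoot_members] = _draw(rng_struct, cfg.endfoot_loading_range, len(endfoot_members))
    for m in range(2, cfg.n_modules + 1):
        members = [g for g in gene_ids if gene_to_module[g] == m]
        loadings[members] = _draw(rng_struct, cfg.loading_range, len(members))

    base_mu = pd.Series(
        rng_struct.normal(cfg.base_log_fpkm[0], cfg.base_log_fpkm[1], len(gene_ids)),
        index=gene_ids,
    )
    base_mu[list(low_expr)] = 0.0  # FPKM around 1: removed by the filter

    # --- subjects -----------------------------------------------------------
    subject_ids = [f"S{i:04d}" for i in range(cfg.n_subjects)]

    # --- eigengenes, correlated across regions ------------------------------
    rho = cfg.inter_region_cor
    shared = rng_expr.normal(size=(cfg.n_modules, cfg.n_subjects))
    eigengenes: dict[str, pd.DataFrame] = {}
    for region in cfg.regions:
        own = rng_expr.normal(size=(cfg.n_modules, cfg.n_subjects))
        e = np.sqrt(rho) * shared + np.sqrt(1 - rho) * own
        eigengenes[region] = pd.DataFrame(
            e, index=range(1, cfg.n_modules + 1), columns=subject_ids
        )

    # --- expression ---------------------------------------------------------
    modules = np.array([gene_to_module[g] for g in gene_ids])
    lam = loadings.to_numpy()
    expressions: dict[str, ExpressionMatrix] = {}
    latent: dict[str, np.ndarray] = {}
    for region in cfg.regions:
        e = eigengenes[region].to_numpy()
        z = rng_expr.normal(0.0, cfg.noise_sd, size=(len(gene_ids), cfg.n_subjects))
        in_module = modules > 0
        z[in_module] += lam[in_module, None] * e[modules[in_module] - 1]
        z[~in_module] = rng_expr.normal(0.0, 1.0, size=(int((~in_module).sum()), cfg.n_subjects))
        latent[region] = z
        vals = np.exp(base_mu.to_numpy()[:, None] + cfg.log_expression_scale * z)
        expressions[region] = ExpressionMatrix(
            region=region,
            unit="fpkm",
            values=pd.DataFrame(vals, index=gene_ids, columns=subject_ids),
        )

    # --- covariates and dementia status ------------------------------------
    age = rng_cov.choice(len(AGE_CLASSES), size=cfg.n_subjects, p=cfg.age_class_probs)
    sex = rng_cov.random(cfg.n_subjects) < cfg.sex_male_rate
    apoe4 = rng_cov.random(cfg.n_subjects) < cfg.apoe4_rate
    tbi = rng_cov.random(cfg.n_subjects) < cfg.tbi_rate
    education = rng_cov.integers(10, 21, size=cfg.n_subjects)

    logit = np.full(cfg.n_subjects, cfg.dementia_logit_intercept, dtype=float)
    dementia_region = "HIP" if "HIP" in cfg.regions else cfg.regions[0]
    log_expr = np.log(expressions[dementia_region].values)
    for gene, coef in cfg.dementia_logit_coefs.items():
        x = log_expr.loc[gene].to_numpy()
        logit += coef * (x - x.mean()) / x.std()
    dementia = rng_cov.random(cfg.n_subjects) < 1.0 / (1.0 + np.exp(-logit))

    subjects = [
        SubjectRecord(
            subject_id=sid,
            age_increment=int(age[i]),
            sex="M" if sex[i] else "F",
            dementia=bool(dementia[i]),
            apoe4_carrier=bool(apoe4[i]),
            tbi_history=bool(tbi[i]),
            education_years=int(education[i]),
        )
        for i, sid in enumerate(subject_ids)
    ]

    # --- pathology ----------------------------------------------------------
    ptau_region = "TCX" if "TCX" in cfg.regions else cfg.regions[0]
    latent_logptau = None
    pathology: dict[str, PathologyPanel] = {}
    for region in cfg.regions:
        quant = {}
        for outcome, (mu, sigma) in cfg.pathology_lognormal_params.items():
            noise = rng_path.normal(0.0, sigma, cfg.n_subjects)
            logy = mu + noise
            if outcome == "ptau_ng_mg" and region == ptau_region:
                e_endfoot = eigengenes[region].loc[1].to_numpy()
                logy = mu + cfg.ptau_link_coef * e_endfoot + noise
                latent_logptau = logy
            quant[outcome] = np.exp(logy)
        pathology[region] = PathologyPanel(
            region=region,
            quantitative=pd.DataFrame(quant, index=subject_ids),
            ordinal=pd.DataFrame(index=subject_ids),
        )
    assert latent_logptau is not None
    ordinal = pd.DataFrame(
        {
            "braak": _monotone_ordinal(latent_logptau, 7),
            "neuritic_plaque_score": _monotone_ordinal(latent_logptau, 4),
            "caa_score": _monotone_ordinal(latent_logptau, 4),
        },
        index=subject_ids,
    )
    for panel in pathology.values():
        panel.ordinal = ordinal.copy()

    # --- cell-type table ----------------------------------------------------
    frac = pd.Series(index=gene_ids, dtype=float)
    ranges = cfg.astro_fraction_ranges
    for g in gene_ids:
        if g == ESTABLISHED_ENDFOOT_GENES["DMD"]:
            frac[g] = rng_cell.uniform(*ranges["dmd"])
        elif g in established:
            frac[g] = rng_cell.uniform(*ranges["established"])
        elif g in candidates:
            frac[g] = rng_cell.uniform(*ranges["candidate"])
        elif g in decoys:
            frac[g] = rng_cell.uniform(*ranges["decoy"])
        else:
            frac[g] = rng_cell.uniform(*ranges["background"])
    total = rng_cell.lognormal(3.0, 0.5, len(gene_ids))
    other_split = rng_cell.dirichlet(np.ones(len(CELL_TYPES) - 1), len(gene_ids))
    table = pd.DataFrame(index=gene_ids, columns=CELL_TYPES, dtype=float)
    table["astrocyte"] = frac * total
    for j, ct in enumerate(CELL_TYPES[1:]):
        table[ct] = (1 - frac) * total * other_split[:, j]
    celltype = CellTypeFractionTable(values=table)

    truth = GroundTruth(
        gene_to_module=gene_to_module,
        established_genes=established,
        planted_candidates=candidates,
        decoy_genes=decoys,
        loadings=loadings,
        eigengenes=eigengenes,
        dementia_coefs=dict(cfg.dementia_logit_coefs),
        ptau_link_coef=cfg.ptau_link_coef,
    )
    return Cohort(expressions, subjects, pathology, celltype, truth, cfg)


def _monotone_ordinal(latent: np.ndarray, n_levels: int) -> np.ndarray:
    """Quantile-bin a latent severity into 0..n_levels-1, monotone in latent."""
    ranks = np.argsort(np.argsort(latent))
    return np.floor(ranks * n_levels / len(latent)).astype(float)


@dataclass
class ValidationCohort:
    """Small degraded cohort mimicking an external microarray validation set."""

    expression: ExpressionMatrix
    subjects: list[SubjectRecord]
    ordinal_pathology: pd.DataFrame


def degrade_to_validation_cohort(
    cohort: Cohort,
    subsample: int = 30,
    keep_genes: Sequence[str] = VALIDATION_GENES,
    age_offset_years: int = 10,
    region: str | None = None,
    seed: int | None = None,
) -> ValidationCohort:
    """Subsample subjects, keep a handful of genes, and inject an age offset
    between the AD and non-AD groups (the confound reported for small
    AD-focused validation cohorts)."""
    if subsample > cohort.config.n_subjects:
        raise ConfigError(
            f"subsample {subsample} larger than cohort ({cohort.config.n_subjects})"
        )
    region = region or ("HIP" if "HIP" in cohort.expressions else next(iter(cohort.expressions)))
    rng = _rng(cohort.config.seed if seed is None else seed, "validation")
    ids = [s.subject_id for s in cohort.subjects]
    chosen = sorted(rng.choice(len(ids), size=subsample, replace=False).tolist())
    chosen_ids = [ids[i] for i in chosen]
    offset_inc = int(round(age_offset_years / 5))
    subjects = []
    for i in chosen:
        s = cohort.subjects[i]
        inc = s.age_increment
        if s.dementia:
            inc = min(inc + offset_inc, len(AGE_CLASSES) - 1)
        subjects.append(
            SubjectRecord(
                subject_id=s.subject_id,
                age_increment=inc,
                sex=s.sex,
                dementia=s.dementia,  # AD flag in the validation setting
                apoe4_carrier=s.apoe4_carrier,
                tbi_history=s.tbi_history,
                education_years=s.education_years,
            )
        )
    present = [g for g in keep_genes if g in cohort.expressions[region].values.index]
    expr = ExpressionMatrix(
        region=region,
        unit="intensity",
        values=cohort.expressions[region].values.loc[present, chosen_ids],
    )
    ordinal = cohort.pathology[region].ordinal.loc[chosen_ids]
    return ValidationCohort(expression=expr, subjects=subjects, ordinal_pathology=ordinal)
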