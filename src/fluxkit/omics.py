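"""Mapping expression time series onto predicted fluxes via GPRs.

Each metabolic gene is given a flux series — at every time point the sum of
|v| over the reactions whose GPR mentions the gene (absolute values because
expression magnitude cannot encode flux direction; sums because a gene with
several reactions needs one number per time point). Expression and flux
series are then compared with Pearson and Spearman correlations; a
variation filter keeps only genes whose transcript level actually moves
across the course.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .data import OmicsMatrix
from .fba import FluxSolution
from .model import Gene, MetabolicModel, ModelError

__all__ = [
    "CorrelationRecord",
    "CorrelationSummary",
    "gene_flux_series",
    "correlate_expression_flux",
    "filter_by_variation",
    "summarize_correlations",
    "order_by_genome_position",
    "CORRELATED_THRESHOLD",
    "ANTI_CORRELATED_THRESHOLD",
]

# Spearman-ρ trichotomy: correlated / uncorrelated / anti-correlated
CORRELATED_THRESHOLD = 0.3
ANTI_CORRELATED_THRESHOLD = -0.3


@dataclass
class CorrelationRecord:
    gene_id: str
    reaction_ids: List[str] = field(default_factory=list)
    pearson_r: Optional[float] = None  # None: undefined (constant series)
    spearman_rho: Optional[float] = None
    n_timepoints: int = 0
    variation_fraction: Optional[float] = None  # (max - min) / min of expression
    classification: str = "undefined"
    genome_start: Optional[int] = None
    flagged: bool = False  # min <= 0 variation, missing position, etc.


@dataclass
class CorrelationSummary:
    median_pearson: Optional[float]
    median_spearman: Optional[float]
    histogram_bins: np.ndarray  # 21 edges over [-1, 1]
    pearson_histogram: np.ndarray
    spearman_histogram: np.ndarray
    classification_counts: Dict[str, int]
    n_records: int


def gene_flux_series(
    model: MetabolicModel, solutions: Sequence[FluxSolution]
) -> Dict[str, np.ndarray]:
    """Per-gene aggregated |flux| series over an ordered solution list.

    Gene g's value at time t is Σ |v_r(t)| over reactions r whose GPR
    contains g; genes in no GPR are omitted.
    """
    if not solutions:
        raise ModelError("empty solution list")
    gene_rxns: Dict[str, List[str]] = {}
    for rxn in model.reactions.values():
        for g in rxn.gpr.genes():
            gene_rxns.setdefault(g, []).append(rxn.id)
    out: Dict[str, np.ndarray] = {}
    for g, rids in gene_rxns.items():
        out[g] = np.array(
            [sum(abs(sol.fluxes[r]) for r in rids) for sol in solutions]
        )
    return out


def _variation(series: np.ndarray) -> tuple[Optional[float], bool]:
    """(max - min)/min, or (None, True) when min <= 0 makes it undefined."""
    lo, hi = float(np.nanmin(series)), float(np.nanmax(series))
    if lo <= 0:
        return None, True
    return (hi - lo) / lo, False


def _classify(rho: Optional[float]) -> str:
    if rho is None:
        return "undefined"
    if rho >= CORRELATED_THRESHOLD:
        return "correlated"
    if rho <= ANTI_CORRELATED_THRESHOLD:
        return "anti-correlated"
    return "uncorrelated"


def correlate_expression_flux(
    expression: OmicsMatrix,
    flux_series: Mapping[str, np.ndarray],
    model: Optional[MetabolicModel] = None,
) -> List[CorrelationRecord]:
    """Pearson and Spearman correlation per gene shared by both inputs.

    Missing expression values (proteomics) are dropped pairwise, and
    ``n_timepoints`` reflects the drop; a gene with fewer than 3 complete
    pairs, or with a constant series on either side, has undefined
    correlations recorded as missing (never as zero). If a model is given,
    the record carries the gene's associated reactions and genome position.
    """
    shared = [g for g in expression.entities if g in flux_series]
    if not shared:
        raise ModelError("no shared genes between expression matrix and flux map")

    records: List[CorrelationRecord] = []
    for g in shared:
        expr = expression.series(g)
        flux = np.asarray(flux_series[g], dtype=float)
        if expr.shape != flux.shape:
            raise ModelError(
                f"gene {g}: series length mismatch {expr.shape} vs {flux.shape}"
            )
        mask = ~(np.isnan(expr) | np.isnan(flux))
        e, f = expr[mask], flux[mask]
        n = int(mask.sum())
        pear = spear = None
        if n >= 3 and np.ptp(e) > 0 and np.ptp(f) > 0:
            pear = float(stats.pearsonr(e, f).statistic)
            spear = float(stats.spearmanr(e, f).statistic)
        var, var_flag = _variation(expr[~np.isnan(expr)])
        rec = CorrelationRecord(
            gene_id=g,
            pearson_r=pear,
            spearman_rho=spear,
            n_timepoints=n,
            variation_fraction=var,
            classification=_classify(spear),
            flagged=var_flag,
        )
        if model is not None:
            rec.reaction_ids = model.reactions_for_gene(g)
            gene = model.genes.get(g)
            if gene is not None:
                rec.genome_start = gene.genome_start
        records.append(rec)
    return records


def filter_by_variation(
    records: Sequence[CorrelationRecord],
    expression: OmicsMatrix,
    threshold: float = 0.25,
) -> List[CorrelationRecord]:
    """Keep genes whose expression varies by strictly more than ``threshold``.

    Variation is (max − min)/min of the expression series; the comparison is
    strict, so a series at exactly the threshold is removed. Genes whose
    minimum is ≤ 0 have an undefined ratio: they are excluded and flagged.
    """
    if threshold < 0:
        raise ModelError("threshold must be >= 0")
    kept: List[CorrelationRecord] = []
    for rec in records:
        if rec.gene_id not in expression:
            continue
        series = expression.series(rec.gene_id)
        var, bad = _variation(series[~np.isnan(series)])
        if bad:
            rec.flagged = True
            continue
        if var > threshold:
            kept.append(rec)
    return kept


def summarize_correlations(records: Sequence[CorrelationRecord]) -> CorrelationSummary:
    """Medians, 20-bin histograms over [−1, 1], and classification counts."""
    if not records:
        raise ModelError("no correlation records to summarize")
    pears = [r.pearson_r for r in records if r.pearson_r is not None]
    spears = [r.spearman_rho for r in records if r.spearman_rho is not None]
    edges = np.linspace(-1.0, 1.0, 21)
    counts: Dict[str, int] = {}
    for r in records:
        counts[r.classification] = counts.get(r.classification, 0) + 1
    return CorrelationSummary(
        median_pearson=float(np.median(pears)) if pears else None,
        median_spearman=float(np.median(spears)) if spears else None,
        histogram_bins=edges,
        pearson_histogram=np.histogram(pears, bins=edges)[0],
        spearman_histogram=np.histogram(spears, bins=edges)[0],
        classification_counts=counts,
        n_records=len(records),
    )


def order_by_genome_position(
    records: Sequence[CorrelationRecord],
    genes: Optional[Mapping[str, Gene]] = None,
) -> List[CorrelationRecord]:
    """Order records by genome position (ascending base pair).

    Positions come from the records themselves or from ``genes``; records
    lacking a position are appended after the positioned ones in gene-id
    order and flagged. The result is a permutation of the input.
    """
    def position(rec: CorrelationRecord) -> Optional[int]:
        if rec.genome_start is not None:
            return rec.genome_start
        if genes is not None and rec.gene_id in genes:
            return genes[rec.gene_id].genome_start
        return None

    positioned = [(position(r), r) for r in records]
    with_pos = sorted(
        [(p, r) for p, r in positioned if p is not None], key=lambda t: t[0]
    )
    without = sorted([r for p, r in positioned if p is None], key=lambda r: r.gene_id)
    for r in without:
        r.flagged = True
    return [r for _, r in with_pos] + without
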