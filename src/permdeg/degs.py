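"""DEG calling, sub-phenotype-unique sets, and confirmation concordance.

A gene is called differentially expressed when, at one or more quantile
levels, simultaneously: the multiplicity-adjusted permutation p-value is
below 0.05, the absolute difference between the two group quantiles is
at least 10 cpm, and the fold change between them is at least 1.5.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import (
    DEGRecord,
    NormalizedMatrix,
    SampleMetadata,
    ValidationError,
    select_samples,
)
from .permtest import LEVEL_NAMES, QuantileSpec, QuantileTestResult, group_quantile

__all__ = [
    "DEGThresholds",
    "UniqueDEGSet",
    "fold_change",
    "call_degs",
    "unique_degs",
    "shared_and_exclusive",
    "confirmation_concordance",
]

# FDR tie-break preference for the reporting level
_LEVEL_PRIORITY = {0.5: 0, 0.75: 1, 0.25: 2}


@dataclass(frozen=True)
class DEGThresholds:
    """The three calling criteria (adjusted p, absolute cpm gap, fold)."""

    fdr_max: float = 0.05
    min_abs_diff_cpm: float = 10.0
    min_fold_change: float = 1.5

    def __post_init__(self) -> None:
        if not (0 < self.fdr_max <= 1):
            raise ValidationError("fdr_max must be in (0, 1]")
        if self.min_abs_diff_cpm <= 0 or self.min_fold_change <= 0:
            raise ValidationError("thresholds must be strictly positive")


@dataclass
class UniqueDEGSet:
    """DEGs significant against one sub-phenotype and not the opposite one."""

    target_subphenotype: str  # "E" | "A"
    records: list[DEGRecord]
    provenance: dict[str, list[str]]  # gene_id -> comparisons it was significant in


def fold_change(cpm_ctl: float, cpm_case: float) -> tuple[float, str]:
    """(ratio >= 1, direction) between two group summaries.

    ``direction`` is ``up`` when the case summary is larger, ``down``
    when smaller, ``none`` when equal.  A zero summary on one side yields
    an infinite ratio (flagged with a warning); negative inputs are an
    error.
    """
    if cpm_ctl < 0 or cpm_case < 0:
        raise ValidationError("group summaries must be non-negative")
    if cpm_case > cpm_ctl:
        direction = "up"
    elif cpm_case < cpm_ctl:
        direction = "down"
    else:
        return 1.0, "none"
    lo = min(cpm_ctl, cpm_case)
    hi = max(cpm_ctl, cpm_case)
    if lo == 0:
        warnings.warn(
            "zero group summary: fold change is infinite", stacklevel=2
        )
        return math.inf, direction
    return hi / lo, direction


def call_degs(
    results: Sequence[QuantileTestResult],
    thresholds: DEGThresholds = DEGThresholds(),
    gene_names: Optional[Mapping[str, str]] = None,
) -> list[DEGRecord]:
    """Apply the three calling criteria to per-gene, per-level results.

    ``results`` must carry the control group as ``q_group1`` and the case
    group as ``q_group2`` (the orientation produced by ``test_all_genes``
    with a (control, case) comparison).  A gene qualifies if any single
    level passes all three criteria at that level's own group quantiles;
    the reported cpm pair comes from the qualifying level with the
    smallest FDR (ties broken median > q3 > q1).  Output is sorted by
    descending ratio within direction (up first), so it does not depend
    on the input ordering.
    """
    by_gene: dict[str, list[QuantileTestResult]] = {}
    for r in results:
        if r.fdr is None:
            raise ValidationError("results must carry FDR values (run bh_fdr first)")
        by_gene.setdefault(r.gene_id, []).append(r)

    records: list[DEGRecord] = []
    for gene_id, rows in by_gene.items():
        qualifying: list[QuantileTestResult] = []
        for r in rows:
            if r.fdr >= thresholds.fdr_max:
                continue
            if abs(r.q_group2 - r.q_group1) < thresholds.min_abs_diff_cpm:
                continue
            with warnings.catch_warnings():
                # an infinite ratio is already flagged by the record itself
                warnings.simplefilter("ignore")
                ratio, direction = fold_change(r.q_group1, r.q_group2)
            if direction == "none" or ratio < thresholds.min_fold_change:
                continue
            qualifying.append(r)
        if not qualifying:
            continue
        best = min(
            qualifying, key=lambda r: (r.fdr, _LEVEL_PRIORITY[r.quantile_level])
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ratio, direction = fold_change(best.q_group1, best.q_group2)
        records.append(
            DEGRecord(
                gene_id=gene_id,
                gene_name=(gene_names or {}).get(gene_id, gene_id),
                cpm_ctl=best.q_group1,
                cpm_case=best.q_group2,
                ratio=ratio,
                direction=direction,
                fdr=best.fdr,
                qualifying_levels=tuple(
                    sorted(r.quantile_level for r in qualifying)
                ),
                report_level=best.quantile_level,
            )
        )
    records.sort(
        key=lambda r: (
            {"up": 0, "none": 1, "down": 2}[r.direction],
            -r.ratio if math.isfinite(r.ratio) else -math.inf,
            r.gene_id,
        )
    )
    return records


_UNIQUE_KEYS = ("ctl_vs_E", "ctl_vs_Eex", "ctl_vs_A", "ctl_vs_Aex")


def unique_degs(
    deg_sets: Mapping[str, Sequence[DEGRecord]],
) -> tuple[UniqueDEGSet, UniqueDEGSet]:
    """Sub-phenotype-unique DEG sets from the four control comparisons.

    E-unique = DEGs of (ctl_vs_E or ctl_vs_Eex) whose gene is not a DEG
    in either ctl_vs_A or ctl_vs_Aex; symmetrically for A.  The two
    outputs are disjoint by construction (asserted).
    """
    missing = [k for k in _UNIQUE_KEYS if k not in deg_sets]
    if missing:
        raise ValidationError(f"missing comparison(s) {missing}")
    sig: dict[str, dict[str, DEGRecord]] = {
        k: {r.gene_id: r for r in deg_sets[k]} for k in _UNIQUE_KEYS
    }

    def build(own: tuple[str, str], other: tuple[str, str], target: str) -> UniqueDEGSet:
        other_genes = set(sig[other[0]]) | set(sig[other[1]])
        records: list[DEGRecord] = []
        provenance: dict[str, list[str]] = {}
        for gene in sorted(set(sig[own[0]]) | set(sig[own[1]])):
            if gene in other_genes:
                continue
            cands = [sig[k][gene] for k in own if gene in sig[k]]
            records.append(min(cands, key=lambda r: r.fdr))
            provenance[gene] = [k for k in _UNIQUE_KEYS if gene in sig[k]]
        return UniqueDEGSet(target, records, provenance)

    e_set = build(("ctl_vs_E", "ctl_vs_Eex"), ("ctl_vs_A", "ctl_vs_Aex"), "E")
    a_set = build(("ctl_vs_A", "ctl_vs_Aex"), ("ctl_vs_E", "ctl_vs_Eex"), "A")
    overlap = {r.gene_id for r in e_set.records} & {r.gene_id for r in a_set.records}
    assert not overlap, f"unique sets overlap: {sorted(overlap)}"
    return e_set, a_set


def shared_and_exclusive(
    set1: Sequence[str], set2: Sequence[str]
) -> tuple[set[str], set[str], set[str]]:
    """Venn partition of two DEG gene-id collections: (shared, only1, only2)."""
    s1, s2 = set(set1), set(set2)
    return s1 & s2, s1 - s2, s2 - s1


def confirmation_concordance(
    discovery_degs: Sequence[DEGRecord],
    norm: NormalizedMatrix,
    metadata: Sequence[SampleMetadata],
    control_selector: dict,
    confirmation_selector: dict,
) -> tuple[pd.DataFrame, float]:
    """Direction agreement of discovery DEGs in a confirmation cohort.

    For each discovery DEG the group-quantile direction (case minus
    control at the record's reporting level) is recomputed on the
    confirmation cases versus the same controls; the check is purely
    descriptive (sign agreement, no significance testing).  Returns the
    per-gene table and the overall concordant fraction.
    """
    ids_ctl = select_samples(metadata, **control_selector)
    ids_conf = select_samples(metadata, **confirmation_selector)
    if not ids_conf:
        raise ValidationError("confirmation selector matches no samples")
    if not ids_ctl:
        raise ValidationError("control selector matches no samples")
    col = {s: j for j, s in enumerate(norm.sample_ids)}
    cols_ctl = [col[s] for s in ids_ctl if s in col]
    cols_conf = [col[s] for s in ids_conf if s in col]
    if len(cols_conf) != len(ids_conf) or len(cols_ctl) != len(ids_ctl):
        raise ValidationError("selected samples missing from the matrix")

    rows = []
    n_concordant = 0
    for rec in discovery_degs:
        try:
            g = norm.gene_index(rec.gene_id)
        except KeyError:
            raise ValidationError(
                f"discovery DEG {rec.gene_id!r} absent from the confirmation matrix"
            ) from None
        spec = QuantileSpec(rec.report_level if rec.report_level is not None else 0.5)
        q_ctl = group_quantile(norm.cpm[g, cols_ctl], spec)
        q_conf = group_quantile(norm.cpm[g, cols_conf], spec)
        delta = q_conf - q_ctl
        conf_direction = "up" if delta > 0 else ("down" if delta < 0 else "none")
        concordant = conf_direction == rec.direction
        n_concordant += concordant
        rows.append(
            {
                "gene_id": rec.gene_id,
                "level": LEVEL_NAMES[spec.level],
                "discovery_direction": rec.direction,
                "confirmation_direction": conf_direction,
                "q_ctl": q_ctl,
                "q_confirmation": q_conf,
                "concordant": concordant,
            }
        )
    table = pd.DataFrame(rows)
    fraction = n_concordant / len(discovery_degs) if discovery_degs else float("nan")
    return table, fraction
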