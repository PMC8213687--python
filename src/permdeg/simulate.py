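"""Synthetic cohort generator with the structure the pipeline assumes.

Counts are negative-binomial with log-normal gene baselines, gamma-
distributed per-gene dispersions and unequal library sizes.  Differential
genes are spiked either as whole-distribution shifts (every affected
sample's mean is multiplied by the fold) or as upper-tail shifts (only a
configurable fraction of the affected samples is multiplied, leaving the
group median approximately unchanged).  An optional co-expressed
high-abundance gene block is elevated in a designated sub-phenotype, and
lung-function covariates are generated with a linear link to that block.
Everything is reproducible from the single mandatory seed.

This generative model is this module's own contract: the generating
distributions are standard bulk RNA-seq assumptions, chosen so the
analysis stages have known ground truth to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import (
    CountMatrix,
    QpcrMeasurement,
    SampleMetadata,
    ValidationError,
    subphenotype_matches,
)

__all__ = [
    "DEGeneSpec",
    "MtBlockSpec",
    "CovariateModel",
    "SimulationConfig",
    "default_group_sizes",
    "simulate_cohort",
    "simulate_qpcr",
]

_CASE_GROUPS = ("E", "Eex", "A", "Aex", "mixed", "normalCT")


@dataclass(frozen=True)
class DEGeneSpec:
    """One spiked differential gene.

    ``subphenotypes=None`` affects every case (including confirmation
    cases); otherwise only cases whose label matches one of the listed
    sub-phenotypes (``E`` includes ``Eex``, ``A`` includes ``Aex``).
    ``upper_tail_shift`` multiplies the mean in a random ``tail_fraction``
    of the affected samples only.
    """

    gene_index: int
    fold: float
    mode: str = "median_shift"  # "median_shift" | "upper_tail_shift"
    sexes: tuple[str, ...] = ("male", "female")
    subphenotypes: Optional[tuple[str, ...]] = None
    tail_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValidationError("fold must be > 0")
        if self.mode not in ("median_shift", "upper_tail_shift"):
            raise ValidationError(f"unknown DE mode {self.mode!r}")
        if not (0 < self.tail_fraction <= 1):
            raise ValidationError("tail_fraction must be in (0, 1]")


@dataclass(frozen=True)
class MtBlockSpec:
    """A co-expressed high-baseline gene block elevated in one subgroup.

    ``confirmation_fraction`` of confirmation-cohort cases also carry the
    fold (emulating latent extreme-phenotype cases without imaging
    labels), so confirmation samples split into high/low expressors.
    """

    gene_indices: tuple[int, ...]
    fold: float = 2.0
    subgroup: str = "Eex"
    sexes: tuple[str, ...] = ("male",)
    baseline_cpm: float = 1e4
    confirmation_fraction: float = 0.4


@dataclass(frozen=True)
class CovariateModel:
    """Linear links from the (log2) block multiplier to lung function."""

    tlco_intercept: float = 6.0
    tlco_slope: float = -1.5  # negative: high block expression, low TLCO/Va
    tlc_intercept: float = 5.0
    tlc_slope: float = 0.8  # positive link to total lung capacity
    noise_sd: float = 0.3


def default_group_sizes() -> dict[tuple[str, str], int]:
    """Cohort sizes mirroring the study design (females about half).

    Males: 145 controls, 50 E-dominant (22 of them extreme), 32
    A-dominant (16 extreme), plus mixed/normal-CT cases and a 36-case
    confirmation group without imaging labels.
    """
    male = {
        "control": 145,
        "E": 28,
        "Eex": 22,
        "A": 16,
        "Aex": 16,
        "mixed": 40,
        "normalCT": 20,
        "confirmation": 36,
    }
    female = {
        "control": 73,
        "E": 14,
        "Eex": 11,
        "A": 8,
        "Aex": 8,
        "mixed": 20,
        "normalCT": 10,
        "confirmation": 17,
    }
    sizes: dict[tuple[str, str], int] = {}
    for g, n in male.items():
        sizes[("male", g)] = n
    for g, n in female.items():
        sizes[("female", g)] = n
    return sizes


@dataclass
class SimulationConfig:
    seed: int
    n_genes: int = 500
    group_sizes: Mapping[tuple[str, str], int] = field(default_factory=default_group_sizes)
    log2_baseline_mean: float = 5.0
    log2_baseline_sd: float = 1.5
    dispersion_shape: float = 2.0
    dispersion_mean: float = 0.2
    library_size_range: tuple[float, float] = (8e5, 1.2e6)
    de_genes: tuple[DEGeneSpec, ...] = ()
    mt_block: Optional[MtBlockSpec] = None
    covariates: CovariateModel = field(default_factory=CovariateModel)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("a seed is mandatory")
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValidationError("group sizes must be >= 0")
        for spec in self.de_genes:
            if not (0 <= spec.gene_index < self.n_genes):
                raise ValidationError(f"DE gene index {spec.gene_index} out of range")
        if self.mt_block is not None:
            for i in self.mt_block.gene_indices:
                if not (0 <= i < self.n_genes):
                    raise ValidationError(f"block gene index {i} out of range")


def _build_metadata(
    config: SimulationConfig, rng: np.random.Generator
) -> list[SampleMetadata]:
    rows: list[SampleMetadata] = []
    for (sex, group), n in sorted(config.group_sizes.items()):
        for i in range(n):
            sid = f"{sex[0]}_{group}_{i:03d}"
            if group == "control":
                status, sub, cohort = "control", "none", "discovery"
            elif group == "confirmation":
                status, sub, cohort = "case", "none", "confirmation"
            else:
                status, sub, cohort = "case", group, "discovery"
            rows.append(
                SampleMetadata(
                    sample_id=sid,
                    disease_status=status,
                    sex=sex,
                    subphenotype=sub,
                    cohort=cohort,
                )
            )
    return rows


def _affected(spec: DEGeneSpec, meta: SampleMetadata) -> bool:
    if meta.disease_status != "case" or meta.sex not in spec.sexes:
        return False
    if spec.subphenotypes is None:
        return True
    return any(subphenotype_matches(meta.subphenotype, s) for s in spec.subphenotypes)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[CountMatrix, list[SampleMetadata], pd.DataFrame]:
    """Generate (counts, metadata, ground truth) from the config.

    The ground-truth table lists every non-null gene with its mode and
    fold; block genes are tagged ``mt_block``.  Identical configs
    (including the seed) produce identical output.
    """
    rng = np.random.default_rng(config.seed)
    metadata = _build_metadata(config, rng)
    n_samples = len(metadata)
    if n_samples == 0:
        raise ValidationError("empty cohort: all group sizes are zero")
    n_genes = config.n_genes

    gene_ids = [f"ENSG{i:011d}.1" for i in range(n_genes)]

    rel = 2.0 ** rng.normal(config.log2_baseline_mean, config.log2_baseline_sd, n_genes)
    block_idx: tuple[int, ...] = ()
    if config.mt_block is not None:
        block_idx = config.mt_block.gene_indices
        f = config.mt_block.baseline_cpm / 1e6
        other = np.delete(rel, list(block_idx)).sum()
        rel[list(block_idx)] = f * other / (1 - len(block_idx) * f)
    frac = rel / rel.sum()

    dispersion = rng.gamma(
        config.dispersion_shape,
        config.dispersion_mean / config.dispersion_shape,
        n_genes,
    )
    lo, hi = config.library_size_range
    lib = rng.uniform(lo, hi, n_samples)

    fold = np.ones((n_genes, n_samples))
    truth_rows = []

    # block multiplier per sample, reused for the covariate link
    block_mult = np.ones(n_samples)
    if config.mt_block is not None:
        mb = config.mt_block
        for j, meta in enumerate(metadata):
            hit = False
            if meta.sex in mb.sexes:
                if meta.cohort == "discovery" and subphenotype_matches(
                    meta.subphenotype, mb.subgroup
                ):
                    hit = True
                elif meta.cohort == "confirmation" and meta.disease_status == "case":
                    hit = rng.random() < mb.confirmation_fraction
            if hit:
                block_mult[j] = mb.fold
        fold[list(mb.gene_indices), :] *= block_mult
        for i in mb.gene_indices:
            truth_rows.append(
                {
                    "gene_id": gene_ids[i],
                    "kind": "mt_block",
                    "fold": mb.fold,
                    "mode": "median_shift",
                    "subphenotypes": mb.subgroup,
                    "sexes": ",".join(mb.sexes),
                    "tail_fraction": float("nan"),
                }
            )

    for spec in config.de_genes:
        affected = np.array([_affected(spec, m) for m in metadata])
        if spec.mode == "upper_tail_shift":
            idx = np.flatnonzero(affected)
            k = max(1, int(round(spec.tail_fraction * idx.size))) if idx.size else 0
            chosen = rng.choice(idx, size=k, replace=False) if k else idx
            mask = np.zeros(n_samples, dtype=bool)
            mask[chosen] = True
        else:
            mask = affected
        fold[spec.gene_index, mask] *= spec.fold
        truth_rows.append(
            {
                "gene_id": gene_ids[spec.gene_index],
                "kind": spec.mode,
                "fold": spec.fold,
                "mode": spec.mode,
                "subphenotypes": (
                    "all_cases"
                    if spec.subphenotypes is None
                    else ",".join(spec.subphenotypes)
                ),
                "sexes": ",".join(spec.sexes),
                "tail_fraction": (
                    spec.tail_fraction if spec.mode == "upper_tail_shift" else float("nan")
                ),
            }
        )

    mu = frac[:, None] * lib[None, :] * fold
    nb_n = 1.0 / dispersion
    p = nb_n[:, None] / (nb_n[:, None] + mu)
    counts = rng.negative_binomial(np.broadcast_to(nb_n[:, None], mu.shape), p)
    matrix = CountMatrix(gene_ids, [m.sample_id for m in metadata], counts.astype(np.int64))

    # covariates
    cov = config.covariates
    log2_mult = np.log2(block_mult)
    enriched: list[SampleMetadata] = []
    for j, meta in enumerate(metadata):
        if meta.disease_status == "control":
            fev = float(np.clip(rng.normal(0.81, 0.025), 0.70, 0.95))
        else:
            fev = float(np.clip(rng.normal(0.55, 0.08), 0.20, 0.74))
        tlco = cov.tlco_intercept + cov.tlco_slope * log2_mult[j] + rng.normal(0, cov.noise_sd)
        tlc = cov.tlc_intercept + cov.tlc_slope * log2_mult[j] + rng.normal(0, cov.noise_sd)
        enriched.append(
            replace(meta, fev1_fvc=round(fev, 4), tlco_va=round(float(tlco), 4), tlc=round(float(tlc), 4))
        )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "gene_id",
            "kind",
            "fold",
            "mode",
            "subphenotypes",
            "sexes",
            "tail_fraction",
        ],
    )
    return matrix, enriched, truth


def simulate_qpcr(
    folds: Mapping[tuple[str, str], float],
    reference_ct: float = 24.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[QpcrMeasurement]:
    """Generate Ct readings whose 2^|dCt| recovers the configured folds.

    ``folds`` maps (sample_id, gene_name) to the intended fold
    enrichment over the housekeeping reference.  The target gene's Ct is
    ``reference_ct - log2(fold)`` plus Gaussian noise; with zero noise
    the fold is recovered exactly.
    """
    rng = np.random.default_rng(seed)
    out = []
    for (sample_id, gene_name), fold in sorted(folds.items()):
        if fold <= 0:
            raise ValidationError(f"fold for {(sample_id, gene_name)} must be > 0")
        ct = reference_ct - float(np.log2(fold)) + float(rng.normal(0, noise_sd))
        out.append(
            QpcrMeasurement(
                sample_id=sample_id,
                gene_name=gene_name,
                ct=ct,
                housekeeping_ct=reference_ct,
            )
        )
    return out
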