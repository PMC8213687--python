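"""Between-sample scaling with trimmed means of M-values (TMM) and cpm.

The scaling factors are computed from the published TMM definition:
pairwise log-ratios (M) and average log-abundances (A) against a
reference sample, doubly trimmed (30% on M, 5% on A by default), then
averaged with inverse approximate-variance (precision) weights.  Factors
are rescaled so their geometric mean is 1.  Counts-per-million divide
each count by the product of library size and scaling factor.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .io import CountMatrix, NormalizedMatrix, ValidationError

__all__ = ["tmm_factors", "cpm_normalize", "normalize_counts"]


def _quantile(values: np.ndarray, level: float) -> float:
    # linear interpolation between order statistics (R type 7)
    return float(np.quantile(values, level, method="linear"))


def _choose_reference(counts: np.ndarray, lib_sizes: np.ndarray) -> int:
    """Sample whose upper-quartile count fraction is closest to the mean."""
    f75 = np.array(
        [_quantile(counts[:, j], 0.75) / lib_sizes[j] for j in range(counts.shape[1])]
    )
    return int(np.argmin(np.abs(f75 - f75.mean())))


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_logfc: float,
    trim_abundance: float,
) -> float:
    """log2 scaling factor of ``obs`` relative to ``ref``."""
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        return 0.0
    o = obs[keep].astype(float)
    r = ref[keep].astype(float)
    po = o / lib_obs
    pr = r / lib_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    if np.max(np.abs(m)) < 1e-6:
        return 0.0
    n = m.size
    lo_m = int(np.floor(n * trim_logfc)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * trim_abundance)) + 1
    hi_a = n + 1 - lo_a
    # ranks are 1-based; average ranks keep the double trim symmetric on ties
    from scipy.stats import rankdata

    rank_m = rankdata(m)
    rank_a = rankdata(a)
    sel = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not sel.any():
        return 0.0
    # precision weights: inverse of the delta-method variance of each M value
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    f = float(np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel]))
    if not np.isfinite(f):
        return 0.0
    return f


def tmm_factors(
    counts: CountMatrix | np.ndarray,
    trim_logfc: float = 0.30,
    trim_abundance: float = 0.05,
) -> np.ndarray:
    """Per-sample TMM scaling factors, geometric-mean normalized to 1.

    Requires at least two samples and at least one positive count per
    sample.  A pure library-size difference between samples yields unit
    factors: it is absorbed by the cpm denominator, not by TMM.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    sample_ids = (
        counts.sample_ids
        if isinstance(counts, CountMatrix)
        else [str(j) for j in range(mat.shape[1])]
    )
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise ValidationError("TMM requires a genes x samples matrix with >= 2 samples")
    lib = mat.sum(axis=0).astype(float)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise ValidationError(f"sample {sample_ids[zero[0]]!r} has all-zero counts")
    ref = _choose_reference(mat, lib)
    log_factors = np.array(
        [
            _tmm_pair(mat[:, j], mat[:, ref], lib[j], lib[ref], trim_logfc, trim_abundance)
            for j in range(mat.shape[1])
        ]
    )
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def cpm_normalize(
    counts: CountMatrix, factors: Optional[Sequence[float]] = None
) -> NormalizedMatrix:
    """Counts per million with optional TMM scaling factors.

    cpm[g, s] = counts[g, s] / (library_size[s] * factor[s]) * 1e6.
    With all-ones factors every sample's cpm column sums to 1e6.
    """
    if factors is None:
        factors = np.ones(counts.n_samples)
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (counts.n_samples,):
        raise ValidationError("one scaling factor per sample required")
    if (factors <= 0).any() or not np.isfinite(factors).all():
        raise ValidationError("scaling factors must be finite and > 0")
    lib = counts.counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        j = int(np.flatnonzero(lib == 0)[0])
        raise ValidationError(f"sample {counts.sample_ids[j]!r} has all-zero counts")
    cpm = counts.counts / (lib * factors) * 1e6
    return NormalizedMatrix(
        gene_ids=list(counts.gene_ids),
        sample_ids=list(counts.sample_ids),
        cpm=cpm,
        scaling_factors=factors,
    )


def normalize_counts(counts: CountMatrix, method: str = "tmm") -> NormalizedMatrix:
    """Convenience: TMM factors + cpm (``method='none'`` for plain cpm)."""
    if method == "tmm":
        return cpm_normalize(counts, tmm_factors(counts))
    if method == "none":
        return cpm_normalize(counts, None)
    raise ValueError(f"unknown normalization method {method!r}")
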