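"""Gene-set signature scoring, clustering, association and qPCR arithmetic.

The default signature is the eight mitochondria-encoded oxidative-
phosphorylation genes; a sample's score is the plain sum of its cpm
values over the set.  Samples are split into "high"/"low" expression
clusters by hierarchical clustering of the row-z-scored signature
sub-matrix, and cluster/phenotype enrichment is assessed with a
two-sided Fisher exact probability.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .io import NormalizedMatrix, ValidationError
from .permtest import bh_fdr

__all__ = [
    "GeneSet",
    "SignatureScore",
    "ClusterAssignment",
    "MT_SIGNATURE_GENES",
    "signature_score",
    "compare_groups_wilcoxon",
    "cluster_mt_signature",
    "extreme_score_samples",
    "fisher_exact_2x2",
    "spearman_assoc",
    "linear_assoc",
    "ddct_fold",
    "genomic_copy_ratio",
]

#: The eight mitochondria-encoded signature genes.
MT_SIGNATURE_GENES = (
    "MT-ND1",
    "MT-ND2",
    "MT-ND3",
    "MT-ND5",
    "MT-CO1",
    "MT-CO2",
    "MT-CO3",
    "MT-ATP6",
)


@dataclass(frozen=True)
class GeneSet:
    name: str
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValidationError("gene set must be non-empty")


MT_SIGNATURE = GeneSet("mt_signature", MT_SIGNATURE_GENES)


@dataclass(frozen=True)
class SignatureScore:
    sample_id: str
    score: float


@dataclass
class ClusterAssignment:
    sample_id: str
    cluster: str  # "high" | "low"


def _resolve_rows(norm: NormalizedMatrix, gene_set: GeneSet) -> list[int]:
    rows = []
    missing = []
    for gid in gene_set.gene_ids:
        try:
            rows.append(norm.gene_index(gid))
        except KeyError:
            missing.append(gid)
    if missing:
        raise ValidationError(f"gene set {gene_set.name!r}: missing gene id(s) {missing}")
    return rows


def signature_score(
    norm: NormalizedMatrix, gene_set: GeneSet = MT_SIGNATURE
) -> list[SignatureScore]:
    """Per-sample sum of cpm over the gene set (exact column sums)."""
    rows = _resolve_rows(norm, gene_set)
    sums = norm.cpm[rows].sum(axis=0)
    return [SignatureScore(s, float(v)) for s, v in zip(norm.sample_ids, sums)]


def compare_groups_wilcoxon(
    values1: Sequence[float], values2: Sequence[float]
) -> float:
    """Two-sided rank-sum p-value between two groups.

    Exact by enumeration of all C(n1+n2, n1) label assignments of the
    pooled mid-ranks when the combined size is at most 20; tie-corrected
    normal approximation (Mann-Whitney U) otherwise.
    """
    x = np.asarray(values1, dtype=float)
    y = np.asarray(values2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    if n <= 20:
        ranks = stats.rankdata(np.concatenate([x, y]))
        w_obs = ranks[:n1].sum()
        mu = n1 * (n + 1) / 2.0
        dev = abs(w_obs - mu)
        hits = 0
        total = 0
        for comb in itertools.combinations(range(n), n1):
            w = ranks[list(comb)].sum()
            if abs(w - mu) >= dev - 1e-9:
                hits += 1
            total += 1
        return hits / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def cluster_mt_signature(
    norm: NormalizedMatrix,
    gene_set: GeneSet = MT_SIGNATURE,
    sample_ids: Optional[Sequence[str]] = None,
    metric: str = "euclidean",
    method: str = "complete",
) -> tuple[list[ClusterAssignment], np.ndarray]:
    """Two-way split of samples by hierarchical clustering of the signature.

    Each gene row of the signature sub-matrix is z-scored (row scaling),
    samples are clustered on the chosen distance/linkage, the tree is cut
    into two clusters, and the cluster with the higher mean signature
    score is labelled "high".  Zero-variance gene rows are dropped with a
    warning.  Returns the assignments and the linkage matrix.
    """
    rows = _resolve_rows(norm, gene_set)
    if sample_ids is None:
        sample_ids = list(norm.sample_ids)
        cols = list(range(len(sample_ids)))
    else:
        col = {s: j for j, s in enumerate(norm.sample_ids)}
        try:
            cols = [col[s] for s in sample_ids]
        except KeyError as exc:
            raise ValidationError(f"sample {exc.args[0]!r} not in matrix") from None
    if len(cols) < 4:
        raise ValidationError("clustering requires at least 4 samples")
    sub = norm.cpm[np.ix_(rows, cols)].astype(float)
    sd = sub.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [gene_set.gene_ids[i] for i in np.flatnonzero(~keep)]
        warnings.warn(f"dropping zero-variance gene row(s): {dropped}", stacklevel=2)
    if not keep.any():
        raise ValidationError("all signature genes have zero variance; nothing to cluster")
    z = (sub[keep] - sub[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    profiles = z.T  # samples x genes
    if np.allclose(pdist(profiles, metric=metric), 0):
        raise ValidationError("all samples identical under the signature; degenerate clustering")
    tree = linkage(profiles, method=method, metric=metric)
    labels = fcluster(tree, t=2, criterion="maxclust")
    scores = sub.sum(axis=0)
    means = {c: scores[labels == c].mean() for c in np.unique(labels)}
    if len(means) < 2:
        raise ValidationError("tree cut produced a single cluster; degenerate clustering")
    high = max(means, key=means.get)
    assignments = [
        ClusterAssignment(s, "high" if c == high else "low")
        for s, c in zip(sample_ids, labels)
    ]
    return assignments, tree


def extreme_score_samples(
    scores: Sequence[SignatureScore], k: int = 5
) -> tuple[list[str], list[str]]:
    """(top-k, bottom-k) sample ids by signature score (surrogate subsets)."""
    if k <= 0 or 2 * k > len(scores):
        raise ValidationError(f"need at least 2k={2 * k} scored samples")
    ordered = sorted(scores, key=lambda s: (-s.score, s.sample_id))
    return [s.sample_id for s in ordered[:k]], [s.sample_id for s in ordered[-k:]]


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact probability of a 2x2 table.

    Sums the hypergeometric probabilities of all tables with the same
    margins whose probability does not exceed the observed one (with a
    1 + 1e-7 relative slack against float round-off).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValidationError("table must be 2x2")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        raise ValidationError("table entries must be non-negative integers")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1 = a + b
    col1 = a + c
    dist = stats.hypergeom(n, row1, col1)
    kmin = max(0, col1 - (c + d))
    kmax = min(row1, col1)
    ks = np.arange(kmin, kmax + 1)
    pmf = dist.pmf(ks)
    p_obs = dist.pmf(a)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def spearman_assoc(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 9
) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Ties are mid-ranked.  For n <= ``exact_max_n`` the p-value is exact
    by enumeration of all n! rank permutations; beyond that the usual
    t-approximation is used.  A constant input vector has no defined
    rank correlation: returns (nan, nan) with a warning.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size or xv.size < 3:
        raise ValidationError("need equal-length vectors with n >= 3")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        warnings.warn("constant vector: Spearman rho undefined", stacklevel=2)
        return float("nan"), float("nan")
    rx = stats.rankdata(xv)
    ry = stats.rankdata(yv)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = xv.size
    if n <= exact_max_n:
        cx = rx - rx.mean()
        cy = ry - ry.mean()
        denom = math.sqrt(float(cx @ cx) * float(cy @ cy))
        obs = abs(float(cx @ cy))
        hits = 0
        total = 0
        for perm in itertools.permutations(cy):
            if abs(float(cx @ np.asarray(perm))) >= obs - 1e-9 * denom:
                hits += 1
            total += 1
        return rho, hits / total
    if abs(rho) >= 1.0:
        return rho, 0.0
    tstat = rho * math.sqrt((n - 2) / (1 - rho * rho))
    p = 2 * stats.t.sf(abs(tstat), df=n - 2)
    return rho, float(p)


def linear_assoc(
    scores: Sequence[float],
    covariates: Mapping[str, Sequence[float]],
) -> pd.DataFrame:
    """OLS regression of each covariate on the signature score.

    Missing covariate values are dropped pairwise; p-values are adjusted
    with Benjamini-Hochberg across the covariates tested.  Returns a
    table with slope, slope sign, p and fdr per covariate.
    """
    s = np.asarray(scores, dtype=float)
    rows = []
    for name, cov in covariates.items():
        c = np.asarray(
            [float("nan") if v is None else float(v) for v in cov], dtype=float
        )
        if c.size != s.size:
            raise ValidationError(f"covariate {name!r} length mismatch")
        keep = np.isfinite(c) & np.isfinite(s)
        if keep.sum() < 3:
            raise ValidationError(f"covariate {name!r}: fewer than 3 complete pairs")
        if np.ptp(c[keep]) == 0:
            raise ValidationError(f"covariate {name!r} is constant")
        fit = stats.linregress(s[keep], c[keep])
        rows.append(
            {
                "covariate": name,
                "n": int(keep.sum()),
                "slope": float(fit.slope),
                "slope_sign": "positive" if fit.slope > 0 else "negative",
                "p_value": float(fit.pvalue),
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(np.clip(out["p_value"].to_numpy(), 1e-300, 1.0))
    return out


def ddct_fold(ct_gene: float, ct_reference: float) -> float:
    """Fold enrichment from a cycle-threshold difference: 2^|dCt|."""
    if not (math.isfinite(ct_gene) and math.isfinite(ct_reference)):
        raise ValidationError("Ct values must be finite")
    return 2.0 ** abs(ct_gene - ct_reference)


def genomic_copy_ratio(fold_group1: float, fold_group2: float) -> float:
    """Ratio of two fold enrichments, display-rounded to one decimal."""
    if fold_group1 <= 0 or fold_group2 <= 0:
        raise ValidationError("fold enrichments must be positive")
    return round(fold_group1 / fold_group2, 1)
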