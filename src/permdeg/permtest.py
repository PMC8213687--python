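"""Exact and Monte-Carlo permutation tests on quantile differences.

The test statistic for one gene and one quantile level is

    Y = | q(group1 cpm) - q(group2 cpm) |

where q is the lower quartile, median, or upper quartile of the
per-sample expression values.  Under the null hypothesis that both
groups share one expression distribution, every assignment of the n1
group-1 labels among the n1+n2 pooled values is equally likely, so the
p-value of an observed difference x is P(Y >= x) over all C(n1+n2, n1)
assignments.  When full enumeration exceeds the budget, the assignment
distribution is sampled instead (seeded, add-one estimator).

Enumeration exploits that quantiles under linear interpolation depend
only on two fixed order statistics: combinations of indices into the
*sorted* pooled vector are themselves sorted, so each group quantile is
an affine function of two fancy-indexed columns.
"""

from __future__ import annotations

import hashlib
import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import numpy as np

from .io import NormalizedMatrix, SampleMetadata, ValidationError, select_samples

__all__ = [
    "QuantileSpec",
    "QuantileTestResult",
    "DEFAULT_SPECS",
    "LEVEL_NAMES",
    "group_quantile",
    "exact_perm_pvalue",
    "monte_carlo_perm_pvalue",
    "perm_pvalue",
    "test_all_genes",
    "bh_fdr",
    "EnumerationBudgetExceeded",
]

#: Default enumeration budget: exact engine when C(n, n1) is at most this.
DEFAULT_BUDGET = 200_000
#: Default Monte-Carlo sample size.
DEFAULT_N_PERM = 100_000

LEVEL_NAMES = {0.25: "q1", 0.5: "median", 0.75: "q3"}


class EnumerationBudgetExceeded(RuntimeError):
    """Exact enumeration would exceed the assignment budget; use Monte Carlo."""


@dataclass(frozen=True)
class QuantileSpec:
    """A tested quantile level with its interpolation rule.

    ``interpolation='linear'`` interpolates between order statistics at
    h = level * (m - 1); ``'lower'`` takes the order statistic at
    floor(h).
    """

    level: float
    interpolation: str = "linear"

    def __post_init__(self) -> None:
        if self.level not in (0.25, 0.5, 0.75):
            raise ValidationError(
                f"quantile level must be one of 0.25, 0.5, 0.75; got {self.level}"
            )
        if self.interpolation not in ("linear", "lower"):
            raise ValidationError(f"unknown interpolation {self.interpolation!r}")

    @property
    def name(self) -> str:
        return LEVEL_NAMES[self.level]


DEFAULT_SPECS = (QuantileSpec(0.25), QuantileSpec(0.5), QuantileSpec(0.75))


@dataclass
class QuantileTestResult:
    gene_id: str
    quantile_level: float
    y_obs: float
    p_value: float
    fdr: Optional[float]
    engine: str  # "exact_enumeration" | "monte_carlo"
    n_permutations_used: int
    q_group1: float
    q_group2: float


def _interp_positions(m: int, spec: QuantileSpec) -> tuple[int, int, float]:
    """(lower index, upper index, fraction) for a size-m sorted vector."""
    h = spec.level * (m - 1)
    j = int(math.floor(h))
    if spec.interpolation == "lower":
        return j, j, 0.0
    g = h - j
    j2 = min(j + 1, m - 1)
    return j, j2, g


def group_quantile(values: Sequence[float], spec: QuantileSpec) -> float:
    """Quantile of a non-empty vector under the spec's interpolation rule."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("cannot take a quantile of an empty vector")
    v = np.sort(v)
    j, j2, g = _interp_positions(v.size, spec)
    return float(v[j] + g * (v[j2] - v[j]))


@lru_cache(maxsize=32)
def _enumeration_indices(n: int, n1: int) -> tuple[np.ndarray, np.ndarray]:
    """All C(n, n1) sorted index combinations and their sorted complements."""
    ncomb = math.comb(n, n1)
    comb = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n), n1)),
        dtype=np.int64,
        count=ncomb * n1,
    ).reshape(ncomb, n1)
    mask = np.zeros((ncomb, n), dtype=bool)
    mask[np.arange(ncomb)[:, None], comb] = True
    comp = np.nonzero(~mask)[1].reshape(ncomb, n - n1)
    return comb, comp

def _quantiles_from_sorted_rows(
    sorted_vals: np.ndarray, rows: np.ndarray, m: int, spec: QuantileSpec
) -> np.ndarray:
    """Group quantile for many sorted index rows into a sorted pooled vector."""
    j, j2, g = _interp_positions(m, spec)
    lo = sorted_vals[rows[:, j]]
    if g == 0.0:
        return lo
    hi = sorted_vals[rows[:, j2]]
    return lo + g * (hi - lo)


def _y_tolerance(y_obs: float) -> float:
    # counting rule: Y >= y_obs up to float round-off in the interpolation
    return 1e-9 * (1.0 + abs(y_obs))


def exact_perm_pvalue(
    group1: Sequence[float],
    group2: Sequence[float],
    spec: QuantileSpec,
    budget: int = DEFAULT_BUDGET,
    gene_id: str = "",
) -> QuantileTestResult:
    """Exact permutation p-value by full enumeration of label assignments.

    p = #{assignments with Y >= y_obs} / C(n1+n2, n1).  The observed
    assignment is in the enumerated set, so p > 0 always.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise ValidationError("both groups must be non-empty")
    n1, n2 = g1.size, g2.size
    n = n1 + n2
    ncomb = math.comb(n, n1)
    if ncomb > budget:
        raise EnumerationBudgetExceeded(
            f"C({n}, {n1}) = {ncomb} exceeds the enumeration budget {budget}; "
            "use the monte_carlo engine"
        )
    q1 = group_quantile(g1, spec)
    q2 = group_quantile(g2, spec)
    y_obs = abs(q1 - q2)
    pooled = np.sort(np.concatenate([g1, g2]))
    comb, comp = _enumeration_indices(n, n1)
    ya = _quantiles_from_sorted_rows(pooled, comb, n1, spec)
    yb = _quantiles_from_sorted_rows(pooled, comp, n2, spec)
    y = np.abs(ya - yb)
    hits = int(np.count_nonzero(y >= y_obs - _y_tolerance(y_obs)))
    return QuantileTestResult(
        gene_id=gene_id,
        quantile_level=spec.level,
        y_obs=y_obs,
        p_value=hits / ncomb,
        fdr=None,
        engine="exact_enumeration",
        n_permutations_used=ncomb,
        q_group1=q1,
        q_group2=q2,
    )


def monte_carlo_perm_pvalue(
    group1: Sequence[float],
    group2: Sequence[float],
    spec: QuantileSpec,
    n_perm: int = DEFAULT_N_PERM,
    seed: Optional[int | np.random.Generator] = None,
    gene_id: str = "",
) -> QuantileTestResult:
    """Sampled permutation p-value with the add-one estimator.

    p = (1 + #{sampled assignments with Y >= y_obs}) / (n_perm + 1),
    which is never 0 and never below 1/(n_perm + 1).  Identical seed and
    inputs give an identical p-value.
    """
    if n_perm < 1000:
        raise ValidationError("n_perm must be >= 1000")
    if seed is None:
        raise ValidationError("a seed (or Generator) is required for reproducibility")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise ValidationError("both groups must be non-empty")
    n1, n2 = g1.size, g2.size
    n = n1 + n2
    q1 = group_quantile(g1, spec)
    q2 = group_quantile(g2, spec)
    y_obs = abs(q1 - q2)
    pooled = np.sort(np.concatenate([g1, g2]))
    tol = _y_tolerance(y_obs)
    hits = 0
    # chunked so memory stays ~ tens of MB regardless of n_perm
    chunk = max(1, min(n_perm, 20_000_000 // max(n, 1)))
    done = 0
    base = np.broadcast_to(np.arange(n), (chunk, n))
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perm = rng.permuted(base[:b], axis=1)
        rows1 = np.sort(perm[:, :n1], axis=1)
        rows2 = np.sort(perm[:, n1:], axis=1)
        ya = _quantiles_from_sorted_rows(pooled, rows1, n1, spec)
        yb = _quantiles_from_sorted_rows(pooled, rows2, n2, spec)
        hits += int(np.count_nonzero(np.abs(ya - yb) >= y_obs - tol))
        done += b
    return QuantileTestResult(
        gene_id=gene_id,
        quantile_level=spec.level,
        y_obs=y_obs,
        p_value=(1 + hits) / (n_perm + 1),
        fdr=None,
        engine="monte_carlo",
        n_permutations_used=n_perm,
        q_group1=q1,
        q_group2=q2,
    )


def perm_pvalue(
    group1: Sequence[float],
    group2: Sequence[float],
    spec: QuantileSpec,
    engine: str = "auto",
    budget: int = DEFAULT_BUDGET,
    n_perm: int = DEFAULT_N_PERM,
    seed: Optional[int | np.random.Generator] = None,
    gene_id: str = "",
) -> QuantileTestResult:
    """Dispatch to exact enumeration or Monte Carlo under the budget."""
    if engine == "exact":
        return exact_perm_pvalue(group1, group2, spec, budget=budget, gene_id=gene_id)
    if engine == "monte_carlo":
        return monte_carlo_perm_pvalue(
            group1, group2, spec, n_perm=n_perm, seed=seed, gene_id=gene_id
        )
    if engine != "auto":
        raise ValueError(f"unknown engine {engine!r}")
    n1 = len(group1)
    if math.comb(n1 + len(group2), n1) <= budget:
        return exact_perm_pvalue(group1, group2, spec, budget=budget, gene_id=gene_id)
    return monte_carlo_perm_pvalue(
        group1, group2, spec, n_perm=n_perm, seed=seed, gene_id=gene_id
    )


def _gene_rng(seed: int, gene_id: str, level: float) -> np.random.Generator:
    # counter-based per-gene seeding keyed on the gene id (not the row
    # index) so results do not depend on gene iteration order
    digest = hashlib.sha256(f"{gene_id}|{level}".encode()).digest()
    words = np.frombuffer(digest[:16], dtype=np.uint32)
    return np.random.default_rng(np.random.SeedSequence([seed, *map(int, words)]))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values.

    Adjusted values are monotone in the sorted order and never below the
    raw p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def test_all_genes(
    norm: NormalizedMatrix,
    metadata: Sequence[SampleMetadata],
    comparison: tuple[dict, dict],
    specs: Iterable[QuantileSpec] = DEFAULT_SPECS,
    engine: str = "auto",
    budget: int = DEFAULT_BUDGET,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    fdr_scope: str = "per_level",
) -> list[QuantileTestResult]:
    """Run the permutation test for every gene at every quantile level.

    ``comparison`` is a pair of sample selectors (keyword dictionaries
    understood by :func:`permdeg.io.select_samples`).  The engine is
    chosen per the enumeration budget and recorded in each result.
    Multiple-testing adjustment is Benjamini-Hochberg, by default within
    each quantile level separately (``fdr_scope='joint'`` corrects across
    genes x levels jointly).
    """
    sel_a, sel_b = comparison
    ids_a = select_samples(metadata, **sel_a)
    ids_b = select_samples(metadata, **sel_b)
    if not ids_a or not ids_b:
        empty = sel_a if not ids_a else sel_b
        raise ValidationError(f"selector {empty!r} matches no samples")
    col = {s: j for j, s in enumerate(norm.sample_ids)}
    try:
        cols_a = [col[s] for s in ids_a]
        cols_b = [col[s] for s in ids_b]
    except KeyError as exc:
        raise ValidationError(f"sample {exc.args[0]!r} not present in the matrix") from None
    specs = tuple(specs)
    if fdr_scope not in ("per_level", "joint"):
        raise ValueError(f"unknown fdr_scope {fdr_scope!r}")

    results: list[QuantileTestResult] = []
    for g, gene_id in enumerate(norm.gene_ids):
        row = norm.cpm[g]
        g1 = row[cols_a]
        g2 = row[cols_b]
        for spec in specs:
            res = perm_pvalue(
                g1,
                g2,
                spec,
                engine=engine,
                budget=budget,
                n_perm=n_perm,
                seed=_gene_rng(seed, gene_id, spec.level),
                gene_id=gene_id,
            )
            results.append(res)

    if fdr_scope == "per_level":
        for spec in specs:
            sub = [r for r in results if r.quantile_level == spec.level]
            adj = bh_fdr([r.p_value for r in sub])
            for r, a in zip(sub, adj):
                r.fdr = float(a)
    else:
        adj = bh_fdr([r.p_value for r in results])
        for r, a in zip(results, adj):
            r.fdr = float(a)
    return results


def results_to_frame(results: Sequence[QuantileTestResult]):
    """Tidy DataFrame view of test results (one row per gene x level)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "level": [LEVEL_NAMES[r.quantile_level] for r in results],
            "y_obs": [r.y_obs for r in results],
            "q_group1": [r.q_group1 for r in results],
            "q_group2": [r.q_group2 for r in results],
            "p_value": [r.p_value for r in results],
            "fdr": [r.fdr for r in results],
            "engine": [r.engine for r in results],
            "n_permutations": [r.n_permutations_used for r in results],
        }
    )
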