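"""Shared domain types and tabular I/O.

Count matrices are read from tab-separated tables (genes in rows, first
column the gene identifier, header row of sample identifiers) or from
MatrixMarket triplet files with plain-text side files naming rows and
columns.  Sample metadata travels as a fixed-column TSV.  All result
tables are tab-separated UTF-8 with ``.`` as the decimal separator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "ValidationError",
    "CountMatrix",
    "SampleMetadata",
    "NormalizedMatrix",
    "QpcrMeasurement",
    "DEGRecord",
    "SUBPHENOTYPES",
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_metadata",
    "filter_eligible_controls",
    "select_samples",
    "subphenotype_matches",
    "write_deg_table",
    "read_deg_table",
    "write_cpm_table",
    "read_cpm_table",
]


class ParseError(ValueError):
    """A file could not be parsed under the declared dialect."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


#: Recognised computed-tomography sub-phenotype labels.  ``none`` marks
#: controls and confirmation-cohort cases, which carry no imaging label.
SUBPHENOTYPES = ("E", "A", "Eex", "Aex", "mixed", "normalCT", "none")

_METADATA_COLUMNS = (
    "sample_id",
    "disease_status",
    "sex",
    "subphenotype",
    "cohort",
    "fev1_fvc",
    "tlco_va",
    "tlc",
)


def strip_version(gene_id: str) -> str:
    """Drop a trailing ``.N`` version suffix from an Ensembl-style id."""
    base, dot, suffix = gene_id.rpartition(".")
    if dot and suffix.isdigit():
        return base
    return gene_id


@dataclass
class CountMatrix:
    """Raw integer read counts, genes x samples.

    Gene identifiers keep any version suffix verbatim; a version-stripped
    alias index is available through :meth:`gene_index` for lookups.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if np.issubdtype(self.counts.dtype, np.floating):
            bad = ~np.isfinite(self.counts) | (self.counts != np.floor(self.counts))
            if bad.any():
                g, s = np.argwhere(bad)[0]
                raise ValidationError(
                    f"non-integer count at gene {self.gene_ids[g]!r}, "
                    f"sample {self.sample_ids[s]!r}: {self.counts[g, s]}"
                )
            self.counts = self.counts.astype(np.int64)
        elif not np.issubdtype(self.counts.dtype, np.integer):
            raise ValidationError(f"counts dtype {self.counts.dtype} is not integral")
        if (self.counts < 0).any():
            g, s = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}: {self.counts[g, s]}"
            )
        stripped = [strip_version(g) for g in self.gene_ids]
        if len(set(stripped)) != len(stripped):
            seen: set[str] = set()
            for g in stripped:
                if g in seen:
                    raise ValidationError(f"duplicate gene id (after version strip): {g!r}")
                seen.add(g)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("sample_ids are not unique")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene_id: str) -> int:
        """Row index of ``gene_id``; falls back to version-stripped match."""
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            pass
        stripped = strip_version(gene_id)
        for i, g in enumerate(self.gene_ids):
            if strip_version(g) == stripped:
                return i
        raise KeyError(gene_id)


@dataclass(frozen=True)
class SampleMetadata:
    """One metadata row per sample.

    ``Eex`` samples are a subset of ``E`` (and ``Aex`` of ``A``) in every
    comparison that requests the broader label; see
    :func:`subphenotype_matches`.
    """

    sample_id: str
    disease_status: str  # "case" | "control"
    sex: str  # "male" | "female"
    subphenotype: str = "none"
    cohort: str = "discovery"
    fev1_fvc: Optional[float] = None
    tlco_va: Optional[float] = None
    tlc: Optional[float] = None

    def __post_init__(self) -> None:
        if self.disease_status not in ("case", "control"):
            raise ValidationError(f"bad disease_status {self.disease_status!r}")
        if self.sex not in ("male", "female"):
            raise ValidationError(f"bad sex {self.sex!r}")
        if self.subphenotype not in SUBPHENOTYPES:
            raise ValidationError(f"unknown subphenotype {self.subphenotype!r}")
        if self.cohort not in ("discovery", "confirmation"):
            raise ValidationError(f"bad cohort {self.cohort!r}")
        if self.disease_status == "control" and self.subphenotype != "none":
            raise ValidationError(
                f"control {self.sample_id!r} must have subphenotype 'none'"
            )


@dataclass
class NormalizedMatrix:
    """Counts-per-million expression, scaled by per-sample factors."""

    gene_ids: list[str]
    sample_ids: list[str]
    cpm: np.ndarray
    scaling_factors: np.ndarray

    def __post_init__(self) -> None:
        self.cpm = np.asarray(self.cpm, dtype=float)
        self.scaling_factors = np.asarray(self.scaling_factors, dtype=float)
        if self.cpm.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError("cpm shape mismatch")
        if (self.cpm < 0).any() or not np.isfinite(self.cpm).all():
            raise ValidationError("cpm values must be finite and >= 0")
        if (self.scaling_factors <= 0).any():
            raise ValidationError("scaling factors must be > 0")

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            pass
        stripped = strip_version(gene_id)
        for i, g in enumerate(self.gene_ids):
            if strip_version(g) == stripped:
                return i
        raise KeyError(gene_id)


@dataclass(frozen=True)
class QpcrMeasurement:
    """A single qPCR cycle-threshold reading plus its housekeeping reference."""

    sample_id: str
    gene_name: str
    ct: float
    housekeeping_ct: float

    def __post_init__(self) -> None:
        for name, v in (("ct", self.ct), ("housekeeping_ct", self.housekeeping_ct)):
            if not math.isfinite(v) or v <= 0:
                raise ValidationError(f"{name} must be finite and > 0, got {v}")


@dataclass
class DEGRecord:
    """A called differentially expressed gene.

    ``ratio`` is always >= 1 with ``direction`` indicating which group is
    higher (``up`` = case above control).  ``qualifying_levels`` lists the
    quantile levels at which all calling criteria held; ``report_level`` is
    the qualifying level with the smallest FDR, whose group quantiles are
    stored in ``cpm_ctl``/``cpm_case``.
    """

    gene_id: str
    gene_name: str
    cpm_ctl: float
    cpm_case: float
    ratio: float
    direction: str  # "up" | "down" | "none"
    fdr: float
    qualifying_levels: tuple[float, ...] = ()
    report_level: Optional[float] = None


# ---------------------------------------------------------------------------
# count matrix I/O


def read_counts(path, format: str = "tsv") -> CountMatrix:
    """Read a raw count matrix.

    ``format='tsv'``: first column gene id, header row of sample ids.
    ``format='mtx_triplet'``: MatrixMarket coordinate file; row and column
    names come from ``<path minus suffix>.genes.txt`` / ``.samples.txt``
    (one name per line).
    """
    path = Path(path)
    if format == "tsv":
        return _read_counts_tsv(path)
    if format == "mtx_triplet":
        return _read_counts_mtx(path)
    raise ValueError(f"unknown counts format {format!r}")


def _read_counts_tsv(path: Path) -> CountMatrix:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header or "\t" not in header:
            raise ParseError(f"{path}:1: malformed header (expected tab-separated sample ids)")
        sample_ids = header.split("\t")[1:]
        if any(not s for s in sample_ids):
            raise ParseError(f"{path}:1: empty sample id in header")
        gene_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(sample_ids) + 1:
                raise ParseError(
                    f"{path}:{lineno}: expected {len(sample_ids) + 1} fields, got {len(parts)}"
                )
            gene_ids.append(parts[0])
            row = []
            for j, tok in enumerate(parts[1:]):
                try:
                    value = int(tok)
                except ValueError:
                    raise ValidationError(
                        f"{path}:{lineno}: non-integer count {tok!r} for gene "
                        f"{parts[0]!r}, sample {sample_ids[j]!r}"
                    ) from None
                if value < 0:
                    raise ValidationError(
                        f"{path}:{lineno}: negative count {value} for gene "
                        f"{parts[0]!r}, sample {sample_ids[j]!r}"
                    )
                row.append(value)
            rows.append(row)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    return CountMatrix(gene_ids, sample_ids, np.array(rows, dtype=np.int64))


def _read_counts_mtx(path: Path) -> CountMatrix:
    from scipy.io import mmread

    stem = path.with_suffix("")
    genes_path = stem.with_suffix(".genes.txt")
    samples_path = stem.with_suffix(".samples.txt")
    for side in (genes_path, samples_path):
        if not side.exists():
            raise ParseError(f"missing side file {side}")
    gene_ids = genes_path.read_text(encoding="utf-8").split()
    sample_ids = samples_path.read_text(encoding="utf-8").split()
    try:
        mat = mmread(str(path))
    except Exception as exc:  # mmread raises bare ValueError on bad indices
        raise ParseError(f"{path}: {exc}") from exc
    dense = np.asarray(mat.todense() if hasattr(mat, "todense") else mat)
    if dense.shape != (len(gene_ids), len(sample_ids)):
        raise ParseError(
            f"{path}: matrix shape {dense.shape} does not match side files "
            f"({len(gene_ids)} genes, {len(sample_ids)} samples)"
        )
    return CountMatrix(gene_ids, sample_ids, dense)


def write_counts(matrix: CountMatrix, path) -> None:
    """Write a count matrix as TSV (inverse of ``read_counts`` for 'tsv')."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for gid, row in zip(matrix.gene_ids, matrix.counts):
            fh.write(gid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# metadata I/O


def _parse_optional_float(token: str, column: str, lineno: int, path) -> Optional[float]:
    token = token.strip()
    if token in ("", "NA", "na", "NaN", "nan", "."):
        return None
    try:
        return float(token)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: bad {column} value {token!r}") from None


def read_metadata(path) -> list[SampleMetadata]:
    """Read the fixed-column sample metadata TSV."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in _METADATA_COLUMNS[:5] if c not in header]
        if missing:
            raise ParseError(f"{path}: missing required column(s) {missing}")
        idx = {c: header.index(c) for c in header}
        out: list[SampleMetadata] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < len(header):
                parts += [""] * (len(header) - len(parts))

            def col(name: str, default: str = "") -> str:
                i = idx.get(name)
                return parts[i].strip() if i is not None and i < len(parts) else default

            sid = col("sample_id")
            if sid in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate sample_id {sid!r}")
            seen.add(sid)
            sub = col("subphenotype") or "none"
            try:
                row = SampleMetadata(
                    sample_id=sid,
                    disease_status=col("disease_status"),
                    sex=col("sex"),
                    subphenotype=sub,
                    cohort=col("cohort") or "discovery",
                    fev1_fvc=_parse_optional_float(col("fev1_fvc"), "fev1_fvc", lineno, path),
                    tlco_va=_parse_optional_float(col("tlco_va"), "tlco_va", lineno, path),
                    tlc=_parse_optional_float(col("tlc"), "tlc", lineno, path),
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
            out.append(row)
    return out


def write_metadata(rows: Sequence[SampleMetadata], path) -> None:
    def fmt(v: Optional[float]) -> str:
        return "" if v is None else format(v, ".6g")

    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_METADATA_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        r.sample_id,
                        r.disease_status,
                        r.sex,
                        r.subphenotype,
                        r.cohort,
                        fmt(r.fev1_fvc),
                        fmt(r.tlco_va),
                        fmt(r.tlc),
                    ]
                )
                + "\n"
            )


def filter_eligible_controls(
    metadata: Sequence[SampleMetadata], threshold: float = 0.75
) -> list[SampleMetadata]:
    """Keep controls with FEV1/FVC strictly above ``threshold``.

    Cases pass through unchanged.  Controls with no recorded FEV1/FVC are
    excluded with a warning (the eligibility rule presumes the value).
    Idempotent.
    """
    out: list[SampleMetadata] = []
    for row in metadata:
        if row.disease_status != "control":
            out.append(row)
            continue
        if row.fev1_fvc is None:
            warnings.warn(
                f"control {row.sample_id!r} has no FEV1/FVC value; excluded",
                stacklevel=2,
            )
            continue
        if row.fev1_fvc > threshold:
            out.append(row)
    return out


def subphenotype_matches(sample_subphenotype: str, requested: str) -> bool:
    """Whether a sample's label satisfies a requested sub-phenotype.

    ``Eex`` counts as ``E`` and ``Aex`` as ``A`` when the broad label is
    requested; requesting ``Eex``/``Aex`` matches only the extreme subset.
    """
    if requested == "E":
        return sample_subphenotype in ("E", "Eex")
    if requested == "A":
        return sample_subphenotype in ("A", "Aex")
    return sample_subphenotype == requested


def select_samples(
    metadata: Sequence[SampleMetadata],
    disease_status: Optional[str] = None,
    sex: Optional[str] = None,
    subphenotype: Optional[str] = None,
    cohort: Optional[str] = None,
) -> list[str]:
    """Sample ids matching every given criterion (None = no constraint)."""
    out = []
    for row in metadata:
        if disease_status is not None and row.disease_status != disease_status:
            continue
        if sex is not None and row.sex != sex:
            continue
        if subphenotype is not None and not subphenotype_matches(
            row.subphenotype, subphenotype
        ):
            continue
        if cohort is not None and row.cohort != cohort:
            continue
        out.append(row.sample_id)
    return out


def write_cpm_table(norm: NormalizedMatrix, path) -> None:
    """Write a normalized matrix as TSV (values at 6 significant digits)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id\t" + "\t".join(norm.sample_ids) + "\n")
        for gid, row in zip(norm.gene_ids, norm.cpm):
            fh.write(gid + "\t" + "\t".join(format(v, ".6g") for v in row) + "\n")


def read_cpm_table(path) -> NormalizedMatrix:
    """Read a cpm TSV written by :func:`write_cpm_table`.

    Scaling factors are not stored in the table; the returned matrix
    carries unit factors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    return NormalizedMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        cpm=df.to_numpy(dtype=float),
        scaling_factors=np.ones(df.shape[1]),
    )


# ---------------------------------------------------------------------------
# DEG table I/O

_DEG_COLUMNS = ("gene_name", "ensembl_id", "cpm_ctl", "cpm_case", "ratio", "fdr")


def _deg_sort_key(rec: DEGRecord):
    direction_rank = {"up": 0, "none": 1, "down": 2}.get(rec.direction, 3)
    return (direction_rank, -rec.ratio if math.isfinite(rec.ratio) else -math.inf, rec.gene_id)


def write_deg_table(records: Sequence[DEGRecord], path) -> None:
    """Write DEG records as a 6-column TSV, up-regulated first.

    Group cpm values and FDR are stored at 6 significant digits; the
    ratio column is display-rounded to 2 decimals (it is recomputed from
    the cpm columns on read, so the round-trip stays lossless to 6
    significant digits).
    """
    ordered = sorted(records, key=_deg_sort_key)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_DEG_COLUMNS) + "\n")
        for r in ordered:
            ratio_str = "inf" if not math.isfinite(r.ratio) else format(r.ratio, ".2f")
            fh.write(
                "\t".join(
                    [
                        r.gene_name,
                        r.gene_id,
                        format(r.cpm_ctl, ".6g"),
                        format(r.cpm_case, ".6g"),
                        ratio_str,
                        format(r.fdr, ".6g"),
                    ]
                )
                + "\n"
            )


def read_deg_table(path) -> list[DEGRecord]:
    """Read a DEG table written by :func:`write_deg_table`.

    Ratio and direction are recomputed from the stored cpm columns;
    qualifying-level provenance is not round-tripped.
    """
    from .degs import fold_change

    df = pd.read_csv(path, sep="\t", dtype={"gene_name": str, "ensembl_id": str})
    missing = [c for c in _DEG_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    out = []
    for row in df.itertuples(index=False):
        ratio, direction = fold_change(float(row.cpm_ctl), float(row.cpm_case))
        out.append(
            DEGRecord(
                gene_id=str(row.ensembl_id),
                gene_name=str(row.gene_name),
                cpm_ctl=float(row.cpm_ctl),
                cpm_case=float(row.cpm_case),
                ratio=ratio,
                direction=direction,
                fdr=float(row.fdr),
            )
        )
    return out
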