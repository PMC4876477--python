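"""Ct matrices: data model, delimited-text I/O, validation, and summaries.

The central container is :class:`CtMatrix`, a samples × genes table of
cycle-threshold (Ct) values. Undetected reactions are stored as missing
(NaN) and are never imputed; the stability algorithms downstream require
complete-case matrices, produced by :func:`complete_case`.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CtMatrix",
    "SampleAnnotation",
    "GeneSummary",
    "CtDataError",
    "load_ct_table",
    "write_ct_table",
    "load_annotations",
    "complete_case",
    "summarize",
]

#: strings treated as "reaction did not cross threshold" on input
MISSING_SENTINELS = {"", "na", "nan", "n/a", "undetermined", "undet", "no ct", "-"}


class CtDataError(ValueError):
    """Raised for structurally invalid Ct tables or annotations."""


@dataclass(frozen=True)
class SampleAnnotation:
    """Treatment group and tissue-location labels for one sample."""

    sample_id: str
    group: str
    location: str
    extra: dict = field(default_factory=dict)


@dataclass(frozen=True)
class GeneSummary:
    """Descriptive Ct statistics for one gene (optionally one stratum).

    ``sd_ct`` uses the n−1 (sample) denominator; ``cv_pct`` is
    100·sd/mean. Both are NaN when fewer than two observations exist.
    """

    gene_id: str
    n: int
    mean_ct: float
    sd_ct: float
    cv_pct: float
    stratum: str | None = None


class CtMatrix:
    """Rectangular samples × genes table of Ct values with missing support.

    Parameters
    ----------
    values
        2-D array-like, shape (n_samples, n_genes); NaN marks an
        undetected reaction.
    sample_ids, gene_ids
        Unique ordered identifiers for the rows and columns.
    """

    def __init__(
        self,
        values: np.ndarray,
        sample_ids: Sequence[str],
        gene_ids: Sequence[str],
    ) -> None:
        values = np.asarray(values, dtype=float)
        sample_ids = [str(s) for s in sample_ids]
        gene_ids = [str(g) for g in gene_ids]
        if values.ndim != 2:
            raise CtDataError("Ct table must be two-dimensional")
        if values.shape != (len(sample_ids), len(gene_ids)):
            raise CtDataError(
                f"shape {values.shape} does not match "
                f"{len(sample_ids)} samples × {len(gene_ids)} genes"
            )
        if len(set(sample_ids)) != len(sample_ids):
            raise CtDataError("duplicate sample ids")
        if len(set(gene_ids)) != len(gene_ids):
            raise CtDataError("duplicate gene ids")
        finite = values[~np.isnan(values)]
        if np.any(~np.isfinite(finite)):
            raise CtDataError("Ct values must be finite or missing (NaN)")
        if np.any(finite <= 0):
            raise CtDataError("non-missing Ct values must be > 0")
        self.values = values
        self.sample_ids = sample_ids
        self.gene_ids = gene_ids

    # -- basic protocol -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"CtMatrix({self.n_samples} samples × {self.n_genes} genes, "
            f"{self.n_missing} missing)"
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, CtMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.gene_ids == other.gene_ids
            and np.array_equal(self.values, other.values, equal_nan=True)
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame, samples as index, genes as columns."""
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CtMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def gene(self, gene_id: str) -> np.ndarray:
        """Ct vector for one gene across samples (may contain NaN)."""
        return self.values[:, self.gene_ids.index(gene_id)]

    def subset(
        self,
        samples: Iterable[str] | None = None,
        genes: Iterable[str] | None = None,
    ) -> "CtMatrix":
        """Submatrix restricted to the given samples and/or genes, in the given order."""
        samples = list(samples) if samples is not None else self.sample_ids
        genes = list(genes) if genes is not None else self.gene_ids
        missing_s = set(samples) - set(self.sample_ids)
        missing_g = set(genes) - set(self.gene_ids)
        if missing_s:
            raise CtDataError(f"unknown sample ids: {sorted(missing_s)}")
        if missing_g:
            raise CtDataError(f"unknown gene ids: {sorted(missing_g)}")
        ridx = [self.sample_ids.index(s) for s in samples]
        cidx = [self.gene_ids.index(g) for g in genes]
        return CtMatrix(self.values[np.ix_(ridx, cidx)], samples, genes)


# ---------------------------------------------------------------------------
# I/O


def _read_delimited(source, **kwargs) -> pd.DataFrame:
    """Read CSV/TSV; the delimiter is taken from the file extension (default comma)."""
    sep = ","
    if isinstance(source, (str, Path)) and str(source).lower().endswith((".tsv", ".tab")):
        sep = "\t"
    return pd.read_csv(source, sep=sep, dtype=str, keep_default_na=False, **kwargs)


def _parse_ct_cell(raw: str) -> float:
    raw = raw.strip()
    if raw.lower() in MISSING_SENTINELS:
        return np.nan
    try:
        return float(raw)
    except ValueError:
        return np.nan


def load_ct_table(
    source: str | Path | io.TextIOBase,
    layout: str = "wide",
    annotation_source: str | Path | io.TextIOBase | None = None,
) -> tuple[CtMatrix, list[SampleAnnotation]]:
    """Load a Ct table from delimited text.

    Wide layout: one row per sample, first column the sample id, one
    column per gene. Long layout: columns ``sample,gene,ct`` with an
    optional ``replicate`` column; technical replicates of the same
    (sample, gene) are collapsed to their arithmetic mean. Non-numeric
    cells ("Undetermined", "NA", empty, …) become missing, with a
    warning per affected cell.
    """
    if layout not in ("wide", "long"):
        raise CtDataError(f"layout must be 'wide' or 'long', got {layout!r}")
    df = _read_delimited(source)
    if df.empty:
        raise CtDataError("empty Ct table")

    n_coerced = 0
    if layout == "wide":
        sample_col = df.columns[0]
        sample_ids = df[sample_col].astype(str).str.strip().tolist()
        if len(set(sample_ids)) != len(sample_ids):
            raise CtDataError("duplicate sample rows in wide table")
        gene_ids = [str(c) for c in df.columns[1:]]
        if not gene_ids:
            raise CtDataError("wide table has no gene columns")
        vals = np.empty((len(sample_ids), len(gene_ids)))
        for j, g in enumerate(df.columns[1:]):
            for i, raw in enumerate(df[g].astype(str)):
                v = _parse_ct_cell(raw)
                if np.isnan(v):
                    n_coerced += 1
                vals[i, j] = v
        ct = CtMatrix(vals, sample_ids, gene_ids)
    else:
        required = {"sample", "gene", "ct"}
        if not required <= set(df.columns):
            raise CtDataError(
                f"long layout requires columns {sorted(required)}, got {list(df.columns)}"
            )
        df = df.assign(
            sample=df["sample"].astype(str).str.strip(),
            gene=df["gene"].astype(str).str.strip(),
            _ct=[_parse_ct_cell(x) for x in df["ct"].astype(str)],
        )
        n_coerced = int(df["_ct"].isna().sum())
        # replicates collapse to the arithmetic mean of detected Ct values
        pivot = df.pivot_table(index="sample", columns="gene", values="_ct", aggfunc="mean")
        pivot = pivot.reindex(
            index=pd.unique(df["sample"]), columns=pd.unique(df["gene"])
        )
        ct = CtMatrix.from_frame(pivot)

    if n_coerced:
        warnings.warn(
            f"{n_coerced} Ct cell(s) were non-numeric or undetected and set to missing",
            stacklevel=2,
        )

    annotations: list[SampleAnnotation] = []
    if annotation_source is not None:
        annotations = load_annotations(annotation_source)
        annotated = {a.sample_id for a in annotations}
        absent = [s for s in ct.sample_ids if s not in annotated]
        if absent:
            raise CtDataError(f"annotation missing for sample(s): {absent}")
    return ct, annotations


def load_annotations(source: str | Path | io.TextIOBase) -> list[SampleAnnotation]:
    """Read a sample annotation CSV with columns ``sample,group,location``."""
    df = _read_delimited(source)
    required = {"sample", "group", "location"}
    if not required <= set(df.columns):
        raise CtDataError(
            f"annotation file requires columns {sorted(required)}, got {list(df.columns)}"
        )
    seen: set[str] = set()
    out = []
    for _, row in df.iterrows():
        sid = str(row["sample"]).strip()
        if sid in seen:
            raise CtDataError(f"duplicate annotation for sample {sid!r}")
        seen.add(sid)
        extra = {
            c: row[c]
            for c in df.columns
            if c not in ("sample", "group", "location")
        }
        out.append(
            SampleAnnotation(sid, str(row["group"]).strip(), str(row["location"]).strip(), extra)
        )
    return out


def write_ct_table(
    ct: CtMatrix,
    target: str | Path | io.TextIOBase,
    layout: str = "wide",
) -> None:
    """Write a Ct matrix back to delimited text (inverse of :func:`load_ct_table`).

    Values are written with full precision (``repr`` round-trip), missing
    entries as empty cells (wide) or omitted rows (long).
    """
    if layout == "wide":
        df = ct.to_frame()
        df.index.name = "sample"
        df.to_csv(target, float_format="%.17g")
    elif layout == "long":
        frame = ct.to_frame()
        long = frame.stack().rename("ct").reset_index()
        long.columns = ["sample", "gene", "ct"]
        long.to_csv(target, index=False, float_format="%.17g")
    else:
        raise CtDataError(f"layout must be 'wide' or 'long', got {layout!r}")


# ---------------------------------------------------------------------------
# Filtering and summaries


def complete_case(
    ct: CtMatrix, genes: Sequence[str] | None = None
) -> tuple[CtMatrix, list[str]]:
    """Restrict to `genes` and drop samples with any missing value among them.

    Returns the complete submatrix and the list of removed sample ids.
    Stability statistics are undefined below 3 samples or 2 genes, which
    is a hard error.
    """
    genes = list(genes) if genes is not None else ct.gene_ids
    sub = ct.subset(genes=genes)
    keep_mask = ~np.isnan(sub.values).any(axis=1)
    kept = [s for s, k in zip(sub.sample_ids, keep_mask) if k]
    removed = [s for s, k in zip(sub.sample_ids, keep_mask) if not k]
    if len(kept) < 3 or len(genes) < 2:
        raise CtDataError(
            f"complete-case matrix has {len(kept)} samples × {len(genes)} genes; "
            "need ≥ 3 samples and ≥ 2 genes for stability statistics"
        )
    return sub.subset(samples=kept), removed


def summarize(
    ct: CtMatrix,
    annotations: Sequence[SampleAnnotation] | None = None,
    stratify_by: str | None = None,
) -> list[GeneSummary]:
    """Per-gene n, mean Ct, sample SD (n−1) and CV% over non-missing entries.

    With ``stratify_by`` ("group" or "location"), statistics are computed
    per gene within each stratum. Strata with fewer than two observations
    report SD and CV as NaN with a warning.
    """
    if stratify_by is not None:
        if annotations is None:
            raise CtDataError("stratified summary requires annotations")
        if stratify_by not in ("group", "location"):
            raise CtDataError("stratify_by must be 'group' or 'location'")
        by_sample = {a.sample_id: getattr(a, stratify_by) for a in annotations}
        absent = [s for s in ct.sample_ids if s not in by_sample]
        if absent:
            raise CtDataError(f"no annotation for sample(s): {absent}")
        labels = [by_sample[s] for s in ct.sample_ids]
        strata = list(dict.fromkeys(labels))  # preserve first-seen order
    else:
        labels = [None] * ct.n_samples
        strata = [None]

    out: list[GeneSummary] = []
    for stratum in strata:
        rows = [i for i, lab in enumerate(labels) if lab == stratum]
        block = ct.values[rows, :]
        for j, gene in enumerate(ct.gene_ids):
            col = block[:, j]
            col = col[~np.isnan(col)]
            n = col.size
            if n == 0:
                out.append(GeneSummary(gene, 0, np.nan, np.nan, np.nan, stratum))
                continue
            mean = float(col.mean())
            if n < 2:
                warnings.warn(
                    f"gene {gene!r}"
                    + (f" stratum {stratum!r}" if stratum else "")
                    + f": n={n} < 2, SD and CV undefined",
                    stacklevel=2,
                )
                sd = cv = np.nan
            else:
                sd = float(col.std(ddof=1))
                cv = 100.0 * sd / mean
            out.append(GeneSummary(gene, n, mean, sd, cv, stratum))
    return out


def summaries_to_frame(summaries: Sequence[GeneSummary]) -> pd.DataFrame:
    """Tabular view of :func:`summarize` output (Ct descriptives per gene)."""
    return pd.DataFrame(
        [
            {
                "gene": s.gene_id,
                "stratum": s.stratum,
                "n": s.n,
                "mean_ct": s.mean_ct,
                "sd_ct": s.sd_ct,
                "cv_pct": s.cv_pct,
            }
            for s in summaries
        ]
    )
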