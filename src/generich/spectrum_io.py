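"""Count tables, frequency spectra and richness reports.

An RNA-seq sample is modelled as a with-replacement draw of ``N`` gene tags
from an effectively infinite pool of transcripts.  The per-gene tag counts
``y_i`` of the detected genes form a :class:`CountVector`; the *frequency of
frequencies* ``f_r`` — the number of genes observed exactly ``r`` times —
forms a :class:`FrequencySpectrum`, which is the sufficient statistic for
every richness estimator in :mod:`generich.estimators`.  ``f_0``, the number
of expressed genes observed zero times, is the estimand and is deliberately
*not* a field of the spectrum.

Raw integer counts are required throughout: normalised data (TPM/CPM, or any
non-integer table) destroy the sampling model and are rejected at parse time.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountTableError",
    "CountVector",
    "ExpressionMatrix",
    "FrequencySpectrum",
    "RichnessEstimate",
    "read_count_table",
    "read_spectrum_table",
    "collapse_libraries",
    "library_counts",
    "spectrum_from_counts",
    "spectrum_from_array",
    "is_complete",
    "report_frame",
    "write_report",
]

_INT_RE = re.compile(r"[+-]?\d+")


class CountTableError(ValueError):
    """A count table violated the raw-integer-count contract."""


@dataclass(frozen=True)
class CountVector:
    """Tag counts of the genes *detected* in one sample.

    Genes with zero tags are "not detected" and must not appear; every count
    is a positive integer.  ``N`` is the sequencing depth (total mapped tags)
    and ``g`` the number of detected genes.
    """

    gene_ids: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "gene_ids", tuple(str(i) for i in self.gene_ids))
        if counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if len(self.gene_ids) != counts.size:
            raise ValueError("gene_ids and counts must have equal length")
        if counts.size and int(counts.min()) < 1:
            raise ValueError("every detected gene must have a count >= 1")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")

    @property
    def N(self) -> int:
        """Total mapped tags (sequencing depth)."""
        return int(self.counts.sum())

    @property
    def g(self) -> int:
        """Number of detected genes."""
        return int(self.counts.size)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Raw integer tag counts, genes x libraries.

    Unlike :class:`CountVector`, zero rows are retained here: a gene missed
    by one library may be detected by another, and per-library versus
    total-library comparisons need the full row set.
    """

    gene_ids: tuple[str, ...]
    libraries: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "gene_ids", tuple(str(i) for i in self.gene_ids))
        object.__setattr__(self, "libraries", tuple(str(i) for i in self.libraries))
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if counts.shape != (len(self.gene_ids), len(self.libraries)):
            raise ValueError("counts shape must be (len(gene_ids), len(libraries))")
        if counts.size and int(counts.min()) < 0:
            raise ValueError("counts must be non-negative")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")


@dataclass(frozen=True)
class FrequencySpectrum:
    """Sparse map ``r -> f_r`` of the frequency of frequencies.

    Only strictly positive entries are stored; absent keys mean ``f_r = 0``.
    ``N = sum(r * f_r)`` and ``g = sum(f_r)`` are derived, so the accounting
    invariants hold by construction.  There is no bound on ``r``.
    """

    f: Mapping[int, int]

    def __post_init__(self) -> None:
        clean: dict[int, int] = {}
        for r, fr in dict(self.f).items():
            r, fr = int(r), int(fr)
            if r < 1:
                raise ValueError(f"frequency class r={r} must be >= 1")
            if fr < 0:
                raise ValueError(f"f_{r} must be >= 0")
            if fr:
                clean[r] = fr
        object.__setattr__(self, "f", clean)

    def __getitem__(self, r: int) -> int:
        return self.f.get(int(r), 0)

    @property
    def N(self) -> int:
        return sum(r * fr for r, fr in self.f.items())

    @property
    def g(self) -> int:
        return sum(self.f.values())


@dataclass(frozen=True)
class RichnessEstimate:
    """One estimator's answer for a sample: ``f0_hat`` missing genes.

    ``f0_hat`` is NaN when the estimator was undefined on the spectrum (a
    zero denominator with no standard correction); ``degenerate`` is set
    whenever a zero denominator was met, including flagged fallbacks.
    """

    estimator_name: str
    f0_hat: float
    g: int
    N: int | None = None
    se: float | None = None
    ci_lower: float | None = None
    ci_upper: float | None = None
    degenerate: bool = False

    @property
    def is_missing(self) -> bool:
        return math.isnan(self.f0_hat)

    @property
    def G_hat(self) -> float:
        """Estimated total number of expressed genes, g + f0_hat."""
        return self.g + self.f0_hat

    @property
    def pct_missing(self) -> float:
        """100 * f0_hat / (g + f0_hat), the estimated percentage undetected."""
        if self.is_missing:
            return math.nan
        if self.f0_hat == 0:
            return 0.0
        return 100.0 * self.f0_hat / (self.g + self.f0_hat)


# ---------------------------------------------------------------------------
# parsing


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_count_table(path: str | Path, delimiter: str | None = None) -> ExpressionMatrix:
    """Parse a delimited gene x library table of raw integer tag counts.

    First column: gene identifier (verbatim string, no grouping of splice
    variants or paralogs).  Header row with library names is mandatory.
    Delimiter is auto-detected from the extension (``.csv`` -> comma,
    anything else -> tab) unless given explicitly.

    Raises :class:`CountTableError` naming the offending line for malformed
    rows, duplicate gene ids, or non-integer/negative cells (normalised
    expression tables are not usable: raw counts are required).
    """
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    try:
        df = pd.read_csv(path, sep=sep, header=0, dtype=str, engine="python")
    except pd.errors.EmptyDataError:
        raise CountTableError(f"{path}: no data rows") from None
    except pd.errors.ParserError as exc:
        raise CountTableError(f"{path}: parse error: {exc}") from None
    if df.shape[0] == 0:
        raise CountTableError(f"{path}: no data rows")
    if df.shape[1] < 2:
        raise CountTableError(
            f"{path}: need a gene-id column plus at least one library column"
        )
    gene_ids = df.iloc[:, 0].astype(str)
    dup = gene_ids[gene_ids.duplicated()]
    if len(dup):
        raise CountTableError(f"{path}: duplicate gene id {dup.iloc[0]!r}")
    cells = df.iloc[:, 1:]
    for j, col in enumerate(cells.columns):
        column = cells[col].astype(str).str.strip()
        bad = ~column.map(lambda s: bool(_INT_RE.fullmatch(s)))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            value = column.iloc[row]
            lineno = row + 2  # header is line 1
            raise CountTableError(
                f"{path}: line {lineno}, library {col!r}: non-integer count "
                f"{value!r}; raw (unnormalized) integer tag counts are required"
            )
    counts = cells.apply(lambda c: c.astype(str).str.strip()).astype(np.int64).to_numpy()
    if counts.size and counts.min() < 0:
        i, j = np.argwhere(counts < 0)[0]
        raise CountTableError(
            f"{path}: line {int(i) + 2}, library {cells.columns[j]!r}: negative count"
        )
    return ExpressionMatrix(tuple(gene_ids), tuple(str(c) for c in cells.columns), counts)


def read_spectrum_table(path: str | Path, delimiter: str | None = None) -> FrequencySpectrum:
    """Parse a bare two-column spectrum file: ``r`` and ``f_r`` per line.

    A single header line is tolerated (skipped when its cells are not
    integers); lines starting with ``#`` are comments.
    """
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    f: dict[int, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in re.split(rf"[{re.escape(sep)}\s]+", line) if p.strip()]
            if len(parts) != 2:
                raise CountTableError(f"{path}: line {lineno}: expected two columns r, f_r")
            if not (_INT_RE.fullmatch(parts[0]) and _INT_RE.fullmatch(parts[1])):
                if lineno == 1:
                    continue  # header
                raise CountTableError(f"{path}: line {lineno}: non-integer spectrum entry")
            r, fr = int(parts[0]), int(parts[1])
            if r in f:
                raise CountTableError(f"{path}: line {lineno}: duplicate frequency class r={r}")
            f[r] = fr
    if not f:
        raise CountTableError(f"{path}: no data rows")
    return FrequencySpectrum(f)


# ---------------------------------------------------------------------------
# reshaping


def collapse_libraries(matrix: ExpressionMatrix) -> CountVector:
    """Total library of an accession: per-gene sums over all libraries.

    ``y_i^t = sum_j y_ij``; genes with zero total are dropped, and N and g
    are recomputed from the collapsed counts.
    """
    totals = matrix.counts.sum(axis=1)
    keep = totals > 0
    ids = tuple(gid for gid, k in zip(matrix.gene_ids, keep) if k)
    return CountVector(ids, totals[keep])


def library_counts(matrix: ExpressionMatrix, library_name: str) -> CountVector:
    """Positive entries of a single library column as a CountVector."""
    try:
        j = matrix.libraries.index(library_name)
    except ValueError:
        raise KeyError(
            f"unknown library {library_name!r}; available: {', '.join(matrix.libraries)}"
        ) from None
    col = matrix.counts[:, j]
    keep = col > 0
    if not keep.any():
        raise ValueError(f"library {library_name!r} has no detected genes")
    ids = tuple(gid for gid, k in zip(matrix.gene_ids, keep) if k)
    return CountVector(ids, col[keep])


def spectrum_from_array(counts: np.ndarray) -> FrequencySpectrum:
    """Tally an array of positive per-gene counts into a spectrum."""
    values, tallies = np.unique(np.asarray(counts, dtype=np.int64), return_counts=True)
    return FrequencySpectrum({int(r): int(fr) for r, fr in zip(values, tallies)})


def spectrum_from_counts(cv: CountVector) -> FrequencySpectrum:
    """Frequency-of-frequencies spectrum of a count vector.

    ``f_r`` is the number of genes with exactly ``r`` tags; by construction
    ``sum(r * f_r) == cv.N`` and ``sum(f_r) == cv.g``.
    """
    return spectrum_from_array(cv.counts)


def is_complete(spectrum: FrequencySpectrum) -> bool:
    """Completeness criterion: no singletons (``f_1 = 0``).

    A sample in which every detected gene carries at least two tags is taken
    as having detected every expressed gene; all estimators then return 0.
    """
    return spectrum[1] == 0


# ---------------------------------------------------------------------------
# reporting


def _fmt(value: float | None, digits: int) -> object:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    if digits <= 0:
        return int(round(value))
    return round(float(value), digits)


def report_frame(
    estimates: Iterable[tuple[str, RichnessEstimate]], digits: int = 0
) -> pd.DataFrame:
    """Format estimates as the report table without writing it anywhere."""
    rows = []
    for sample, est in estimates:
        rows.append(
            {
                "sample": sample,
                "N": "NA" if est.N is None else int(est.N),
                "g": int(est.g),
                "f0_hat": _fmt(est.f0_hat, digits),
                "se": _fmt(est.se, digits),
                "ci_lower": _fmt(est.ci_lower, digits),
                "ci_upper": _fmt(est.ci_upper, digits),
                "pct_missing": _fmt(est.pct_missing, digits),
                "estimator": est.estimator_name,
                "flags": "degenerate" if est.degenerate else "",
            }
        )
    if not rows:
        raise ValueError("no estimates to report")
    return pd.DataFrame(rows)


def write_report(
    estimates: Iterable[tuple[str, RichnessEstimate]],
    destination: str | Path,
    fmt: str | None = None,
    digits: int = 0,
) -> pd.DataFrame:
    """Write a delimited richness report, one row per (sample, estimator).

    Columns: sample, N, g, f0_hat, se, ci_lower, ci_upper, pct_missing,
    estimator, flags.  Integers are reported rounded to nearest; ``digits``
    controls decimal places of the real-valued columns (0 means round to
    integer, matching the convention of published tables).  ``fmt`` is
    ``"tsv"`` or ``"csv"``, auto-detected from the extension by default.
    Returns the formatted frame that was written.
    """
    destination = Path(destination)
    if fmt is None:
        fmt = "csv" if destination.suffix.lower() == ".csv" else "tsv"
    if fmt not in ("tsv", "csv"):
        raise ValueError("fmt must be 'tsv' or 'csv'")
    df = report_frame(estimates, digits=digits)
    df.to_csv(destination, sep="\t" if fmt == "tsv" else ",", index=False)
    return df
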