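"""Numeric-format case/control GWAS matrices: reading, conversion, QC, layout.

A study is an n-subjects x m-SNPs matrix over {0, 1, 2} (copies of the
alphabetically larger allele), with all case subjects stored before all
controls.  Two text dialects are supported: ``compact`` (one unseparated
character per genotype, one subject per line) and ``whitespace``
(whitespace-separated tokens per subject).

Quality control mirrors standard GWAS cleaning: drop SNPs that deviate
from Hardy-Weinberg equilibrium in controls and SNPs with more than 1%
missing entries; residual missing genotypes in surviving columns are
imputed to the column mode so downstream tests see complete data.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np

from .stats import chi2_sf

__all__ = [
    "MISSING",
    "GwasMatrix",
    "FlatGwas",
    "PairReport",
    "letters_to_numeric",
    "read_numeric_gwas",
    "read_raw_numeric",
    "write_numeric_gwas",
    "filter_missingness",
    "filter_hwe",
    "flatten_row_major",
    "unflatten_row_major",
    "write_pairs_tsv",
    "read_pairs_tsv",
]

#: sentinel for a missing genotype in raw (pre-QC) matrices
MISSING = -1

_MISSING_CODES = ("N", "?")


@dataclasses.dataclass
class GwasMatrix:
    """Validated n x m genotype matrix with cases-first subject ordering.

    Rows ``0 .. n_cases-1`` are cases, the remaining rows controls; both
    classes must be non-empty.
    """

    genotypes: np.ndarray
    n_cases: int
    snp_ids: list[str] | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes)
        if g.ndim != 2:
            raise ValueError(f"genotype matrix must be 2-dimensional, got shape {g.shape}")
        if g.size == 0:
            raise ValueError("genotype matrix is empty")
        if not np.issubdtype(g.dtype, np.integer):
            gi = g.astype(np.int8)
            if np.any(gi != g):
                raise ValueError("genotype matrix contains non-integer entries")
            g = gi
        if g.min() < 0 or g.max() > 2:
            bad = np.argwhere((g < 0) | (g > 2))[0]
            raise ValueError(
                f"genotype out of range at row {bad[0]}, column {bad[1]}: "
                f"{int(g[bad[0], bad[1]])} (expected 0, 1 or 2)"
            )
        self.genotypes = g.astype(np.int8, copy=False)
        n = g.shape[0]
        if not 0 < self.n_cases < n:
            raise ValueError(
                f"n_cases must satisfy 0 < n_cases < n_subjects; got {self.n_cases} of {n}"
            )
        if self.snp_ids is None:
            self.snp_ids = [f"snp_{c}" for c in range(g.shape[1])]
        elif len(self.snp_ids) != g.shape[1]:
            raise ValueError(
                f"{len(self.snp_ids)} SNP ids for {g.shape[1]} columns"
            )

    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_controls(self) -> int:
        return self.n_subjects - self.n_cases

    @property
    def cases(self) -> np.ndarray:
        return self.genotypes[: self.n_cases]

    @property
    def controls(self) -> np.ndarray:
        return self.genotypes[self.n_cases :]


@dataclasses.dataclass
class FlatGwas:
    """Row-major one-dimensional layout: data[r * n_cols + c] = genotypes[r, c]."""

    data: np.ndarray
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if d.ndim != 1 or d.size != self.n_rows * self.n_cols:
            raise ValueError(
                f"flat data of length {d.size} inconsistent with "
                f"{self.n_rows} x {self.n_cols}"
            )
        self.data = d


def flatten_row_major(gwas: GwasMatrix) -> FlatGwas:
    """Lay the genotype matrix out as one row-major 1-d array."""
    g = gwas.genotypes
    return FlatGwas(data=np.ascontiguousarray(g).ravel(), n_rows=g.shape[0], n_cols=g.shape[1])


def unflatten_row_major(flat: FlatGwas) -> np.ndarray:
    """Inverse of :func:`flatten_row_major` (returns the 2-d genotype array)."""
    return np.asarray(flat.data).reshape(flat.n_rows, flat.n_cols)


def letters_to_numeric(letter_matrix: Sequence[Sequence[str]]) -> np.ndarray:
    """Convert a two-letter genotype matrix over {A, C, G, T} to 0/1/2 counts.

    For each SNP column the numeric genotype is the number of copies of the
    alphabetically larger of the (at most two) nucleotides observed in that
    column.  A monomorphic column — only one letter seen — maps to all 0,
    treating its single allele as the smaller one.
    """
    rows = list(letter_matrix)
    if not rows:
        raise ValueError("letter matrix is empty")
    n, m = len(rows), len(rows[0])
    out = np.zeros((n, m), dtype=np.int8)
    for c in range(m):
        letters: set[str] = set()
        for r, row in enumerate(rows):
            if len(row) != m:
                raise ValueError(f"row {r} has {len(row)} columns, expected {m}")
            gt = row[c]
            if not isinstance(gt, str) or len(gt) != 2 or any(ch not in "ACGT" for ch in gt):
                raise ValueError(
                    f"malformed genotype {gt!r} at row {r}, column {c} "
                    "(expected two letters from A/C/G/T)"
                )
            letters.update(gt)
        if len(letters) > 2:
            raise ValueError(
                f"column {c} carries {len(letters)} distinct nucleotides "
                f"({''.join(sorted(letters))}); at most two alleles allowed"
            )
        if len(letters) == 1:
            continue  # monomorphic: all zero by convention
        larger = max(letters)
        for r, row in enumerate(rows):
            out[r, c] = row[c].count(larger)
    return out


def _tokenize(line: str, dialect: str, lineno: int) -> list[str]:
    if dialect == "compact":
        return list(line.strip())
    if dialect == "whitespace":
        return line.split()
    raise ValueError(f"unknown dialect {dialect!r} (expected 'compact' or 'whitespace')")


def read_raw_numeric(
    path: str | Path,
    dialect: str = "compact",
    missing_codes: Sequence[str] = _MISSING_CODES,
) -> np.ndarray:
    """Read a numeric GWAS text file, allowing missing-genotype codes.

    Returns an n x m int8 matrix with entries in {0, 1, 2} and
    :data:`MISSING` (-1) wherever a missing code appears.
    """
    rows: list[list[int]] = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            if not line.strip():
                continue
            tokens = _tokenize(line, dialect, lineno)
            if width is None:
                width = len(tokens)
            elif len(tokens) != width:
                raise ValueError(
                    f"ragged input: row {lineno} has {len(tokens)} columns, expected {width}"
                )
            row = []
            for col, tok in enumerate(tokens):
                if tok in missing_codes:
                    row.append(MISSING)
                elif tok in ("0", "1", "2"):
                    row.append(int(tok))
                else:
                    raise ValueError(
                        f"invalid genotype {tok!r} at row {lineno}, column {col}"
                    )
            rows.append(row)
    if not rows:
        raise ValueError(f"no genotype rows found in {path}")
    return np.array(rows, dtype=np.int8)


def read_numeric_gwas(
    path: str | Path,
    n_cases: int,
    dialect: str = "compact",
    snp_ids: list[str] | None = None,
) -> GwasMatrix:
    """Read a complete (no missing entries) numeric GWAS into a :class:`GwasMatrix`."""
    raw = read_raw_numeric(path, dialect=dialect, missing_codes=())
    if n_cases >= raw.shape[0]:
        raise ValueError(
            f"n_cases={n_cases} must be smaller than the number of subjects ({raw.shape[0]})"
        )
    return GwasMatrix(genotypes=raw, n_cases=n_cases, snp_ids=snp_ids)


def write_numeric_gwas(gwas: GwasMatrix, path: str | Path, dialect: str = "compact") -> None:
    """Write a :class:`GwasMatrix` in one of the numeric text dialects."""
    sep = {"compact": "", "whitespace": " "}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        for row in gwas.genotypes:
            fh.write(sep.join(str(int(v)) for v in row) + "\n")


def filter_missingness(
    raw: np.ndarray, max_missing: float = 0.01
) -> tuple[np.ndarray, list[int]]:
    """Drop SNP columns whose missing fraction strictly exceeds ``max_missing``.

    Residual missing entries in surviving columns are imputed to the column
    mode (ties to the smaller genotype).  Returns the filtered complete
    matrix and the list of removed column indices.
    """
    if not 0 <= max_missing <= 1:
        raise ValueError(f"max_missing must lie in [0, 1], got {max_missing!r}")
    raw = np.asarray(raw)
    n = raw.shape[0]
    miss = raw == MISSING
    frac = miss.mean(axis=0)
    removed = np.flatnonzero(frac > max_missing)
    kept = np.flatnonzero(frac <= max_missing)
    if kept.size == 0:
        raise ValueError("missingness filter removed every column")
    out = raw[:, kept].astype(np.int8).copy()
    for k in range(out.shape[1]):
        col = out[:, k]
        hole = col == MISSING
        if hole.any():
            counts = np.bincount(col[~hole], minlength=3)
            col[hole] = int(np.argmax(counts))  # argmax ties -> smaller genotype
    return out, removed.tolist()


def hwe_pvalues(matrix: np.ndarray) -> np.ndarray:
    """Per-column Hardy-Weinberg 1-df chi-square goodness-of-fit p-values.

    The allele frequency is estimated from the observed genotype counts of
    each column (missing entries ignored); expected counts follow the HWE
    proportions ((1-p)^2, 2p(1-p), p^2).  Monomorphic columns score p = 1.
    """
    matrix = np.asarray(matrix)
    m = matrix.shape[1]
    pvals = np.ones(m)
    for c in range(m):
        col = matrix[:, c]
        col = col[col != MISSING]
        counts = np.bincount(col, minlength=3).astype(float)
        n = counts.sum()
        if n == 0:
            continue
        phat = (counts[1] + 2 * counts[2]) / (2 * n)
        if phat in (0.0, 1.0):
            continue
        expected = n * np.array([(1 - phat) ** 2, 2 * phat * (1 - phat), phat**2])
        stat = float(((counts - expected) ** 2 / expected).sum())
        pvals[c] = chi2_sf(stat, 1)
    return pvals


def filter_hwe(
    matrix: np.ndarray, n_cases: int, p_threshold: float = 1e-6
) -> tuple[np.ndarray, list[int]]:
    """Drop SNP columns deviating from Hardy-Weinberg equilibrium in controls.

    The goodness-of-fit test is computed in controls only (rows from
    ``n_cases`` on), the usual convention so that true disease associations
    in cases do not masquerade as genotyping artefacts.  Columns with
    p < ``p_threshold`` are removed.
    """
    if not 0 <= p_threshold < 1:
        raise ValueError(f"p_threshold must lie in [0, 1), got {p_threshold!r}")
    matrix = np.asarray(matrix)
    if not 0 < n_cases < matrix.shape[0]:
        raise ValueError(f"n_cases={n_cases} out of range for {matrix.shape[0]} subjects")
    pvals = hwe_pvalues(matrix[n_cases:])
    removed = np.flatnonzero(pvals < p_threshold)
    kept = np.flatnonzero(pvals >= p_threshold)
    if kept.size == 0:
        raise ValueError("HWE filter removed every column")
    return matrix[:, kept].copy(), removed.tolist()


@dataclasses.dataclass
class PairReport:
    """One reported SNP pair with its univariate and pairwise test results."""

    snp_i: str
    snp_j: str
    index_i: int
    index_j: int
    p_uni_i: float
    p_uni_j: float
    chi8_stat: float
    chi8_p: float


_TSV_HEADER = "snp_i\tsnp_j\tindex_i\tindex_j\tp_uni_i\tp_uni_j\tchi8_stat\tchi8_p"


def write_pairs_tsv(records: Sequence[PairReport], path: str | Path) -> None:
    """Write pair reports as TSV, sorted ascending by pairwise p-value.

    Floats are written with 17 significant digits (scientific notation) so
    the file re-parses to the exact values.
    """
    ordered = sorted(records, key=lambda r: (r.chi8_p, r.index_i, r.index_j))
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER + "\n")
        for r in ordered:
            fh.write(
                f"{r.snp_i}\t{r.snp_j}\t{r.index_i}\t{r.index_j}\t"
                f"{r.p_uni_i:.16e}\t{r.p_uni_j:.16e}\t"
                f"{r.chi8_stat:.16e}\t{r.chi8_p:.16e}\n"
            )


def read_pairs_tsv(path: str | Path) -> list[PairReport]:
    """Parse a file written by :func:`write_pairs_tsv`."""
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _TSV_HEADER:
            raise ValueError(f"unexpected pair-report header: {header!r}")
        for line in fh:
            si, sj, ii, jj, pui, puj, stat, p = line.rstrip("\n").split("\t")
            records.append(
                PairReport(si, sj, int(ii), int(jj), float(pui), float(puj), float(stat), float(p))
            )
    return records
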