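"""Exhaustive pairwise SNP-interaction scan with the chi-square 8-df test.

Two biallelic genotypes x, y in {0, 1, 2} are folded into a single
9-state code x + 3*y, a bijection on {0,1,2}^2.  A 2 (case/control) x 9
contingency table of the encoded pair, initialized with pseudocounts of 1
in every cell to avoid zero expected counts, feeds a Pearson chi-square
test with (2-1)(9-1) = 8 degrees of freedom.  The scan visits every pair
of columns (i, j) with j - i > ldwidth; the LD-width constraint excludes
nearby SNPs, which tend to be in strong linkage disequilibrium.

Because the 9-state encoding also picks up single SNPs that are strongly
associated on their own, reported pairs are usually post-filtered to those
whose members are both univariately insignificant under the 2-df
single-SNP chi-square test.

The scan itself walks one reference column at a time against all eligible
partner columns, tallying all partner tables of one reference in a single
vectorized pass, so peak memory stays O(n * m) regardless of the number of
pairs tested.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np
from scipy import special

from .gwas_io import GwasMatrix
from .stats import TestResult, chi2_sf

__all__ = [
    "ContingencyTable",
    "PairResult",
    "ScanConfig",
    "encode_pair",
    "build_contingency",
    "chi8_test",
    "univariate_test",
    "univariate_pvalues",
    "scan_all_pairs",
    "scan_pairs_arrays",
    "count_eligible_pairs",
    "extract_significant",
    "filter_univariate_insignificant",
]


class PairResult(NamedTuple):
    """Test result for the SNP pair at columns (i, j), i < j."""

    i: int
    j: int
    statistic: float
    p_value: float


@dataclasses.dataclass
class ContingencyTable:
    """2 x 9 case/control-by-code count table, pseudocounted.

    Row 0 holds cases, row 1 controls; column c counts subjects whose
    encoded pair genotype equals c.  Every cell starts at ``pseudocount``.
    """

    counts: np.ndarray
    pseudocount: int = 1

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (2, 9):
            raise ValueError(f"contingency table must be 2x9, got shape {c.shape}")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if c.min() < self.pseudocount:
            raise ValueError("every cell must be at least the pseudocount")
        self.counts = c


@dataclasses.dataclass
class ScanConfig:
    """Knobs of the pairwise scan.

    ldwidth
        Minimum index separation of tested pairs (j - i > ldwidth).  100
        by default for real data; 0 for simulated data with independent
        SNPs, which tests all pairs.
    alpha
        Family-wise error rate for the Bonferroni threshold.
    pseudocount
        Value every contingency cell is initialized to.
    univariate_filter
        Whether reported pairs are restricted to those whose SNPs are
        both individually insignificant.
    """

    ldwidth: int = 100
    alpha: float = 0.05
    pseudocount: int = 1
    univariate_filter: bool = True

    def __post_init__(self) -> None:
        if self.ldwidth < 0:
            raise ValueError("ldwidth must be non-negative")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")


def encode_pair(x, y):
    """Encode genotypes (x, y) in {0,1,2}^2 to the 9-state code x + 3*y."""
    xa = np.asarray(x)
    ya = np.asarray(y)
    for name, arr in (("x", xa), ("y", ya)):
        if arr.min() < 0 or arr.max() > 2:
            raise ValueError(f"genotype {name} out of range {{0,1,2}}")
    code = xa + 3 * ya
    if np.ndim(x) == 0 and np.ndim(y) == 0:
        return int(code)
    return code


def build_contingency(
    snp_x: np.ndarray,
    snp_y: np.ndarray,
    n_cases: int,
    pseudocount: int = 1,
) -> ContingencyTable:
    """Tally the 2 x 9 pseudocounted table for one SNP pair.

    Subjects 0..n_cases-1 contribute to the case row, the rest to the
    control row.
    """
    x = np.asarray(snp_x)
    y = np.asarray(snp_y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"genotype vectors must be equal-length 1-d, got {x.shape} vs {y.shape}")
    n = x.size
    if not 0 < n_cases < n:
        raise ValueError(f"n_cases must satisfy 0 < n_cases < {n}, got {n_cases}")
    codes = encode_pair(x, y)
    counts = np.empty((2, 9), dtype=np.int64)
    counts[0] = np.bincount(codes[:n_cases], minlength=9)
    counts[1] = np.bincount(codes[n_cases:], minlength=9)
    counts += pseudocount
    return ContingencyTable(counts=counts, pseudocount=pseudocount)


def _pearson_chi2(counts: np.ndarray) -> float:
    """Pearson chi-square statistic of a 2 x k table (expected from marginals)."""
    O = np.asarray(counts, dtype=float)
    col = O.sum(axis=0)
    row = O.sum(axis=1)
    total = O.sum()
    if np.any(col == 0) or np.any(row == 0):
        raise ValueError("zero marginal in contingency table (use pseudocount >= 1)")
    E = np.outer(row, col) / total
    return float(((O - E) ** 2 / E).sum())


def chi8_test(table: ContingencyTable) -> TestResult:
    """Chi-square 8-df test of the pairwise 2 x 9 table.

    The degrees of freedom stay fixed at 8 even when some genotype codes
    are absent from the data: the pseudocounts keep every expected count
    positive, so no category is collapsed.
    """
    stat = _pearson_chi2(table.counts)
    return TestResult(statistic=stat, df=8, p_value=chi2_sf(stat, 8))


def univariate_test(snp: np.ndarray, n_cases: int, pseudocount: int = 1) -> TestResult:
    """Single-SNP 2-df chi-square test on the 2 x 3 case/control table."""
    g = np.asarray(snp)
    if g.ndim != 1:
        raise ValueError("genotype vector must be 1-d")
    n = g.size
    if not 0 < n_cases < n:
        raise ValueError(f"n_cases must satisfy 0 < n_cases < {n}, got {n_cases}")
    if g.min() < 0 or g.max() > 2:
        raise ValueError("genotype out of range {0,1,2}")
    counts = np.empty((2, 3), dtype=np.int64)
    counts[0] = np.bincount(g[:n_cases], minlength=3)
    counts[1] = np.bincount(g[n_cases:], minlength=3)
    counts += pseudocount
    stat = _pearson_chi2(counts)
    return TestResult(statistic=stat, df=2, p_value=chi2_sf(stat, 2))


def univariate_pvalues(gwas: GwasMatrix, pseudocount: int = 1) -> np.ndarray:
    """Vectorized univariate 2-df p-values for every SNP column."""
    G = gwas.genotypes
    nc = gwas.n_cases
    counts = np.empty((2, 3, G.shape[1]), dtype=np.int64)
    for g in range(3):
        counts[0, g] = (G[:nc] == g).sum(axis=0)
        counts[1, g] = (G[nc:] == g).sum(axis=0)
    counts += pseudocount
    O = counts.astype(float)  # (2, 3, m)
    col = O.sum(axis=0)  # (3, m)
    row = O.sum(axis=1)  # (2, m)
    total = O.sum(axis=(0, 1))  # (m,)
    E = row[:, None, :] * col[None, :, :] / total
    stats = ((O - E) ** 2 / E).sum(axis=(0, 1))
    return special.gammaincc(1.0, stats / 2.0)


def count_eligible_pairs(m: int, ldwidth: int) -> int:
    """Number of pairs (i, j) with 0 <= i < j < m and j - i > ldwidth."""
    k = m - ldwidth - 1
    return k * (k + 1) // 2 if k > 0 else 0


def scan_pairs_arrays(
    gwas: GwasMatrix, config: ScanConfig | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Run the full pairwise scan, returning flat result arrays.

    Returns ``(i, j, statistic, p_value)`` arrays covering exactly the
    pairs with j - i > ldwidth, ordered by i ascending then j ascending.
    This is the vectorized workhorse behind :func:`scan_all_pairs`.
    """
    config = config or ScanConfig()
    G = gwas.genotypes
    n, m = G.shape
    nc = gwas.n_cases
    w = config.ldwidth
    pc = config.pseudocount
    n_pairs = count_eligible_pairs(m, w)
    if n_pairs == 0:
        raise ValueError(f"no eligible pairs: m={m}, ldwidth={w}")

    i_out = np.empty(n_pairs, dtype=np.int32)
    j_out = np.empty(n_pairs, dtype=np.int32)
    stat_out = np.empty(n_pairs, dtype=float)

    row_case = float(nc + 9 * pc)
    row_ctrl = float(n - nc + 9 * pc)
    total = float(n + 18 * pc)

    pos = 0
    offs = 9 * np.arange(m, dtype=np.int32)
    Gi32 = G.astype(np.int32)
    for i in range(m - w - 1):
        js = np.arange(i + w + 1, m, dtype=np.int32)
        P = js.size
        # 9-state codes of the reference column against each partner
        codes = Gi32[:, i, None] + 3 * Gi32[:, js]
        flat = codes + offs[:P]
        case = np.bincount(flat[:nc].ravel(), minlength=9 * P).reshape(P, 9)
        ctrl = np.bincount(flat[nc:].ravel(), minlength=9 * P).reshape(P, 9)
        O0 = case + pc
        O1 = ctrl + pc
        colsum = (O0 + O1).astype(float)
        if np.any(colsum == 0):
            raise ValueError("zero column marginal in contingency table (use pseudocount >= 1)")
        E0 = row_case * colsum / total
        E1 = row_ctrl * colsum / total
        stats = ((O0 - E0) ** 2 / E0 + (O1 - E1) ** 2 / E1).sum(axis=1)
        i_out[pos : pos + P] = i
        j_out[pos : pos + P] = js
        stat_out[pos : pos + P] = stats
        pos += P
    p_out = special.gammaincc(4.0, stat_out / 2.0)
    return i_out, j_out, stat_out, p_out


def scan_all_pairs(gwas: GwasMatrix, config: ScanConfig | None = None) -> Iterator[PairResult]:
    """Yield the chi-square 8-df result of every eligible SNP pair.

    Pairs are emitted in deterministic order (i ascending, then j), exactly
    the set {(i, j) : j - i > ldwidth}.
    """
    i_arr, j_arr, stat_arr, p_arr = scan_pairs_arrays(gwas, config)
    for i, j, s, p in zip(i_arr, j_arr, stat_arr, p_arr):
        yield PairResult(int(i), int(j), float(s), float(p))


def extract_significant(results: Iterable[PairResult], tau: float) -> list[PairResult]:
    """Pairs with p < tau, in ascending-p order (ties by (i, j)).

    Equivalent to repeatedly popping the minimum p-value until it rises
    above the threshold, without the quadratic re-scan.
    """
    hits = [r for r in results if r.p_value < tau]
    hits.sort(key=lambda r: (r.p_value, r.i, r.j))
    return hits


def filter_univariate_insignificant(
    pairs: Sequence[PairResult],
    p_uni: Mapping[int, float] | np.ndarray,
    tau_uni: float,
) -> list[PairResult]:
    """Keep pairs whose SNPs are both individually insignificant.

    A pair (i, j) survives iff p_uni[i] >= tau_uni and p_uni[j] >= tau_uni.
    This removes the pairs the 9-state encoding reports only because one
    member has a strong marginal effect.
    """

    def lookup(idx: int) -> float:
        try:
            return float(p_uni[idx])
        except (KeyError, IndexError) as exc:
            raise ValueError(f"no univariate p-value for SNP index {idx}") from exc

    return [r for r in pairs if lookup(r.i) >= tau_uni and lookup(r.j) >= tau_uni]
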