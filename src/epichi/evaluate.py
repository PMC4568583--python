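"""Power, false-positive rate and mean ROC-AUC of the pairwise scan.

Over the replicate datasets of one simulation setting:

* power — fraction of datasets in which the true interacting pair is
  among the reported (significant, univariate-filtered) pairs;
* false-positive rate — fraction of datasets in which at least one
  reported pair is not the true interaction;
* mean AUC — per dataset, the binary detection flags across a descending
  ladder of p-value thresholds trace an ROC polyline (anchored at (0,0)
  and (1,1)); the trapezoidal area is averaged across datasets.

The univariate-insignificance filter is applied at every threshold of the
ladder, so a pair driven by one SNP's marginal effect never counts as a
detection or a false positive.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np

from .gwas_io import GwasMatrix
from .pairscan import (
    PairResult,
    ScanConfig,
    count_eligible_pairs,
    extract_significant,
    filter_univariate_insignificant,
    scan_pairs_arrays,
    univariate_pvalues,
)
from .simulate import SimulationConfig, simulate_suite
from .stats import bonferroni_threshold

__all__ = [
    "CHI8_THRESHOLD_LADDER",
    "DetectionRecord",
    "EvalSummary",
    "detect",
    "dataset_flags",
    "power_fpr",
    "mean_auc",
    "setting_auc",
    "pair_label_correlation",
    "evaluate_setting",
]

#: descending p-value threshold ladder used for the ROC construction
CHI8_THRESHOLD_LADDER: tuple[float, ...] = (
    1.0,
    5e-6,
    3e-6,
    1e-6,
    5e-7,
    1e-7,
    5e-8,
    1e-8,
    5e-9,
    1e-9,
    5e-10,
    1e-10,
    5e-11,
    1e-11,
    1e-29,
)


@dataclasses.dataclass
class DetectionRecord:
    """Detection outcome of one replicate dataset.

    ``true_flags[k]`` / ``false_flags[k]`` say whether the true pair was
    reported / any non-true pair was reported at ladder threshold k.  The
    headline booleans refer to the operating (Bonferroni) threshold.
    """

    dataset_id: int
    true_pair_detected: bool
    any_false_pair_reported: bool
    true_flags: tuple[bool, ...] = ()
    false_flags: tuple[bool, ...] = ()


@dataclasses.dataclass
class EvalSummary:
    """Per-setting summary across replicate datasets."""

    power: float
    fpr: float
    mean_auc: float
    n_datasets: int
    model: str | None = None
    maf: float | None = None
    n_subjects: int | None = None


def detect(
    results: Iterable[PairResult],
    truth_pair: tuple[int, int],
    tau_pair: float,
    tau_uni: float,
    p_uni: np.ndarray,
) -> tuple[bool, bool]:
    """Classify one dataset's scan output against the known true pair.

    Returns (true_detected, false_reported): whether the truth pair
    survives significance extraction plus the univariate filter, and
    whether any surviving pair differs from the truth.
    """
    if not 0 < tau_pair <= 1 or not 0 <= tau_uni <= 1:
        raise ValueError("thresholds must lie in (0, 1]")
    hits = extract_significant(results, tau_pair)
    hits = filter_univariate_insignificant(hits, p_uni, tau_uni)
    truth = tuple(truth_pair)
    true_detected = any((r.i, r.j) == truth for r in hits)
    false_reported = any((r.i, r.j) != truth for r in hits)
    return true_detected, false_reported


def dataset_flags(
    gwas: GwasMatrix,
    truth_pair: tuple[int, int],
    scan_config: ScanConfig,
    ladder: Sequence[float],
    tau_uni: float,
) -> tuple[tuple[bool, ...], tuple[bool, ...]]:
    """Detection flags of one dataset at every ladder threshold.

    Only two numbers decide every flag: the truth pair's p-value (infinity
    if the pair is LD-excluded or fails the univariate filter) and the
    minimum p-value among all other filter-surviving pairs.
    """
    i_arr, j_arr, _, p_arr = scan_pairs_arrays(gwas, scan_config)
    p_uni = univariate_pvalues(gwas, scan_config.pseudocount)
    if scan_config.univariate_filter:
        keep = (p_uni[i_arr] >= tau_uni) & (p_uni[j_arr] >= tau_uni)
    else:
        keep = np.ones(p_arr.size, dtype=bool)
    ti, tj = truth_pair
    is_truth = (i_arr == ti) & (j_arr == tj)
    p_truth = np.inf
    if np.any(is_truth & keep):
        p_truth = float(p_arr[is_truth & keep][0])
    others = keep & ~is_truth
    min_false = float(p_arr[others].min()) if np.any(others) else np.inf
    true_flags = tuple(bool(p_truth < tau) for tau in ladder)
    false_flags = tuple(bool(min_false < tau) for tau in ladder)
    return true_flags, false_flags


def power_fpr(records: Sequence[DetectionRecord]) -> tuple[float, float]:
    """Fraction of datasets detecting the truth, and reporting any false pair."""
    if not records:
        raise ValueError("no detection records")
    n = len(records)
    power = sum(r.true_pair_detected for r in records) / n
    fpr = sum(r.any_false_pair_reported for r in records) / n
    return power, fpr


def _check_monotone(flags: Sequence[bool], ladder: Sequence[float]) -> None:
    # ladder is descending, so flags must be non-increasing along it
    order = np.argsort(ladder)[::-1]
    arr = np.asarray(flags, dtype=bool)[order]
    if np.any(np.diff(arr.astype(int)) > 0):
        raise ValueError("detection flags are not monotone in the threshold")


def _roc_area(true_flags: Sequence[bool], false_flags: Sequence[bool], ladder: Sequence[float]) -> float:
    _check_monotone(true_flags, ladder)
    _check_monotone(false_flags, ladder)
    order = np.argsort(ladder)  # tightest threshold first
    tpr = np.asarray(true_flags, dtype=float)[order]
    fpr = np.asarray(false_flags, dtype=float)[order]
    fpr = np.concatenate([[0.0], fpr, [1.0]])
    tpr = np.concatenate([[0.0], tpr, [1.0]])
    return float(np.trapezoid(tpr, fpr))


def mean_auc(records: Sequence[DetectionRecord], ladder: Sequence[float]) -> float:
    """Average per-dataset ROC area across replicates."""
    if not records:
        raise ValueError("no detection records")
    ladder = list(ladder)
    if any(len(r.true_flags) != len(ladder) for r in records):
        raise ValueError("flag vectors do not match the threshold ladder")
    areas = [_roc_area(r.true_flags, r.false_flags, ladder) for r in records]
    return float(np.mean(areas))


def setting_auc(records: Sequence[DetectionRecord], ladder: Sequence[float]) -> float:
    """Alternative AUC: one setting-level ROC from the power/FPR curves.

    Power and false-positive rate are computed across datasets at each
    ladder threshold and the trapezoidal area of that single curve is
    returned.  Kept as a cross-check on :func:`mean_auc`, whose
    per-dataset construction is the default.
    """
    if not records:
        raise ValueError("no detection records")
    order = np.argsort(ladder)
    tf = np.asarray([r.true_flags for r in records], dtype=float)
    ff = np.asarray([r.false_flags for r in records], dtype=float)
    tpr = tf.mean(axis=0)[order]
    fpr = ff.mean(axis=0)[order]
    fpr = np.concatenate([[0.0], fpr, [1.0]])
    tpr = np.concatenate([[0.0], tpr, [1.0]])
    return float(np.trapezoid(tpr, fpr))


def pair_label_correlation(snp_x: np.ndarray, snp_y: np.ndarray, n_cases: int) -> float | None:
    """Pearson correlation between the encoded pair and the 0/1 class labels.

    Labels are 0 for cases and 1 for controls; the encoded value is
    x + 3*y per subject.  Returns None when the encoded vector has zero
    variance (the correlation is undefined).
    """
    x = np.asarray(snp_x)
    y = np.asarray(snp_y)
    n = x.size
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("genotype vectors must be equal-length 1-d")
    if not 0 < n_cases < n:
        raise ValueError(f"n_cases must satisfy 0 < n_cases < {n}")
    code = (x + 3 * y).astype(float)
    labels = np.concatenate([np.zeros(n_cases), np.ones(n - n_cases)])
    if np.all(code == code[0]):
        return None
    return float(np.corrcoef(code, labels)[0, 1])


def evaluate_setting(
    sim_config: SimulationConfig,
    scan_config: ScanConfig | None = None,
    ladder: Sequence[float] = CHI8_THRESHOLD_LADDER,
    tau_pair: float | None = None,
    tau_uni: float | None = None,
    auc_mode: str = "per_dataset",
) -> tuple[EvalSummary, list[DetectionRecord]]:
    """Run the full simulate -> scan -> detect pipeline for one setting.

    ``tau_pair`` defaults to the Bonferroni threshold alpha over the
    number of pairs actually tested; ``tau_uni`` to alpha over the number
    of SNPs.  ``auc_mode`` selects the per-dataset ROC average (default)
    or the single setting-level ROC ("per_setting").
    """
    scan_config = scan_config or ScanConfig(ldwidth=0)
    m = sim_config.m_snps
    if tau_pair is None:
        tau_pair = bonferroni_threshold(
            scan_config.alpha, count_eligible_pairs(m, scan_config.ldwidth)
        )
    if tau_uni is None:
        tau_uni = bonferroni_threshold(scan_config.alpha, m)
    ladder = list(ladder)
    records: list[DetectionRecord] = []
    truth = tuple(sim_config.interacting_indices)
    for d, gwas in simulate_suite(sim_config):
        tf, ff = dataset_flags(gwas, truth, scan_config, list(ladder) + [tau_pair], tau_uni)
        records.append(
            DetectionRecord(
                dataset_id=d,
                true_pair_detected=tf[-1],
                any_false_pair_reported=ff[-1],
                true_flags=tf[:-1],
                false_flags=ff[:-1],
            )
        )
    power, fpr = power_fpr(records)
    if auc_mode == "per_dataset":
        auc = mean_auc(records, ladder)
    elif auc_mode == "per_setting":
        auc = setting_auc(records, ladder)
    else:
        raise ValueError(f"unknown auc_mode {auc_mode!r}")
    summary = EvalSummary(
        power=power,
        fpr=fpr,
        mean_auc=auc,
        n_datasets=len(records),
        model=sim_config.model.name,
        maf=sim_config.model.maf,
        n_subjects=sim_config.n_cases + sim_config.n_controls,
    )
    return summary, records
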