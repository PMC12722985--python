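"""Associating fencing participation with patient outcomes.

Given per-patient FPM values this module provides the outcome analyses:
two-group t-tests, Pearson correlation against binary response codes, a
density/FPM combined score c(r), Ripley's K cross function (uncorrected, as
a comparison metric), its weighted auto/cross combination f_R(ω), and the
cohort-mean FPM split with a log-rank survival comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy import stats
from scipy.spatial import cKDTree

from .data import PatientOutcome, Slide
from .null_model import FpmRecord, bh_significant

__all__ = [
    "DensityRecord",
    "RipleyKValue",
    "GroupComparison",
    "SurvivalSplit",
    "phenotype_density",
    "combined_density_fpm",
    "response_correlation",
    "ripley_k_cross",
    "combined_ripley",
    "compare_groups_ttest",
    "ttest_across_phenotypes",
    "survival_mean_split_logrank",
    "patient_fpm",
]


@dataclass(frozen=True)
class DensityRecord:
    slide_id: str
    phenotype: str
    sigma: float  # cells per mm²
    sigma_max: float  # cohort maximum density


@dataclass(frozen=True)
class RipleyKValue:
    phenotype_a: str
    phenotype_b: str
    r_c: float
    lambda_b: float  # cells per μm²
    k_value: float


@dataclass(frozen=True)
class GroupComparison:
    phenotype: str
    group_labels: tuple[str, str]
    group_means: tuple[float, float]
    group_sizes: tuple[int, int]
    t_statistic: float
    p_value: float


@dataclass(frozen=True)
class SurvivalSplit:
    phenotype: str
    threshold: float  # cohort-mean FPM
    n_high: int
    n_low: int
    statistic: float
    p_value: float


def phenotype_density(slide: Slide, phenotype: str) -> float:
    """Cells of ``phenotype`` per mm² of slide area."""
    if slide.area_mm2 <= 0:
        raise ValueError("slide has zero area")
    return slide.n_phenotype(phenotype) / slide.area_mm2


def combined_density_fpm(
    sigma: float,
    sigma_max: float,
    fpm: float,
    r: float,
    sign: int = -1,
) -> float:
    """Density/FPM combination c(r) = (1-r)·σ/σ_max + sign·r·M.

    The default ``sign=-1`` follows the printed formula; ``sign=+1`` gives
    the variant in which c(1) correlates with response the same way the FPM
    does.  Both are available because the two published descriptions of the
    score disagree on the sign; neither is asserted as canonical here.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError("r must lie in [0, 1]")
    if sign not in (-1, 1):
        raise ValueError("sign must be -1 or +1")
    if sigma_max <= 0:
        raise ValueError("sigma_max must be positive")
    return (1.0 - r) * sigma / sigma_max + sign * r * fpm


def response_correlation(values: Sequence[float], groups: Sequence[int]) -> float:
    """Pearson correlation of a per-patient score with binary response codes
    (responders coded 1, non-responders 0)."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups, dtype=float)
    if len(v) != len(g) or len(v) < 3:
        raise ValueError("need >= 3 paired observations")
    if len(np.unique(g)) < 2:
        raise ValueError("both outcome groups must be present")
    if np.std(v) == 0:
        raise ValueError("constant score: correlation undefined")
    return float(stats.pearsonr(v, g).statistic)


def ripley_k_cross(
    slide: Slide,
    phenotype_a: str,
    phenotype_b: str,
    r_c: float = 30.0,
) -> RipleyKValue:
    """Uncorrected Ripley's K cross value at radius r_c.

    K = λ_b⁻¹ · (# ordered pairs (a_i, b_j) with d <= r_c) / N_a, with
    λ_b = N_b / slide area (μm²).  No edge correction is applied: the value
    is the plain intensity-normalized neighbor count, which is how it is
    used here (as a per-slide covariate, not an unbiased K estimate).  For
    the auto case (a == b) self-pairs are excluded.
    """
    pos = slide.positions()
    ph = slide.phenotypes()
    a_pos = pos[ph == phenotype_a]
    b_pos = pos[ph == phenotype_b]
    n_a, n_b = len(a_pos), len(b_pos)
    if n_a == 0 or n_b == 0:
        raise ValueError("both phenotypes must be present on the slide")
    area_um2 = slide.extent[0] * slide.extent[1]
    lambda_b = n_b / area_um2
    tree = cKDTree(b_pos)
    counts = tree.query_ball_point(a_pos, r_c, return_length=True)
    n_pairs = int(np.sum(counts))
    if phenotype_a == phenotype_b:
        n_pairs -= n_a  # drop the d=0 self-pairs
    k = n_pairs / (lambda_b * n_a)
    return RipleyKValue(phenotype_a, phenotype_b, r_c, lambda_b, k)


def combined_ripley(
    k_auto: float,
    k_cross: float,
    k_auto_max: float,
    k_cross_max: float,
    omega: float,
) -> float:
    """Weighted combination f_R(ω) = ω·K_auto/K_auto,max + (1-ω)·K_cross/K_cross,max.

    Maxima are taken over the cohort (leave-self-in), so f_R ∈ [0, 1]
    whenever the inputs do not exceed their cohort maxima.
    """
    if not 0.0 <= omega <= 1.0:
        raise ValueError("omega must lie in [0, 1]")
    if k_auto_max <= 0 or k_cross_max <= 0:
        raise ValueError("cohort maxima must be positive")
    return omega * k_auto / k_auto_max + (1.0 - omega) * k_cross / k_cross_max


def patient_fpm(records: Sequence[FpmRecord]) -> dict[str, float]:
    """Mean FPM per patient (patients with several eligible slides are
    averaged before any association analysis)."""
    acc: dict[str, list[float]] = {}
    for r in records:
        acc.setdefault(r.patient_id, []).append(r.fpm)
    return {pid: float(np.mean(v)) for pid, v in acc.items()}


def compare_groups_ttest(
    fpm_by_patient: Mapping[str, float],
    outcomes: Mapping[str, PatientOutcome],
    phenotype: str = "",
) -> GroupComparison:
    """Two-sample t-test of per-patient FPM between the two outcome groups."""
    groups: dict[str, list[float]] = {}
    for pid, fpm in fpm_by_patient.items():
        groups.setdefault(outcomes[pid].group, []).append(fpm)
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 outcome groups, got {sorted(groups)}")
    (la, va), (lb, vb) = sorted(groups.items())
    if len(va) < 2 or len(vb) < 2:
        raise ValueError("each group needs >= 2 patients")
    if np.std(va) == 0 and np.std(vb) == 0:
        raise ValueError("zero variance in both groups: t-test undefined")
    res = stats.ttest_ind(va, vb)
    return GroupComparison(
        phenotype=phenotype,
        group_labels=(la, lb),
        group_means=(float(np.mean(va)), float(np.mean(vb))),
        group_sizes=(len(va), len(vb)),
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


def ttest_across_phenotypes(
    fpm_by_phenotype: Mapping[str, Mapping[str, float]],
    outcomes: Mapping[str, PatientOutcome],
    q: float = 0.05,
) -> pd.DataFrame:
    """t-tests for several phenotypes with BH adjustment across the scan."""
    rows = []
    for pheno, fpms in fpm_by_phenotype.items():
        cmp_ = compare_groups_ttest(fpms, outcomes, pheno)
        rows.append(
            {
                "phenotype": pheno,
                "group_a": cmp_.group_labels[0],
                "group_b": cmp_.group_labels[1],
                "mean_a": cmp_.group_means[0],
                "mean_b": cmp_.group_means[1],
                "n_a": cmp_.group_sizes[0],
                "n_b": cmp_.group_sizes[1],
                "t": cmp_.t_statistic,
                "p_raw": cmp_.p_value,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        from statsmodels.stats.multitest import multipletests

        _, p_bh, *_ = multipletests(df["p_raw"], alpha=q, method="fdr_bh")
        df["p_bh"] = p_bh
        df["significant_bh"] = bh_significant(df["p_raw"], q=q)
    return df


def survival_mean_split_logrank(
    fpm_by_patient: Mapping[str, float],
    outcomes: Mapping[str, PatientOutcome],
    phenotype: str = "",
) -> SurvivalSplit:
    """Split patients at the cohort-mean FPM (high: FPM >= mean) and compare
    survival between the two groups with the standard log-rank test."""
    pids = [p for p in fpm_by_patient if outcomes[p].survival_time is not None]
    if not pids:
        raise ValueError("no patients with survival data")
    fpm = np.array([fpm_by_patient[p] for p in pids])
    thresh = float(np.mean(fpm))
    high = fpm >= thresh
    n_high, n_low = int(high.sum()), int((~high).sum())
    if n_high < 2 or n_low < 2:
        raise ValueError("degenerate mean split: need >= 2 patients per side")
    times = np.array([outcomes[p].survival_time for p in pids], dtype=float)
    events = np.array([outcomes[p].event for p in pids], dtype=bool)
    res = logrank_test(times[high], times[~high], events[high], events[~high])
    return SurvivalSplit(
        phenotype=phenotype,
        threshold=thresh,
        n_high=n_high,
        n_low=n_low,
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
    )
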