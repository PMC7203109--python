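"""Per-peptide depletion statistics for the +/-4SU contrast.

The quantitative core of RBR-ID: run-sum normalization, condition means with
a zero-imputation floor, log2 depletion ratios, an unpaired two-sided
Student's t test per peptide, and the RBR-ID score

    score = -log2(mean_plus / mean_minus) * (log10 P)**2

which is positive for peptides depleted by crosslinking (mean_plus <
mean_minus) and grows with statistical confidence. Peptides with P < alpha
(default 0.1) and a negative log2 ratio are flagged significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .table_io import Condition, ExperimentDesign, PeptideRecord

logger = logging.getLogger(__name__)

#: Lower clamp on P before the (log10 P)^2 term; bounds a single peptide's
#: score at (log2 ratio) * 225.
P_FLOOR = 1e-15


@dataclass
class PeptideStat:
    """Depletion statistics for one peptide."""

    peptide_seq: str
    protein_ids: list[str]
    mean_plus: float
    mean_minus: float
    imputed_plus: bool
    imputed_minus: bool
    log2_ratio: float
    p_value: float
    score: float
    significant: bool = False


def normalize_run_intensities(
    records: Sequence[PeptideRecord], design: ExperimentDesign
) -> list[PeptideRecord]:
    """Divide each intensity by the summed intensity of its MS run.

    Equalizes loading/acquisition differences between runs: after
    normalization every run's intensities sum to 1. Returns new records;
    inputs are not mutated.
    """
    totals = {run: 0.0 for run in design.run_ids}
    for rec in records:
        for run in design.run_ids:
            totals[run] += rec.intensities.get(run, 0.0)
    zero_runs = [run for run, tot in totals.items() if tot <= 0]
    if zero_runs:
        raise ValueError(f"cannot normalize run(s) with zero total intensity: {zero_runs}")
    return [
        PeptideRecord(
            peptide_seq=rec.peptide_seq,
            protein_ids=list(rec.protein_ids),
            intensities={
                run: rec.intensities.get(run, 0.0) / totals[run]
                for run in design.run_ids
            },
            is_contaminant=rec.is_contaminant,
        )
        for rec in records
    ]


def _intensity_matrix(
    records: Sequence[PeptideRecord], design: ExperimentDesign, condition: Condition
) -> np.ndarray:
    runs = design.runs_for(condition)
    return np.array(
        [[rec.intensities.get(run, 0.0) for run in runs] for rec in records],
        dtype=float,
    )


def global_imputation_floor(
    records: Sequence[PeptideRecord],
    design: ExperimentDesign,
    factor: float = 0.5,
) -> float:
    """``factor`` x the smallest strictly positive condition mean.

    The minimum is taken over all peptides and both conditions; it replaces
    the mean of any condition observed as all zeros.
    """
    mins = []
    for cond in Condition:
        means = _intensity_matrix(records, design, cond).mean(axis=1)
        pos = means[means > 0]
        if pos.size:
            mins.append(pos.min())
    if not mins:
        raise ValueError("every condition mean is zero; imputation floor undefined")
    return factor * min(mins)


def condition_means(
    record: PeptideRecord,
    design: ExperimentDesign,
    imputation_floor: float,
) -> tuple[float, float, bool, bool]:
    """Arithmetic condition means including zeros, with all-zero imputation.

    A zero within a condition counts as a measured value; only when *every*
    replicate of a condition is zero is the mean replaced by the
    dataset-wide ``imputation_floor`` and the corresponding flag set.
    """
    out = []
    for cond in Condition:
        values = np.array(
            [record.intensities.get(run, 0.0) for run in design.runs_for(cond)]
        )
        if np.all(values == 0):
            out.append((imputation_floor, True))
        else:
            out.append((float(values.mean()), False))
    (mean_plus, imp_plus), (mean_minus, imp_minus) = out
    return mean_plus, mean_minus, imp_plus, imp_minus


def depletion_ratio(mean_plus: float, mean_minus: float) -> float:
    """log2(mean_plus / mean_minus); negative means depletion by crosslinking."""
    if mean_plus <= 0 or mean_minus <= 0:
        raise ValueError("condition means must be positive (post-imputation)")
    return float(np.log2(mean_plus / mean_minus))


def peptide_pvalue(
    values_plus: Sequence[float], values_minus: Sequence[float]
) -> float:
    """Two-sided unpaired Student's t test (pooled variance).

    Degenerate zero-pooled-variance groups give P = 1 when the means are
    equal and P = ``P_FLOOR`` otherwise.
    """
    a = np.asarray(values_plus, dtype=float)
    b = np.asarray(values_minus, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group for the t test")
    return float(_vectorized_pvalues(a[None, :], b[None, :])[0])


def _vectorized_pvalues(plus: np.ndarray, minus: np.ndarray) -> np.ndarray:
    """Row-wise pooled-variance t test; degenerate rows handled explicitly."""
    with np.errstate(invalid="ignore", divide="ignore"):
        res = sps.ttest_ind(plus, minus, axis=1, equal_var=True)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        equal_means = np.isclose(plus.mean(axis=1), minus.mean(axis=1))
        p[degenerate & equal_means] = 1.0
        p[degenerate & ~equal_means] = P_FLOOR
    return np.clip(p, P_FLOOR, 1.0)


def rbr_score(log2_ratio: float, p_value: float) -> float:
    """RBR-ID score: -log2_ratio * (log10 P)^2, with P clamped to [1e-15, 1]."""
    if not (0 < p_value):
        raise ValueError(f"p_value must be in (0, 1], got {p_value}")
    p = min(max(p_value, P_FLOOR), 1.0)
    return float(-log2_ratio * np.log10(p) ** 2)


def compute_peptide_stats(
    records: Sequence[PeptideRecord],
    design: ExperimentDesign,
    alpha: float = 0.1,
    imputation_floor_factor: float = 0.5,
    test_scale: str = "linear",
) -> list[PeptideStat]:
    """Full per-peptide statistics on already-normalized records.

    Parameters
    ----------
    records
        Normalized peptide records (see :func:`normalize_run_intensities`).
    alpha
        Significance threshold; a peptide is significant when P < alpha and
        its log2 ratio is negative (depleted).
    imputation_floor_factor
        Multiplier of the global minimum positive condition mean used for
        all-zero conditions.
    test_scale
        ``"linear"`` tests the normalized intensities themselves; ``"log"``
        tests log2 intensities (zeros offset by half the smallest positive
        value in the pair of groups).

    Peptides undetected in every run of both conditions are dropped with a
    warning: both means would be imputed to the same floor, giving ratio 1
    and score 0.
    """
    if test_scale not in ("linear", "log"):
        raise ValueError(f"test_scale must be 'linear' or 'log', got {test_scale!r}")

    plus_all = _intensity_matrix(records, design, Condition.CROSSLINKED)
    minus_all = _intensity_matrix(records, design, Condition.CONTROL)
    detected = (plus_all.sum(axis=1) > 0) | (minus_all.sum(axis=1) > 0)
    n_dropped = int((~detected).sum())
    if n_dropped:
        logger.warning(
            "dropping %d peptide(s) with zero intensity in every run", n_dropped
        )
    kept = [rec for rec, keep in zip(records, detected) if keep]
    plus, minus = plus_all[detected], minus_all[detected]
    if not kept:
        raise ValueError("no peptide detected in any run")

    floor = global_imputation_floor(kept, design, imputation_floor_factor)

    mean_plus = plus.mean(axis=1)
    mean_minus = minus.mean(axis=1)
    imputed_plus = mean_plus == 0
    imputed_minus = mean_minus == 0
    mean_plus = np.where(imputed_plus, floor, mean_plus)
    mean_minus = np.where(imputed_minus, floor, mean_minus)
    log2_ratio = np.log2(mean_plus / mean_minus)

    if test_scale == "log":
        offset = 0.5 * min(
            x[x > 0].min() for x in (plus, minus) if (x > 0).any()
        )
        p_values = _vectorized_pvalues(
            np.log2(plus + offset), np.log2(minus + offset)
        )
    else:
        p_values = _vectorized_pvalues(plus, minus)

    scores = -log2_ratio * np.log10(p_values) ** 2
    significant = (p_values < alpha) & (log2_ratio < 0)

    return [
        PeptideStat(
            peptide_seq=rec.peptide_seq,
            protein_ids=list(rec.protein_ids),
            mean_plus=float(mean_plus[i]),
            mean_minus=float(mean_minus[i]),
            imputed_plus=bool(imputed_plus[i]),
            imputed_minus=bool(imputed_minus[i]),
            log2_ratio=float(log2_ratio[i]),
            p_value=float(p_values[i]),
            score=float(scores[i]),
            significant=bool(significant[i]),
        )
        for i, rec in enumerate(kept)
    ]


def significant_peptides(
    stats: Sequence[PeptideStat], alpha: float = 0.1
) -> list[PeptideStat]:
    """Peptides with P < alpha (strict) that are depleted (log2 ratio < 0).

    Also (re)sets the ``significant`` flag on every stat in place.
    """
    out = []
    for s in stats:
        s.significant = s.p_value < alpha and s.log2_ratio < 0
        if s.significant:
            out.append(s)
    return out


def stats_to_frame(stats: Sequence[PeptideStat]) -> pd.DataFrame:
    """Tabular view of per-peptide statistics (for the output TSV)."""
    return pd.DataFrame(
        {
            "peptide": [s.peptide_seq for s in stats],
            "protein": [";".join(s.protein_ids) for s in stats],
            "mean_plus": [s.mean_plus for s in stats],
            "mean_minus": [s.mean_minus for s in stats],
            "imputed_plus": [s.imputed_plus for s in stats],
            "imputed_minus": [s.imputed_minus for s in stats],
            "log2_ratio": [s.log2_ratio for s in stats],
            "p_value": [s.p_value for s in stats],
            "score": [s.score for s in stats],
            "significant": [s.significant for s in stats],
        }
    )
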