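"""Projection of peptide scores onto protein residues and RBR segment calling.

Peptides are located in the protein by exact substring search (all
occurrences, overlapping included; I and L are distinct). Per-residue
RBR-ID scores are the sum of the scores of every peptide overlapping that
residue; the raw track is smoothed with the supersmoother and candidate
RNA-binding segments are called as long runs of residues above a quantile
threshold.

All coordinates are 1-based and inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .smoothing import SmootherConfig, supersmooth
from .table_io import ProteinSequence

logger = logging.getLogger(__name__)

MULTIMAP_POLICIES = ("all", "drop", "split")


@dataclass
class LocatedPeptide:
    """A peptide placed on a protein; multimapped if it occurs more than once."""

    peptide_seq: str
    intervals: list[tuple[int, int]]

    @property
    def multimapped(self) -> bool:
        return len(self.intervals) > 1


@dataclass
class ResidueProfile:
    """Per-residue score tracks along one protein (1-based positions)."""

    accession: str
    raw_score: np.ndarray
    smoothed_score: np.ndarray
    coverage: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.raw_score)
        if len(self.smoothed_score) != n or len(self.coverage) != n:
            raise ValueError("profile tracks must have equal length")

    def __len__(self) -> int:
        return len(self.raw_score)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "accession": self.accession,
                "position": np.arange(1, len(self) + 1),
                "raw_score": self.raw_score,
                "smoothed_score": self.smoothed_score,
                "coverage": self.coverage,
            }
        )


@dataclass(frozen=True)
class RBRSegment:
    """A called candidate RNA-binding interval (1-based, inclusive)."""

    start: int
    end: int
    peak_score: float
    mean_score: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start must be <= end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2


def locate_peptide(peptide_seq: str, protein: ProteinSequence) -> LocatedPeptide:
    """Exact substring search for all (possibly overlapping) occurrences."""
    pep = peptide_seq.upper()
    seq = protein.residues
    if len(pep) > len(seq):
        logger.warning(
            "peptide %s (len %d) longer than protein %s (len %d)",
            pep, len(pep), protein.accession, len(seq),
        )
        return LocatedPeptide(pep, [])
    intervals = []
    pos = seq.find(pep)
    while pos != -1:
        intervals.append((pos + 1, pos + len(pep)))
        pos = seq.find(pep, pos + 1)  # overlapping occurrences allowed
    return LocatedPeptide(pep, intervals)


def residue_score_profile(
    located: Sequence[tuple[LocatedPeptide, float]],
    protein_length: int,
    multimap_policy: str = "all",
    accession: str = "",
    smoother: SmootherConfig | None = None,
) -> ResidueProfile:
    """Sum peptide scores over every residue each peptide covers.

    ``multimap_policy`` controls peptides with more than one match:
    ``"all"`` adds the full score at every match, ``"drop"`` excludes them,
    ``"split"`` divides the score evenly across matches. Coverage counts
    overlapping peptides with the same policy (score 1 per peptide).

    The smoothed track is the supersmoothed raw track over residue index.
    """
    if protein_length < 1:
        raise ValueError("protein_length must be positive")
    if multimap_policy not in MULTIMAP_POLICIES:
        raise ValueError(
            f"multimap_policy must be one of {MULTIMAP_POLICIES}, got {multimap_policy!r}"
        )
    raw = np.zeros(protein_length)
    cov = np.zeros(protein_length)
    for pep, score in located:
        if not pep.intervals:
            continue
        if pep.multimapped and multimap_policy == "drop":
            continue
        weight = 1.0 / len(pep.intervals) if multimap_policy == "split" else 1.0
        for start, end in pep.intervals:
            if start < 1 or end > protein_length:
                raise ValueError(
                    f"peptide {pep.peptide_seq}: interval ({start}, {end}) outside "
                    f"[1, {protein_length}]"
                )
            raw[start - 1 : end] += weight * score
            cov[start - 1 : end] += weight

    x = np.arange(1, protein_length + 1, dtype=float)
    smoothed = supersmooth(x, raw, smoother or SmootherConfig())
    return ResidueProfile(
        accession=accession,
        raw_score=raw,
        smoothed_score=smoothed,
        coverage=cov,
    )


def call_rbr_segments(
    profile: ResidueProfile,
    threshold_quantile: float = 0.85,
    min_length: int = 10,
    merge_gap: int = 5,
) -> list[RBRSegment]:
    """Call candidate RBR segments from the smoothed score track.

    The threshold is the given quantile of smoothed scores over covered
    residues. Maximal runs of residues above the threshold are found, runs
    separated by at most ``merge_gap`` residues are merged, and runs shorter
    than ``min_length`` are discarded. Segments are returned sorted by peak
    smoothed score, descending.

    The default quantile of 0.85 allows a called segment to span up to
    ~15% of the covered protein, the scale of a large RNA-binding region
    (ATRX's spans about 14% of its sequence); raise it for sharper calls.
    """
    covered = profile.coverage > 0
    if not covered.any():
        logger.warning("profile has no covered residues; no segments called")
        return []
    threshold = float(np.quantile(profile.smoothed_score[covered], threshold_quantile))
    above = profile.smoothed_score > threshold

    runs: list[list[int]] = []  # [start, end] 1-based, mutable for merging
    in_run = False
    for i, flag in enumerate(above, start=1):
        if flag and not in_run:
            runs.append([i, i])
            in_run = True
        elif flag:
            runs[-1][1] = i
        else:
            in_run = False

    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 <= merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)

    segments = []
    for start, end in merged:
        if end - start + 1 < min_length:
            continue
        window = profile.smoothed_score[start - 1 : end]
        segments.append(
            RBRSegment(
                start=start,
                end=end,
                peak_score=float(window.max()),
                mean_score=float(window.mean()),
            )
        )
    segments.sort(key=lambda s: s.peak_score, reverse=True)
    return segments


def segments_to_frame(segments: Sequence[RBRSegment], accession: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "accession": accession,
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "peak_score": [s.peak_score for s in segments],
            "mean_score": [s.mean_score for s in segments],
        }
    )
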