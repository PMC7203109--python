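"""Reading and validation of peptide tables, experiment designs and protein FASTA.

Two table dialects are supported: a generic TSV (``peptide``, ``protein``,
then one intensity column per MS run) and the ``peptides.txt`` layout produced
by MaxQuant (``Sequence``, ``Proteins``, ``Intensity <run>`` columns).
Intensities are label-free MS intensities in arbitrary units; an empty cell or
0 means the peptide was not detected in that run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino acids. Ambiguity codes (B/Z/X) and rare letters
#: (U/O) are rejected: they cannot be matched against a canonical protein
#: string unambiguously.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Identifier substrings tagging MaxQuant contaminant / reversed-decoy entries.
DEFAULT_CONTAMINANT_PATTERNS = ("CON__", "REV__")


class Condition(str, Enum):
    """Experimental condition of an MS run in the +/-4SU contrast."""

    CROSSLINKED = "+4SU"
    CONTROL = "-4SU"


class FormatError(ValueError):
    """A file does not conform to the expected layout."""


class ValidationError(ValueError):
    """A file parses but violates a content invariant."""


@dataclass
class PeptideRecord:
    """One peptide row: sequence, parent protein ids and per-run intensities."""

    peptide_seq: str
    protein_ids: list[str]
    intensities: dict[str, float]
    is_contaminant: bool = False

    def __post_init__(self) -> None:
        if not self.peptide_seq:
            raise ValidationError("empty peptide sequence")
        bad = set(self.peptide_seq) - AMINO_ACIDS
        if bad:
            raise ValidationError(
                f"peptide {self.peptide_seq!r} contains non-standard residues: "
                f"{sorted(bad)}"
            )
        for run, value in self.intensities.items():
            if value < 0:
                raise ValidationError(
                    f"negative intensity {value} for run {run!r} in peptide "
                    f"{self.peptide_seq}"
                )


@dataclass(frozen=True)
class RunInfo:
    run_id: str
    condition: Condition
    replicate: int
    batch: str


@dataclass
class ExperimentDesign:
    """Maps each MS run to (condition, replicate, batch); defines the contrast."""

    runs: list[RunInfo]

    def __post_init__(self) -> None:
        ids = [r.run_id for r in self.runs]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate run_id in design")
        for cond in Condition:
            if len(self.runs_for(cond)) < 2:
                raise ValidationError(
                    f"need >= 2 runs per condition for the t test; "
                    f"condition {cond.value} has {len(self.runs_for(cond))}"
                )

    def runs_for(self, condition: Condition) -> list[str]:
        return [r.run_id for r in self.runs if r.condition == condition]

    @property
    def run_ids(self) -> list[str]:
        return [r.run_id for r in self.runs]


@dataclass(frozen=True)
class ProteinSequence:
    """A protein in 1-based, inclusive residue coordinates."""

    accession: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError(f"protein {self.accession}: empty sequence")
        for pos, aa in enumerate(self.residues, start=1):
            if aa not in AMINO_ACIDS:
                raise ValidationError(
                    f"protein {self.accession}: invalid residue {aa!r} "
                    f"at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


# ---------------------------------------------------------------------------
# peptide tables

_CONDITION_ALIASES = {
    "+4su": Condition.CROSSLINKED,
    "crosslinked": Condition.CROSSLINKED,
    "xl": Condition.CROSSLINKED,
    "-4su": Condition.CONTROL,
    "−4su": Condition.CONTROL,  # unicode minus
    "control": Condition.CONTROL,
    "ctrl": Condition.CONTROL,
}


def _parse_intensity(value, column: str, row: int) -> float:
    if pd.isna(value) or (isinstance(value, str) and not value.strip()):
        return 0.0  # MaxQuant convention: empty = not detected
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise FormatError(
            f"row {row}: cannot parse intensity {value!r} in column {column!r}"
        ) from None
    if out < 0:
        raise ValidationError(f"row {row}: negative intensity in column {column!r}")
    return out


def read_peptide_table(path: str | Path, dialect: str = "generic-tsv") -> list[PeptideRecord]:
    """Read a tab-delimited peptide quantification table.

    Parameters
    ----------
    path
        Table file.
    dialect
        ``"generic-tsv"`` (columns ``peptide``, ``protein``, one per run) or
        ``"maxquant-peptides"`` (``Sequence``, ``Proteins``, ``Intensity <run>``).

    Returns
    -------
    One :class:`PeptideRecord` per row, in file order. Empty intensity cells
    become 0. Duplicate peptide sequences raise :class:`ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise FormatError(f"{path}: table has no data rows")

    if dialect == "generic-tsv":
        seq_col, prot_col = "peptide", "protein"
        for col in (seq_col, prot_col):
            if col not in df.columns:
                raise FormatError(f"{path}: missing mandatory column {col!r}")
        run_cols = {c: c for c in df.columns if c not in (seq_col, prot_col)}
    elif dialect == "maxquant-peptides":
        seq_col, prot_col = "Sequence", "Proteins"
        for col in (seq_col, prot_col):
            if col not in df.columns:
                raise FormatError(f"{path}: missing mandatory column {col!r}")
        run_cols = {
            c: c[len("Intensity "):]
            for c in df.columns
            if c.startswith("Intensity ") and c != "Intensity"
        }
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if not run_cols:
        raise FormatError(f"{path}: no intensity columns found for dialect {dialect!r}")

    records: list[PeptideRecord] = []
    seen: set[str] = set()
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        row_d = dict(zip(df.columns, row))
        seq = str(row_d[seq_col]).strip().upper()
        if seq in seen:
            raise ValidationError(f"{path}: duplicate peptide {seq!r} at row {idx}")
        seen.add(seq)
        proteins = [p for p in str(row_d[prot_col]).split(";") if p and p != "nan"]
        intensities = {
            run_id: _parse_intensity(row_d[col], col, idx)
            for col, run_id in run_cols.items()
        }
        records.append(PeptideRecord(seq, proteins, intensities))
    return records


def write_peptide_table(records: Sequence[PeptideRecord], path: str | Path) -> None:
    """Write records as a generic-tsv table (round-trips with the reader)."""
    if not records:
        raise ValueError("no records to write")
    run_ids = list(records[0].intensities)
    rows = [
        {
            "peptide": r.peptide_seq,
            "protein": ";".join(r.protein_ids),
            **{run: r.intensities[run] for run in run_ids},
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def filter_contaminants(
    records: Iterable[PeptideRecord],
    patterns: Sequence[str] = DEFAULT_CONTAMINANT_PATTERNS,
) -> list[PeptideRecord]:
    """Drop records whose protein ids contain any contaminant pattern.

    Matching is substring-based, mirroring MaxQuant's ``CON__``/``REV__``
    prefixes. Idempotent; order-preserving.
    """
    if not patterns:
        raise ValueError("patterns must be non-empty")
    kept, removed = [], 0
    for rec in records:
        if any(pat in pid for pid in rec.protein_ids for pat in patterns):
            rec.is_contaminant = True
            removed += 1
        else:
            kept.append(rec)
    logger.info("filter_contaminants: removed %d record(s)", removed)
    if not kept:
        logger.warning("filter_contaminants: all records were removed")
    return kept


# ---------------------------------------------------------------------------
# design files and FASTA


def read_design(path: str | Path) -> ExperimentDesign:
    """Read a TSV design with columns run_id, condition, replicate, batch."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("run_id", "condition", "replicate", "batch"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    runs = []
    for idx, row in df.iterrows():
        key = str(row["condition"]).strip().lower()
        if key not in _CONDITION_ALIASES:
            raise ValidationError(
                f"{path}: unknown condition {row['condition']!r} at row {idx + 2}"
            )
        runs.append(
            RunInfo(
                run_id=str(row["run_id"]).strip(),
                condition=_CONDITION_ALIASES[key],
                replicate=int(row["replicate"]),
                batch=str(row["batch"]).strip(),
            )
        )
    return ExperimentDesign(runs)


def write_design(design: ExperimentDesign, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "run_id": r.run_id,
                "condition": r.condition.value,
                "replicate": r.replicate,
                "batch": r.batch,
            }
            for r in design.runs
        ]
    ).to_csv(path, sep="\t", index=False)


def read_protein_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read protein sequences; uppercase, strip trailing ``*``, check alphabet."""
    proteins = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper().rstrip("*")
        proteins.append(ProteinSequence(accession=record.id, residues=seq))
    if not proteins:
        raise FormatError(f"{path}: no FASTA records found")
    return proteins


def validate_against_design(
    records: Sequence[PeptideRecord], design: ExperimentDesign
) -> None:
    """Check that every run in the records is declared in the design."""
    declared = set(design.run_ids)
    for rec in records:
        extra = set(rec.intensities) - declared
        if extra:
            raise ValidationError(
                f"peptide {rec.peptide_seq}: runs {sorted(extra)} not in design"
            )
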