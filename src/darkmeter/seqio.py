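"""Readers and writers for the on-disk formats used by the pipeline.

FASTA, FASTQ (Phred+33 only) and newick parsing go through Biopython and
scikit-bio; this module adds the cross-referencing and validation the
pipeline needs (tree tips must have sequences and metadata, copy numbers
must be positive integers, run ids must be unique) and the consensus
environment vocabulary for sample metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

from .config import CONSENSUS_ENVIRONMENTS, Config

logger = logging.getLogger("darkmeter")

DNA_ALPHABET = frozenset("ACGTN")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ConsistencyError(ValueError):
    """Cross-referenced inputs (FASTA / tree / metadata) disagree."""


@dataclass
class SeqRecord:
    """A DNA sequence with optional per-base Phred qualities."""

    id: str
    sequence: str
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r}: non-DNA characters {sorted(bad)}"
            )
        if self.qualities is not None:
            if len(self.qualities) != len(self.sequence):
                raise FormatError(
                    f"record {self.id!r}: sequence length "
                    f"{len(self.sequence)} != quality length "
                    f"{len(self.qualities)}"
                )
            if any(q < 0 or q > 93 for q in self.qualities):
                raise FormatError(
                    f"record {self.id!r}: Phred scores outside [0, 93]"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SampleRecord:
    """Per-run bookkeeping: environment label and read accounting."""

    run_id: str
    environment: str
    reads_raw: int = 0
    reads_qc: int = 0
    reads_bacteria: int = 0
    reads_archaea: int = 0
    reads_unassigned: int = 0

    def validate(self) -> None:
        if self.reads_qc > self.reads_raw:
            raise ValueError(
                f"sample {self.run_id}: QC-passing reads exceed raw reads"
            )
        assigned = self.reads_bacteria + self.reads_archaea + self.reads_unassigned
        if assigned != self.reads_qc:
            raise ValueError(
                f"sample {self.run_id}: domain counts {assigned} != "
                f"QC-passing reads {self.reads_qc}"
            )


def read_fastq(path: str | Path) -> Iterator[SeqRecord]:
    """Stream Phred+33 FASTQ records in file order.

    Malformed records (truncated blocks, sequence/quality length
    mismatches) raise :class:`FormatError` naming the offending record.
    """
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            yield SeqRecord(
                id=rec.id,
                sequence=str(rec.seq),
                qualities=list(rec.letter_annotations["phred_quality"]),
            )
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for rec in records:
            if rec.qualities is None:
                raise ValueError(f"record {rec.id} has no qualities")
            qual = "".join(chr(q + 33) for q in rec.qualities)
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")
            n += 1
    return n


def read_fasta(path: str | Path) -> Iterator[SeqRecord]:
    for rec in SeqIO.parse(str(path), "fasta"):
        yield SeqRecord(id=rec.id, sequence=str(rec.seq))


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")
            n += 1
    return n


def read_reference_db(
    fasta_path: str | Path,
    newick_path: str | Path,
    meta_path: str | Path,
):
    """Load and cross-reference a reference database.

    The FASTA holds one full-length 16S rRNA gene per reference genome;
    the newick file a rooted tree whose tip labels are the reference
    ids; the TSV columns ``ref_id``, ``copy_number``, ``domain`` and
    ``lineage``.  Every tree tip must have a sequence and a metadata row
    with a positive integer copy number.
    """
    from .refdb import ReferenceDB, RefTip  # deferred: refdb imports seqio types

    seqs = {rec.id: rec.sequence for rec in read_fasta(fasta_path)}
    meta = pd.read_csv(meta_path, sep="\t", dtype={"ref_id": str})
    required = {"ref_id", "copy_number", "domain", "lineage"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise FormatError(f"{meta_path}: missing columns {sorted(missing_cols)}")
    if meta["ref_id"].duplicated().any():
        dups = meta.loc[meta["ref_id"].duplicated(), "ref_id"].tolist()
        raise ConsistencyError(f"duplicate metadata rows for {dups}")

    with open(newick_path) as fh:
        newick = fh.read()

    rows = meta.set_index("ref_id")
    tips: dict[str, RefTip] = {}
    problems: list[str] = []
    for tip_id in sorted(set(seqs) | set(rows.index)):
        if tip_id not in seqs:
            problems.append(f"{tip_id}: no FASTA record")
            continue
        if tip_id not in rows.index:
            problems.append(f"{tip_id}: no metadata row")
            continue
        row = rows.loc[tip_id]
        cn = row["copy_number"]
        if cn != int(cn) or int(cn) < 1:
            raise ConsistencyError(
                f"{tip_id}: copy number {cn!r} is not a positive integer"
            )
        tips[tip_id] = RefTip(
            tip_id=tip_id,
            sequence=seqs[tip_id],
            copy_number=int(cn),
            domain=str(row["domain"]),
            lineage=str(row["lineage"]),
        )
    if problems:
        raise ConsistencyError("; ".join(problems))
    return ReferenceDB.from_newick(newick, tips)


def read_sample_metadata(
    path: str | Path, config: Config | None = None
) -> dict[str, SampleRecord]:
    """Read the run-id → consensus-environment TSV.

    Labels outside the consensus vocabulary are collapsed through the
    alias map when possible; otherwise they are preserved as "unknown"
    and logged.  Duplicate run ids raise.
    """
    config = config or Config()
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"run_id", "environment"} <= set(df.columns):
        raise FormatError(f"{path}: need columns run_id, environment")
    if df["run_id"].duplicated().any():
        dups = df.loc[df["run_id"].duplicated(), "run_id"].tolist()
        raise ConsistencyError(f"duplicate run ids: {dups}")
    samples: dict[str, SampleRecord] = {}
    for row in df.itertuples(index=False):
        env = str(row.environment).strip().lower()
        env = config.env_aliases.get(env, env)
        if env not in CONSENSUS_ENVIRONMENTS:
            logger.warning(
                "run %s: environment %r outside consensus vocabulary; "
                "recorded as 'unknown'",
                row.run_id,
                row.environment,
            )
            env = "unknown"
        samples[row.run_id] = SampleRecord(run_id=row.run_id, environment=env)
    return samples


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as deterministic TSV (no index, '\\n' endings)."""
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
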