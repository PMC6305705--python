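"""Quality trimming, length filtering and dereplication of forward reads.

Reads are truncated at the first base whose Phred score drops below the
threshold (default Q20); trimmed reads shorter than the length floor
(default 75 nt) are discarded.  Surviving reads are dereplicated into
unique reads — one record per distinct sequence string with per-sample
counts — the unit every downstream statistic operates on.  An optional
greedy one-mismatch collapse absorbs rare near-duplicates into abundant
uniques; it is a deterministic stand-in for error-model denoising, not a
re-implementation of it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, TYPE_CHECKING

from .seqio import SeqRecord

if TYPE_CHECKING:  # pragma: no cover
    from .placement import Placement


@dataclass
class UniqueRead:
    """A dereplicated read sequence with per-sample counts."""

    uid: str
    sequence: str
    counts: Counter = field(default_factory=Counter)
    domain: str = "unassigned"
    placement: Optional["Placement"] = None

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


def quality_trim(
    read: SeqRecord, q_min: int = 20, len_min: int = 75
) -> SeqRecord | None:
    """Truncate at the first base below ``q_min``; drop short survivors.

    Returns the trimmed record, or ``None`` when fewer than ``len_min``
    bases remain.  The kept prefix ends strictly before the first
    low-quality base, so the operation is idempotent.
    """
    if read.qualities is None:
        raise ValueError(f"read {read.id}: no quality scores, cannot trim")
    cut = len(read)
    for i, q in enumerate(read.qualities):
        if q < q_min:
            cut = i
            break
    if cut < len_min:
        return None
    if cut == len(read):
        return read
    return SeqRecord(
        id=read.id,
        sequence=read.sequence[:cut],
        qualities=read.qualities[:cut],
    )


def trim_sample(
    reads: Iterable[SeqRecord], q_min: int = 20, len_min: int = 75
) -> Iterator[SeqRecord]:
    for read in reads:
        kept = quality_trim(read, q_min, len_min)
        if kept is not None:
            yield kept


def dereplicate(reads_by_sample: dict[str, Iterable[str]]) -> list[UniqueRead]:
    """Collapse identical sequences into unique reads with sample counts.

    ``reads_by_sample`` maps sample id to an iterable of (already
    trimmed and filtered) read sequences.  The sum of unique-read total
    counts equals the number of input reads, exactly.  Output is sorted
    by descending total count, then lexicographically by sequence, and
    uids are assigned in that order.
    """
    per_seq: dict[str, Counter] = {}
    for sample_id, seqs in reads_by_sample.items():
        for seq in seqs:
            per_seq.setdefault(seq, Counter())[sample_id] += 1
    ordered = sorted(
        per_seq.items(), key=lambda kv: (-sum(kv[1].values()), kv[0])
    )
    return [
        UniqueRead(uid=f"u{i:06d}", sequence=seq, counts=counts)
        for i, (seq, counts) in enumerate(ordered)
    ]


def hamming(a: str, b: str) -> int | None:
    """Substitution distance between equal-length strings, else ``None``."""
    if len(a) != len(b):
        return None
    return sum(x != y for x, y in zip(a, b))


def error_collapse(
    uniques: list[UniqueRead], max_mismatch: int = 1
) -> list[UniqueRead]:
    """Greedy absorption of near-duplicate uniques into abundant ones.

    Uniques are visited in descending total-count order (sequence
    lexicographic tie-break).  A unique within ``max_mismatch``
    substitutions of an already-accepted, strictly more abundant unique
    is merged into the closest such acceptor (first accepted wins ties);
    otherwise it is accepted itself.  Total counts are conserved and the
    number of uniques never grows.
    """
    ordered = sorted(uniques, key=lambda u: (-u.total_count, u.sequence))
    accepted: list[UniqueRead] = []
    by_length: dict[int, list[UniqueRead]] = {}
    for u in ordered:
        best: UniqueRead | None = None
        best_d = max_mismatch + 1
        for cand in by_length.get(len(u.sequence), ()):
            if cand.total_count <= u.total_count:
                continue
            d = hamming(cand.sequence, u.sequence)
            if d is not None and d <= max_mismatch and d < best_d:
                best, best_d = cand, d
        if best is None:
            keep = UniqueRead(
                uid=u.uid,
                sequence=u.sequence,
                counts=Counter(u.counts),
                domain=u.domain,
            )
            accepted.append(keep)
            by_length.setdefault(len(keep.sequence), []).append(keep)
        else:
            best.counts.update(u.counts)
    return accepted
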