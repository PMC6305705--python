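"""Nearest-reference search, map ratio, edge assignment, normalization.

The map ratio is the fraction of identical positions between a query
amplicon read and its best-matching full-length 16S reference: the
pipeline's proxy for how well a community member is represented by the
completely sequenced genomes.  It is computed from an optimal semi-global
alignment in which terminal gaps on the reference are free (a short read
aligns within a full-length gene), with the read length as denominator:
every query base counts, whether aligned, inserted, or clipped at a read
end, while reference overhangs do not.  ``N`` bases never count as
matches.

Nearest-reference search ranks candidates by shared-k-mer count and
aligns only the top tier; when a query shares no k-mers with any
reference — or so few that the ranking is chance-level — the prefilter
is bypassed and every reference is aligned, so the prefiltered search
returns the same co-optimal set as an exhaustive scan.  Reads with a unique best reference are placed on that tip's edge;
ties are placed on the edge above the most recent common ancestor of the
tied references.  Edge abundances are normalized by dividing each edge's
read count by its 16S copy-number estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align

from .config import Config
from .qc import UniqueRead
from .refdb import ReferenceDB


@dataclass(frozen=True)
class AlignmentResult:
    """Counts from one semi-global query/reference alignment."""

    score: float
    matches: int
    mismatches: int
    query_gaps: int  # query bases aligned to reference gaps (insertions)
    ref_gaps: int  # internal reference bases aligned to query gaps (deletions)
    aligned_len: int  # query positions in the identity denominator

    @property
    def identity(self) -> float:
        if self.aligned_len == 0:
            raise ZeroDivisionError("zero aligned length: identity undefined")
        return self.matches / self.aligned_len


@dataclass(frozen=True)
class Placement:
    """Edge assignment and identity for one unique read."""

    unique_read_id: str
    best_refs: tuple[str, ...]
    edge_id: int
    map_ratio: float
    aligned_len: int


@dataclass
class EdgeAbundance:
    edge_id: int
    raw_count: int
    normalized_count: float
    per_sample: dict[str, int]


def make_aligner(config: Config | None = None) -> Align.PairwiseAligner:
    """Semi-global aligner: reference terminal overhangs are free."""
    config = config or Config()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = config.match
    aligner.mismatch_score = config.mismatch
    aligner.open_gap_score = config.gap_open
    aligner.extend_gap_score = config.gap_extend
    # Deletions are reference bases aligned to gaps in the query row;
    # making them free at the alignment ends yields the semi-global
    # (read-within-gene) regime.
    aligner.end_deletion_score = 0.0
    return aligner


def align_semi_global(
    query: str,
    reference: str,
    aligner: Align.PairwiseAligner | None = None,
) -> AlignmentResult:
    """Optimal semi-global alignment of a read against a reference.

    Biopython's PairwiseAligner computes the optimal score; counts are
    taken from its first (deterministically ordered) traceback.  ``N``
    positions are counted as mismatches regardless of the other base.
    """
    if not query or not reference:
        raise ValueError("sequences must be nonempty")
    if aligner is None:
        aligner = make_aligner()
    aln = aligner.align(reference, query)[0]
    blocks_ref, blocks_query = aln.aligned
    matches = 0
    aligned_cols = 0
    for (rs, re_), (qs, qe) in zip(blocks_ref, blocks_query):
        aligned_cols += qe - qs
        for r, q in zip(reference[rs:re_], query[qs:qe]):
            if r == q and r != "N":
                matches += 1
    # Query bases not inside an aligned block are insertions (aligned to
    # reference gaps) or end-clipped; both consume query positions.
    query_gaps = len(query) - aligned_cols
    # Internal reference gap columns: reference bases skipped between
    # consecutive aligned blocks.
    ref_gaps = sum(
        int(blocks_ref[i + 1][0] - blocks_ref[i][1])
        for i in range(len(blocks_ref) - 1)
    )
    return AlignmentResult(
        score=aln.score,
        matches=matches,
        mismatches=aligned_cols - matches,
        query_gaps=query_gaps,
        ref_gaps=ref_gaps,
        aligned_len=len(query),
    )


def map_ratio(alignment: AlignmentResult) -> float:
    """Identity fraction: identical columns over query positions consumed."""
    return alignment.identity


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


class KmerIndex:
    """Per-reference k-mer sets for the nearest-reference prefilter."""

    def __init__(self, db: ReferenceDB, k: int):
        self.k = k
        self.ref_kmers = {
            tip_id: _kmer_set(tip.sequence, k) for tip_id, tip in db.tips.items()
        }

    def shared_counts(self, query: str) -> dict[str, int]:
        qk = _kmer_set(query, self.k)
        return {r: len(qk & rk) for r, rk in self.ref_kmers.items()}


def nearest_reference(
    query: str,
    db: ReferenceDB,
    config: Config | None = None,
    aligner: Align.PairwiseAligner | None = None,
    index: KmerIndex | None = None,
    exhaustive: bool = False,
) -> tuple[tuple[str, ...], AlignmentResult]:
    """References with maximal identity to the query, with the alignment.

    Candidates are ranked by shared-k-mer count and only those within
    ``config.kmer_tier`` of the best count are aligned; when the k-mer
    signal is absent or chance-level (best count below
    ``config.kmer_min_signal``), every reference is aligned.  Ties are
    returned as a sorted tuple, never broken arbitrarily.
    """
    if not db.tips:
        raise ValueError("reference database is empty")
    config = config or Config()
    if aligner is None:
        aligner = make_aligner(config)
    if exhaustive:
        candidates = sorted(db.tips)
    else:
        if index is None:
            index = KmerIndex(db, config.kmer_size)
        shared = index.shared_counts(query)
        best_k = max(shared.values())
        if best_k < config.kmer_min_signal:
            # no k-mers shared, or so few that the ranking is chance-level
            candidates = sorted(db.tips)
        else:
            floor = config.kmer_tier * best_k
            candidates = sorted(r for r, c in shared.items() if c >= floor)

    best_ids: list[str] = []
    best_aln: AlignmentResult | None = None
    for ref_id in candidates:
        aln = align_semi_global(query, db.tips[ref_id].sequence, aligner)
        if best_aln is None or aln.identity > best_aln.identity + 1e-12:
            best_ids = [ref_id]
            best_aln = aln
        elif abs(aln.identity - best_aln.identity) <= 1e-12:
            best_ids.append(ref_id)
    assert best_aln is not None
    return tuple(sorted(best_ids)), best_aln


def place_read(
    uread: UniqueRead,
    db: ReferenceDB,
    config: Config | None = None,
    aligner: Align.PairwiseAligner | None = None,
    index: KmerIndex | None = None,
) -> Placement:
    """Assign a unique read to a tree edge via its nearest reference(s)."""
    best_refs, aln = nearest_reference(
        uread.sequence, db, config, aligner=aligner, index=index
    )
    if len(best_refs) == 1:
        edge = db.tip_edge(best_refs[0])
    else:
        edge = db.mrca_edge(best_refs)
    return Placement(
        unique_read_id=uread.uid,
        best_refs=best_refs,
        edge_id=edge,
        map_ratio=map_ratio(aln),
        aligned_len=aln.aligned_len,
    )


def place_all(
    uniques: Sequence[UniqueRead],
    db: ReferenceDB,
    config: Config | None = None,
) -> list[Placement]:
    """Place every unique read, reusing one aligner and k-mer index."""
    config = config or Config()
    aligner = make_aligner(config)
    index = KmerIndex(db, config.kmer_size)
    placements = []
    for u in uniques:
        p = place_read(u, db, config, aligner=aligner, index=index)
        u.placement = p
        placements.append(p)
    return placements


def tally_edges(
    uniques: Sequence[UniqueRead],
    placements: Sequence[Placement] | None = None,
) -> dict[int, EdgeAbundance]:
    """Raw per-edge read counts (per-sample breakdown retained)."""
    tally: dict[int, EdgeAbundance] = {}
    by_uid = (
        {p.unique_read_id: p for p in placements} if placements is not None else None
    )
    for u in uniques:
        p = by_uid[u.uid] if by_uid is not None else u.placement
        if p is None:
            raise ValueError(f"unique read {u.uid} has no placement")
        rec = tally.setdefault(
            p.edge_id, EdgeAbundance(p.edge_id, 0, 0.0, {})
        )
        rec.raw_count += u.total_count
        for sample, n in u.counts.items():
            rec.per_sample[sample] = rec.per_sample.get(sample, 0) + n
    return tally


def normalize(
    edge_counts: Mapping[int, EdgeAbundance] | Mapping[int, int],
    db: ReferenceDB,
) -> dict[int, EdgeAbundance]:
    """Divide each edge's raw count by its 16S copy-number estimate.

    The transform is exactly invertible: summing normalized counts times
    edge copy number over edges recovers the raw total.
    """
    out: dict[int, EdgeAbundance] = {}
    for edge_id, rec in edge_counts.items():
        if edge_id not in db.edge_copy:
            raise KeyError(f"edge {edge_id} has no copy-number estimate")
        if isinstance(rec, EdgeAbundance):
            raw, per_sample = rec.raw_count, dict(rec.per_sample)
        else:
            raw, per_sample = int(rec), {}
        out[edge_id] = EdgeAbundance(
            edge_id=edge_id,
            raw_count=raw,
            normalized_count=raw / db.edge_copy[edge_id],
            per_sample=per_sample,
        )
    return out


def placements_frame(
    uniques: Sequence[UniqueRead], placements: Sequence[Placement]
) -> pd.DataFrame:
    """Flat table of placements for TSV output."""
    by_uid = {u.uid: u for u in uniques}
    rows = []
    for p in placements:
        u = by_uid[p.unique_read_id]
        rows.append(
            {
                "unique_id": p.unique_read_id,
                "best_refs": ",".join(p.best_refs),
                "edge_id": p.edge_id,
                "map_ratio": p.map_ratio,
                "aligned_len": p.aligned_len,
                "domain": u.domain,
                "total_count": u.total_count,
            }
        )
    return pd.DataFrame(rows)
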