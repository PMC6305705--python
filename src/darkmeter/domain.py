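"""Domain assignment: Bacteria, Archaea, or unassigned.

Each unique read is scored against per-domain panels of full-length 16S
sequences drawn from the reference database, using the same semi-global
aligner as placement.  The read receives the domain of the strictly best
panel score; ties, and best scores below a configurable fraction of the
read's maximum attainable score, leave the read unassigned.  An optional
Eukarya panel can be supplied; its hits are labeled and then discarded
by the pipeline, which carries only bacterial and archaeal reads
forward.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio import Align

from .config import Config
from .placement import align_semi_global, make_aligner
from .qc import UniqueRead
from .refdb import ReferenceDB

UNASSIGNED = "unassigned"


class PanelError(ValueError):
    """Domain panels are missing or empty."""


@dataclass(frozen=True)
class DomainPanel:
    domain: str
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise PanelError(f"domain panel {self.domain!r} is empty")


def build_panels(db: ReferenceDB) -> list[DomainPanel]:
    """Group reference sequences into per-domain panels.

    Panels are disjoint by construction (each reference genome carries
    one domain label).
    """
    by_domain: dict[str, list[str]] = {}
    for tip_id in sorted(db.tips):
        tip = db.tips[tip_id]
        by_domain.setdefault(tip.domain, []).append(tip.sequence)
    if not by_domain:
        raise PanelError("reference database has no tips")
    return [
        DomainPanel(domain=d, sequences=tuple(seqs))
        for d, seqs in sorted(by_domain.items())
    ]


def assign_domain(
    sequence: str,
    panels: Sequence[DomainPanel],
    config: Config | None = None,
    aligner: Align.PairwiseAligner | None = None,
) -> tuple[str, dict[str, float]]:
    """Best-panel decision rule with tie and cutoff protection.

    Returns ``(label, best score per panel)``.  The label is
    ``"unassigned"`` when two panels tie for the best score or when the
    best score is below ``config.domain_cutoff`` times the maximum
    attainable score (a perfect ungapped match).
    """
    if not panels:
        raise PanelError("no domain panels configured")
    config = config or Config()
    if aligner is None:
        aligner = make_aligner(config)
    scores: dict[str, float] = {}
    for panel in panels:
        best = max(
            align_semi_global(sequence, ref, aligner).score
            for ref in panel.sequences
        )
        scores[panel.domain] = best
    cutoff = config.domain_cutoff * config.match * len(sequence)
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    if ranked[0][1] < cutoff:
        return UNASSIGNED, scores
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return UNASSIGNED, scores
    return ranked[0][0], scores


def assign_all(
    uniques: Sequence[UniqueRead],
    panels: Sequence[DomainPanel],
    config: Config | None = None,
) -> None:
    """Label every unique read in place, reusing one aligner."""
    config = config or Config()
    aligner = make_aligner(config)
    for u in uniques:
        u.domain, _ = assign_domain(u.sequence, panels, config, aligner)
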