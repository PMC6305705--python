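"""Reference tree model: edges, MRCA queries, edge copy numbers.

A reference database couples one full-length 16S rRNA gene per completely
sequenced genome with a rooted phylogeny over those genomes and the
per-genome 16S gene copy number.  Query reads are placed onto *edges* of
the tree — there is one edge above every node, tips and root included, so
a rooted bifurcating tree over n genomes exposes 2n-1 edges.  Reads whose
nearest reference is unique land on that tip's edge; ambiguous reads land
on the edge above the most recent common ancestor of their co-optimal
references.

Edge copy numbers drive abundance normalization: a tip edge carries the
tip's own 16S copy number, an internal edge the arithmetic mean over the
tips it subtends, so the estimate is always bounded by the observed copy
numbers below it.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from skbio import TreeNode

from . import seqio


class TreeError(ValueError):
    """The reference tree is unusable (unrooted, unknown tips, ...)."""


@dataclass(frozen=True)
class RefTip:
    tip_id: str
    sequence: str
    copy_number: int
    domain: str
    lineage: str


class ReferenceDB:
    """Cross-referenced 16S reference database over a rooted tree."""

    def __init__(self, tree: TreeNode, tips: Mapping[str, RefTip]):
        if len(tree.children) != 2:
            raise TreeError(
                f"tree root has {len(tree.children)} children; a rooted "
                "tree (two root children) is required"
            )
        self.tree = tree
        self.tips: dict[str, RefTip] = dict(tips)

        tip_names = {t.name for t in tree.tips()}
        missing = sorted(tip_names - set(self.tips))
        if missing:
            raise seqio.ConsistencyError(
                f"tree tips without reference records: {missing}"
            )
        extra = sorted(set(self.tips) - tip_names)
        if extra:
            raise seqio.ConsistencyError(
                f"reference records not in the tree: {extra}"
            )

        # Stable edge ids: postorder index of the node below each edge.
        self._nodes: list[TreeNode] = []
        self._tip_edge: dict[str, int] = {}
        self._subtended: dict[int, frozenset[str]] = {}
        for i, node in enumerate(tree.postorder(include_self=True)):
            node.edge_id = i
            self._nodes.append(node)
            if node.is_tip():
                self._tip_edge[node.name] = i
                self._subtended[i] = frozenset([node.name])
            else:
                sub: set[str] = set()
                for child in node.children:
                    sub |= self._subtended[child.edge_id]
                self._subtended[i] = frozenset(sub)

        self.edge_copy: dict[int, float] = {
            e: sum(self.tips[t].copy_number for t in sub) / len(sub)
            for e, sub in self._subtended.items()
        }

    # ------------------------------------------------------------------
    # construction / serialization

    @classmethod
    def from_newick(cls, newick: str, tips: Mapping[str, RefTip]) -> "ReferenceDB":
        tree = TreeNode.read(io.StringIO(newick))
        return cls(tree, tips)

    def write(self, out_dir: str | Path) -> None:
        """Write FASTA + newick + metadata TSV + edge table."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        seqio.write_fasta(
            (seqio.SeqRecord(id=t.tip_id, sequence=t.sequence)
             for t in sorted(self.tips.values(), key=lambda t: t.tip_id)),
            out / "references.fasta",
        )
        with open(out / "tree.nwk", "w") as fh:
            fh.write(str(self.tree).strip() + "\n")
        meta = pd.DataFrame(
            [
                (t.tip_id, t.copy_number, t.domain, t.lineage)
                for t in sorted(self.tips.values(), key=lambda t: t.tip_id)
            ],
            columns=["ref_id", "copy_number", "domain", "lineage"],
        )
        seqio.write_tsv(meta, out / "metadata.tsv")
        seqio.write_tsv(self.edge_table(), out / "edges.tsv")

    @classmethod
    def read(cls, in_dir: str | Path) -> "ReferenceDB":
        d = Path(in_dir)
        return seqio.read_reference_db(
            d / "references.fasta", d / "tree.nwk", d / "metadata.tsv"
        )

    # ------------------------------------------------------------------
    # edge queries

    @property
    def n_edges(self) -> int:
        return len(self._nodes)

    def tip_edge(self, tip_id: str) -> int:
        try:
            return self._tip_edge[tip_id]
        except KeyError:
            raise TreeError(f"unknown tip {tip_id!r}") from None

    def subtended_tips(self, edge_id: int) -> frozenset[str]:
        return self._subtended[edge_id]

    def is_tip_edge(self, edge_id: int) -> bool:
        return self._nodes[edge_id].is_tip()

    def mrca_edge(self, tip_ids: Iterable[str]) -> int:
        """Edge above the most recent common ancestor of ``tip_ids``.

        Order-invariant in its tip set; a single tip maps to its own
        tip edge.  Polytomies are handled by scikit-bio's LCA.
        """
        ids = sorted(set(tip_ids))
        if not ids:
            raise ValueError("tip_ids must be nonempty")
        unknown = [t for t in ids if t not in self._tip_edge]
        if unknown:
            raise TreeError(f"unknown tips {unknown}")
        if len(ids) == 1:
            return self._tip_edge[ids[0]]
        node = self.tree.lca(ids)
        return node.edge_id

    def edge_table(self) -> pd.DataFrame:
        """One row per edge: id, parent edge, label, tip status, copy number."""
        rows = []
        for node in self._nodes:
            rows.append(
                {
                    "edge_id": node.edge_id,
                    "parent_edge": (
                        node.parent.edge_id if node.parent is not None else -1
                    ),
                    "label": node.name or "",
                    "is_tip": node.is_tip(),
                    "n_subtended_tips": len(self._subtended[node.edge_id]),
                    "edge_copy": self.edge_copy[node.edge_id],
                }
            )
        return pd.DataFrame(rows)

    def domain_of_edge(self, edge_id: int) -> str:
        """Domain label of an edge's subtended tips ('mixed' if they disagree)."""
        domains = {self.tips[t].domain for t in self._subtended[edge_id]}
        return domains.pop() if len(domains) == 1 else "mixed"

    def edge_label(self, edge_id: int) -> str:
        """Human-readable nearest-taxon label for reporting tables."""
        sub = self._subtended[edge_id]
        if len(sub) == 1:
            return next(iter(sub))
        node = self._nodes[edge_id]
        if node.name:
            return node.name
        return f"clade({len(sub)} genomes)"
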