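"""Synthetic reference databases and amplicon read sets with known truth.

The generator emulates the structure of a 16S rRNA amplicon survey
against a genome-derived reference database: a rooted bifurcating
reference tree (pure-birth topology, exponential branch lengths) whose
two root-child clades define the Bacteria and Archaea panels; tip
sequences evolved from a random root gene by site-wise substitution
(no indels by default); integer 16S copy numbers per tip; and per-sample
FASTQ read sets drawn both from in-database genomes and from "dark"
lineages at controlled divergence from their nearest sequenced relative.

Divergence is applied as an exact count of substitutions at distinct
sites — ``round(d * read_len)`` — so the constructed identity between a
pre-error read and its source window is exactly ``1 - d``, which makes
parameter-recovery checks sharp rather than statistical.  Sequencing
errors and sub-Q20 quality positions are then layered on top at
configurable rates.  Every read is recorded in a truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .config import CONSENSUS_ENVIRONMENTS
from .refdb import ReferenceDB, RefTip
from . import seqio

BASES = np.array(list("ACGT"))


@dataclass
class SynthParams:
    """Knobs for the synthetic survey generator.

    ``divergence_levels`` are the constructed distances of dark-lineage
    queries from their nearest sequenced genome; level 0 queries are
    in-database.  ``tree_branch_scale`` is the mean per-site
    substitution probability per branch; ``domain_divergence`` is added
    to the two root-child branches so the Bacteria and Archaea clades
    are well separated, as the real domains are.  ``quality_profile``
    controls how many reads carry a sub-Q20 base late (trim survives the
    length floor) or early (read rejected).
    """

    n_refs: int = 20
    n_dark: int = 12
    n_in_db: int = 20
    gene_len: int = 1500
    read_len: int = 250
    divergence_levels: tuple[float, ...] = (0.05, 0.10, 0.20)
    seq_error_rate: float = 0.001
    copy_number_range: tuple[int, int] = (1, 15)
    n_samples: int = 6
    mean_abundance: float = 60.0
    tree_branch_scale: float = 0.02
    domain_divergence: float = 0.15
    indel_rate: float = 0.0
    environments: tuple[str, ...] | None = None
    quality_profile: dict = field(
        default_factory=lambda: {
            "high_q": 38,
            "low_q": 15,
            "trim_fraction": 0.10,
            "reject_fraction": 0.05,
        }
    )
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_refs < 2:
            raise ValueError("n_refs must be at least 2")
        if self.read_len > self.gene_len:
            raise ValueError("read_len must not exceed gene_len")
        for d in self.divergence_levels:
            if not 0 <= d < 1:
                raise ValueError(f"divergence level {d} outside [0, 1)")
        if not 0 <= self.seq_error_rate < 1:
            raise ValueError("seq_error_rate must be in [0, 1)")
        lo, hi = self.copy_number_range
        if lo < 1 or hi < lo:
            raise ValueError("copy_number_range must be a positive interval")


def _mutate(seq: np.ndarray, n_sub: int, rng: np.random.Generator) -> np.ndarray:
    """Substitute exactly ``n_sub`` distinct sites to a different base."""
    if n_sub == 0:
        return seq.copy()
    out = seq.copy()
    sites = rng.choice(len(seq), size=n_sub, replace=False)
    for s in sites:
        choices = BASES[BASES != out[s]]
        out[s] = rng.choice(choices)
    return out


def generate_reference_db(params: SynthParams) -> ReferenceDB:
    """Simulate a reference database: tree, sequences, copy numbers.

    Pure-birth topology: starting from a root with two children, a
    uniformly chosen leaf is repeatedly split until ``n_refs`` leaves
    exist.  Branch lengths are exponential with mean
    ``tree_branch_scale`` (per-site substitution probability); tip
    sequences accumulate ``round(length * gene_len)`` substitutions per
    branch from a random root gene.  The two root children found the
    Bacteria and Archaea clades.
    """
    # nonzero stream tag: SeedSequence zero-pads entropy, so a 0 tag
    # would collide with a plain default_rng(seed) stream elsewhere
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1014]))
    root = TreeNode(name="root")
    leaves: list[TreeNode] = []
    for _ in range(2):
        child = TreeNode(
            length=float(
                rng.exponential(params.tree_branch_scale) + params.domain_divergence
            )
        )
        root.append(child)
        leaves.append(child)
    n_internal = 0
    while len(leaves) < params.n_refs:
        parent = leaves.pop(int(rng.integers(len(leaves))))
        n_internal += 1
        parent.name = f"n{n_internal:03d}"
        for _ in range(2):
            child = TreeNode(length=float(rng.exponential(params.tree_branch_scale)))
            parent.append(child)
            leaves.append(child)

    # Name tips by domain side and evolve sequences from the root gene.
    bacteria_side = root.children[0]
    counters = {"Bacteria": 0, "Archaea": 0}
    root_seq = rng.choice(BASES, size=params.gene_len)
    seqs: dict[str, str] = {}
    lineages: dict[str, str] = {}
    domains: dict[str, str] = {}

    def walk(node: TreeNode, parent_seq: np.ndarray, side: str, path: list[str]):
        n_sub = int(round(node.length * params.gene_len))
        n_sub = min(n_sub, params.gene_len)
        seq = _mutate(parent_seq, n_sub, rng)
        if node.is_tip():
            prefix = "B" if side == "Bacteria" else "A"
            counters[side] += 1
            node.name = f"{prefix}{counters[side]:03d}"
            seqs[node.name] = "".join(seq)
            lineages[node.name] = ";".join([side, *path])
            domains[node.name] = side
        else:
            for child in node.children:
                walk(child, seq, side, path + [node.name or ""])

    for child in root.children:
        side = "Bacteria" if child is bacteria_side else "Archaea"
        walk(child, root_seq, side, [])

    lo, hi = params.copy_number_range
    tips = {}
    for tip_id in sorted(seqs):
        tips[tip_id] = RefTip(
            tip_id=tip_id,
            sequence=seqs[tip_id],
            copy_number=int(rng.integers(lo, hi + 1)),
            domain=domains[tip_id],
            lineage=lineages[tip_id],
        )
    return ReferenceDB(root, tips)


def generate_reads(
    db: ReferenceDB, params: SynthParams
) -> tuple[dict[str, list[seqio.SeqRecord]], pd.DataFrame, dict[str, str]]:
    """Simulate per-sample FASTQ reads plus a per-read truth table.

    Returns ``(reads per sample, truth table, sample -> environment)``.
    Query templates are built first: ``n_in_db`` in-database templates at
    divergence 0 and ``n_dark`` dark-lineage templates cycling through
    ``divergence_levels``.  Each template is a ``read_len`` window of a
    source gene with an exact substitution count; per-sample abundances
    are Poisson around ``mean_abundance / n_samples``.  Sequencing
    errors and quality dips are applied per emitted read.
    """
    if not params.divergence_levels:
        raise ValueError("divergence_levels must be nonempty")
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 2028]))
    tip_ids = sorted(db.tips)
    samples = [f"run{i:03d}" for i in range(params.n_samples)]
    envs = params.environments or CONSENSUS_ENVIRONMENTS
    # Sampling effort varies widely by environment in real surveys, so
    # allocate runs triangularly: 1 to the first environment, 2 to the
    # next, 3 to the next, ...
    sample_env: dict[str, str] = {}
    env_idx, remaining = 0, 1
    for s in samples:
        sample_env[s] = envs[env_idx % len(envs)]
        remaining -= 1
        if remaining == 0:
            env_idx += 1
            remaining = env_idx + 1

    templates = []  # (template_id, source_tip, window_start, divergence, seq)
    specs = [(i, 0.0) for i in range(params.n_in_db)]
    specs += [
        (params.n_in_db + j, params.divergence_levels[j % len(params.divergence_levels)])
        for j in range(params.n_dark)
    ]
    for tid, d in specs:
        source = tip_ids[int(rng.integers(len(tip_ids)))]
        start = int(rng.integers(params.gene_len - params.read_len + 1))
        window = np.array(
            list(db.tips[source].sequence[start : start + params.read_len])
        )
        n_sub = int(round(d * params.read_len))
        seq = _mutate(window, n_sub, rng)
        if params.indel_rate > 0:
            seq = _apply_indels(seq, params.indel_rate, rng)
        templates.append((f"q{tid:04d}", source, start, n_sub / params.read_len, seq))

    qp = params.quality_profile
    reads: dict[str, list[seqio.SeqRecord]] = {s: [] for s in samples}
    truth_rows = []
    lam = params.mean_abundance / params.n_samples
    for template_id, source, start, d_exact, tseq in templates:
        abundances = rng.poisson(lam, size=params.n_samples)
        if abundances.sum() == 0:
            abundances[0] = 1
        for sample, n in zip(samples, abundances):
            for j in range(int(n)):
                seq = tseq.copy()
                if params.seq_error_rate > 0:
                    err = rng.random(len(seq)) < params.seq_error_rate
                    for s in np.nonzero(err)[0]:
                        seq[s] = rng.choice(BASES[BASES != seq[s]])
                quals = [int(qp["high_q"])] * len(seq)
                u = rng.random()
                if u < qp["reject_fraction"]:
                    pos = int(rng.integers(0, min(75, len(seq))))
                    quals[pos] = int(qp["low_q"])
                elif u < qp["reject_fraction"] + qp["trim_fraction"]:
                    if len(seq) > 75:
                        pos = int(rng.integers(75, len(seq)))
                        quals[pos] = int(qp["low_q"])
                read_id = f"{template_id}:{sample}:{j:04d}"
                reads[sample].append(
                    seqio.SeqRecord(
                        id=read_id, sequence="".join(seq), qualities=quals
                    )
                )
                truth_rows.append(
                    {
                        "query_id": read_id,
                        "template_id": template_id,
                        "source_tip_id": source,
                        "window_start": start,
                        "applied_divergence": d_exact,
                        "is_dark": d_exact > 0,
                        "domain_truth": db.tips[source].domain,
                        "sample": sample,
                    }
                )
    truth = pd.DataFrame(truth_rows)
    return reads, truth, sample_env


def _apply_indels(
    seq: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Optional single-base indels, for exercising gapped alignment."""
    out = []
    for base in seq:
        r = rng.random()
        if r < rate / 2:
            continue  # deletion
        out.append(base)
        if rate / 2 <= r < rate:
            out.append(rng.choice(BASES))  # insertion after this base
    if not out:
        out = [rng.choice(BASES)]
    return np.array(out)


def write_synthetic_survey(params: SynthParams, out_dir: str | Path) -> dict:
    """Generate and write a full synthetic survey to ``out_dir``.

    Layout: ``refdb/`` (FASTA, newick, metadata, edge table),
    ``reads/<run>.fastq``, ``truth.tsv``, ``samples.tsv``.  Outputs are
    byte-identical across runs with the same parameters.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    db = generate_reference_db(params)
    db.write(out / "refdb")
    reads, truth, sample_env = generate_reads(db, params)
    (out / "reads").mkdir(exist_ok=True)
    n_reads = {}
    for sample, recs in reads.items():
        n_reads[sample] = seqio.write_fastq(recs, out / "reads" / f"{sample}.fastq")
    seqio.write_tsv(truth, out / "truth.tsv")
    seqio.write_tsv(
        pd.DataFrame(
            sorted(sample_env.items()), columns=["run_id", "environment"]
        ),
        out / "samples.tsv",
    )
    return {"n_refs": len(db.tips), "reads_per_sample": n_reads}
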