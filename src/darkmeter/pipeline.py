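"""End-to-end orchestration: synth → QC → domain → placement → stats.

``run_all`` executes the stages in order on either a synthetic survey
(generated in place from a seed) or pre-existing inputs, writes every
stage output as TSV/FASTA under one output directory, and records a run
manifest: the configuration snapshot, the seed, input digests, and a
read-count ledger (raw → QC-passing → domain-assigned → placed) whose
conservation identities are checked before the manifest is written.
All randomness flows from the single config seed, so a rerun with the
same config reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import darkstats, domain, placement, qc, seqio, synth
from .config import Config
from .refdb import ReferenceDB


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(
    config: Config,
    out_dir: str | Path,
    synth_params: synth.SynthParams | None = None,
    input_dir: str | Path | None = None,
) -> dict:
    """Run the full pipeline; returns the manifest dict.

    Exactly one of ``synth_params`` / ``input_dir`` drives the run.  An
    input directory must follow the synthetic-survey layout: ``refdb/``,
    ``reads/<run>.fastq``, ``samples.tsv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ledger: dict[str, int] = {}

    # stage: inputs -------------------------------------------------
    try:
        if synth_params is not None:
            synth_params = dataclasses.replace(synth_params, seed=config.seed)
            synth.write_synthetic_survey(synth_params, out / "inputs")
            input_dir = out / "inputs"
        elif input_dir is None:
            raise ValueError("either synth_params or input_dir is required")
        input_dir = Path(input_dir)
        db = ReferenceDB.read(input_dir / "refdb")
        sample_records = seqio.read_sample_metadata(
            input_dir / "samples.tsv", config
        )
    except Exception as exc:
        raise StageError(f"input stage failed: {exc}") from exc

    # stage: qc ------------------------------------------------------
    try:
        trimmed: dict[str, list[str]] = {}
        for run_id, rec in sorted(sample_records.items()):
            fq = input_dir / "reads" / f"{run_id}.fastq"
            raw = list(seqio.read_fastq(fq))
            kept = list(qc.trim_sample(raw, config.q_min, config.len_min))
            rec.reads_raw = len(raw)
            rec.reads_qc = len(kept)
            trimmed[run_id] = [r.sequence for r in kept]
        uniques = qc.dereplicate(trimmed)
        ledger["reads_raw"] = sum(r.reads_raw for r in sample_records.values())
        ledger["reads_qc"] = sum(r.reads_qc for r in sample_records.values())
        ledger["uniques_dereplicated"] = len(uniques)
        if config.collapse:
            uniques = qc.error_collapse(uniques, config.collapse_max_mismatch)
        ledger["uniques_final"] = len(uniques)
        assert sum(u.total_count for u in uniques) == ledger["reads_qc"]
    except Exception as exc:
        raise StageError(f"qc stage failed: {exc}") from exc

    # stage: domain --------------------------------------------------
    try:
        panels = domain.build_panels(db)
        domain.assign_all(uniques, panels, config)
        for rec in sample_records.values():
            rec.reads_bacteria = sum(
                u.counts.get(rec.run_id, 0) for u in uniques if u.domain == "Bacteria"
            )
            rec.reads_archaea = sum(
                u.counts.get(rec.run_id, 0) for u in uniques if u.domain == "Archaea"
            )
            rec.reads_unassigned = (
                rec.reads_qc - rec.reads_bacteria - rec.reads_archaea
            )
            rec.validate()
        ledger["reads_bacteria"] = sum(
            r.reads_bacteria for r in sample_records.values()
        )
        ledger["reads_archaea"] = sum(
            r.reads_archaea for r in sample_records.values()
        )
        ledger["reads_unassigned"] = sum(
            r.reads_unassigned for r in sample_records.values()
        )
        # Only bacterial and archaeal reads are carried forward.
        placed_uniques = [u for u in uniques if u.domain != domain.UNASSIGNED]
    except Exception as exc:
        raise StageError(f"domain stage failed: {exc}") from exc

    # stage: placement ----------------------------------------------
    try:
        placements = placement.place_all(placed_uniques, db, config)
        ledger["reads_placed"] = sum(u.total_count for u in placed_uniques)
        edges = placement.tally_edges(placed_uniques)
        norm = placement.normalize(edges, db)
        seqio.write_fasta(
            (seqio.SeqRecord(id=u.uid, sequence=u.sequence) for u in uniques),
            out / "uniques.fasta",
        )
        seqio.write_tsv(
            placement.placements_frame(placed_uniques, placements),
            out / "placements.tsv",
        )
        edge_rows = pd.DataFrame(
            [
                {
                    "edge_id": e,
                    "raw_count": norm[e].raw_count,
                    "normalized_count": norm[e].normalized_count,
                    "edge_copy": db.edge_copy[e],
                    "domain": db.domain_of_edge(e),
                }
                for e in sorted(norm)
            ]
        )
        seqio.write_tsv(edge_rows, out / "edge_abundance.tsv")
    except Exception as exc:
        raise StageError(f"placement stage failed: {exc}") from exc

    # stage: stats ---------------------------------------------------
    try:
        sample_env = {r.run_id: r.environment for r in sample_records.values()}
        sample_summary = darkstats.sample_summary_frame(
            placed_uniques, sample_env, config
        )
        seqio.write_tsv(sample_summary, out / "sample_summary.tsv")
        env_table = darkstats.env_summary(placed_uniques, sample_env, db)
        seqio.write_tsv(env_table, out / "env_summary.tsv")
        dark_table = darkstats.dark_read_table(placed_uniques, sample_env, config)
        seqio.write_tsv(dark_table, out / "dark_reads.tsv")
        dark_edges = []
        for dom in ("Bacteria", "Archaea"):
            dark_edges.extend(darkstats.top_dark_edges(dark_table, db, dom))
        seqio.write_tsv(
            darkstats.dark_edges_frame(dark_edges), out / "dark_edges.tsv"
        )
        rare = pd.concat(
            [
                darkstats.rarefaction_frame(placed_uniques, sample_env, dom)
                for dom in ("Bacteria", "Archaea")
            ],
            ignore_index=True,
        )
        seqio.write_tsv(rare, out / "rarefaction.tsv")
        regression: dict | None = None
        env_bact = env_table[env_table["final_reads_bacteria"] > 0]
        if len(env_bact) >= 3 and env_bact["n_samples"].nunique() > 1:
            fit = darkstats.unique_vs_samples_fit(
                env_bact["n_samples"].tolist(),
                env_bact["unique_reads_bacteria"].tolist(),
            )
            regression = {
                "r_squared": fit.r_squared,
                "p_value": fit.p_value,
                "slope": fit.slope,
                "intercept": fit.intercept,
            }
            seqio.write_tsv(pd.DataFrame([regression]), out / "regression.tsv")
    except Exception as exc:
        raise StageError(f"stats stage failed: {exc}") from exc

    # manifest -------------------------------------------------------
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "synthetic": synth_params is not None,
        "synth_params": (
            _params_dict(synth_params) if synth_params is not None else None
        ),
        "inputs": {
            p.relative_to(input_dir).as_posix(): _digest(p)
            for p in sorted(input_dir.rglob("*"))
            if p.is_file()
        },
        "ledger": ledger,
        "regression": regression,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _params_dict(params: synth.SynthParams) -> dict:
    d = dataclasses.asdict(params)
    for key, val in d.items():
        if isinstance(val, tuple):
            d[key] = list(val)
    return d
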