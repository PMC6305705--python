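"""Survey statistics: map-ratio summaries, dark-read flagging, rarefaction.

These are the roll-ups a 16S dark-matter survey reports: per-sample
mean map ratios (read-count weighted) with flagging of abundant,
poorly represented samples; the dark-read rule selecting unique reads
whose identity to any sequenced genome falls below a linear function of
log10 abundance; the most abundant low-identity tree edges; analytic
rarefaction curves; and the regression of unique-read richness on
sampling effort across environments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .config import Config
from .placement import Placement
from .qc import UniqueRead
from .refdb import ReferenceDB


@dataclass(frozen=True)
class SampleMapSummary:
    run_id: str
    domain: str
    n_reads: int
    mean_map_ratio: float
    in_distribution: bool  # passed the >min_reads floor
    flagged: bool


@dataclass(frozen=True)
class DarkEdgeRecord:
    edge_id: int
    n_unique_reads: int
    abundance: int
    mean_map_ratio: float
    nearest_taxon: str
    predominant_environment: str


@dataclass(frozen=True)
class RarefactionCurve:
    depths: tuple[int, ...]
    expected_uniques: tuple[float, ...]


# ----------------------------------------------------------------------
# per-sample summaries and flagging


def sample_mean_map_ratio(
    uniques: Sequence[UniqueRead],
    run_id: str,
    domain: str,
    config: Config | None = None,
) -> SampleMapSummary:
    """Read-count-weighted mean map ratio for one sample and domain.

    The mean is weighted by read counts, not by unique reads: a unique
    read observed 3,000 times contributes 3,000 draws.  Samples at or
    below the read floor are summarized but excluded from the flagging
    distribution (``in_distribution=False``), and never flagged.
    """
    config = config or Config()
    total = 0
    weighted = 0.0
    for u in uniques:
        if u.domain != domain or u.placement is None:
            continue
        n = u.counts.get(run_id, 0)
        total += n
        weighted += n * u.placement.map_ratio
    if total == 0:
        raise ValueError(
            f"sample {run_id}: no placed {domain} reads, mean undefined"
        )
    mean = weighted / total
    in_dist = total > config.min_reads_flag
    return SampleMapSummary(
        run_id=run_id,
        domain=domain,
        n_reads=total,
        mean_map_ratio=mean,
        in_distribution=in_dist,
        flagged=in_dist and mean < config.mean_ratio_flag,
    )


def sample_summary_frame(
    uniques: Sequence[UniqueRead],
    sample_env: Mapping[str, str],
    config: Config | None = None,
) -> pd.DataFrame:
    """SampleMapSummary rows for every (sample, domain) with placed reads."""
    rows = []
    for run_id in sorted(sample_env):
        for domain in ("Bacteria", "Archaea"):
            try:
                s = sample_mean_map_ratio(uniques, run_id, domain, config)
            except ValueError:
                continue
            rows.append(
                {
                    "run_id": s.run_id,
                    "environment": sample_env[run_id],
                    "domain": s.domain,
                    "n_reads": s.n_reads,
                    "mean_map_ratio": s.mean_map_ratio,
                    "in_distribution": s.in_distribution,
                    "flagged": s.flagged,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "run_id",
            "environment",
            "domain",
            "n_reads",
            "mean_map_ratio",
            "in_distribution",
            "flagged",
        ],
    )


# ----------------------------------------------------------------------
# dark-read flagging


def flag_dark_read(
    abundance: int, map_ratio: float, config: Config | None = None
) -> bool:
    """Dark-read rule: identity below a linear function of log abundance.

    A unique read is flagged when
    ``map_ratio < dark_slope * log10(abundance) + dark_intercept``.
    Abundance enters on a log10 scale; at abundance 1 the threshold is
    exactly the intercept.
    """
    config = config or Config()
    if abundance < 1:
        raise ValueError("abundance must be at least 1")
    threshold = config.dark_slope * math.log10(abundance) + config.dark_intercept
    return map_ratio < threshold


def dark_read_table(
    uniques: Sequence[UniqueRead],
    sample_env: Mapping[str, str],
    config: Config | None = None,
) -> pd.DataFrame:
    """Per-(unique, environment) abundance, map ratio, and dark flag.

    Abundance is tallied within each consensus environment (a unique
    read may appear in several environments with different abundances),
    or across the whole dataset when
    ``config.dark_abundance_scope == "global"``.
    """
    config = config or Config()
    rows = []
    for u in uniques:
        if u.placement is None or u.domain == "unassigned":
            continue
        by_env: dict[str, int] = {}
        for sample, n in u.counts.items():
            env = sample_env.get(sample, "unknown")
            by_env[env] = by_env.get(env, 0) + n
        if config.dark_abundance_scope == "global":
            by_env = {"all": u.total_count}
        for env, abundance in sorted(by_env.items()):
            if abundance == 0:
                continue
            rows.append(
                {
                    "unique_id": u.uid,
                    "domain": u.domain,
                    "environment": env,
                    "edge_id": u.placement.edge_id,
                    "abundance": abundance,
                    "map_ratio": u.placement.map_ratio,
                    "dark": flag_dark_read(abundance, u.placement.map_ratio, config),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "unique_id",
            "domain",
            "environment",
            "edge_id",
            "abundance",
            "map_ratio",
            "dark",
        ],
    )


def top_dark_edges(
    dark_table: pd.DataFrame,
    db: ReferenceDB,
    domain: str,
    k: int = 10,
) -> list[DarkEdgeRecord]:
    """The k most abundant tree edges among flagged unique reads.

    Flagged uniques of the given domain are aggregated by edge;
    per-edge abundance sums flagged counts (within-environment tallies
    summed), the edge mean map ratio is abundance-weighted, and the
    predominant environment is the one contributing the most flagged
    reads.  Ordering: abundance descending, edge id ascending on ties.
    """
    flagged = dark_table[(dark_table["dark"]) & (dark_table["domain"] == domain)]
    if flagged.empty:
        return []
    records = []
    for edge_id, grp in flagged.groupby("edge_id"):
        abundance = int(grp["abundance"].sum())
        env_totals = grp.groupby("environment")["abundance"].sum()
        env_order = sorted(
            env_totals.items(), key=lambda kv: (-kv[1], kv[0])
        )
        records.append(
            DarkEdgeRecord(
                edge_id=int(edge_id),
                n_unique_reads=grp["unique_id"].nunique(),
                abundance=abundance,
                mean_map_ratio=float(
                    (grp["abundance"] * grp["map_ratio"]).sum() / abundance
                ),
                nearest_taxon=db.edge_label(int(edge_id)),
                predominant_environment=env_order[0][0],
            )
        )
    records.sort(key=lambda r: (-r.abundance, r.edge_id))
    return records[:k]


def dark_edges_frame(records: Sequence[DarkEdgeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "edge_id": r.edge_id,
                "unique_reads": r.n_unique_reads,
                "abundance": r.abundance,
                "mean_map_ratio": r.mean_map_ratio,
                "nearest_taxon": r.nearest_taxon,
                "predominant_environment": r.predominant_environment,
            }
            for r in records
        ],
        columns=[
            "edge_id",
            "unique_reads",
            "abundance",
            "mean_map_ratio",
            "nearest_taxon",
            "predominant_environment",
        ],
    )


# ----------------------------------------------------------------------
# rarefaction


def rarefaction(
    counts: Sequence[int], depths: Sequence[int]
) -> RarefactionCurve:
    """Analytic rarefaction: expected richness under subsampling.

    For total reads ``N`` distributed over uniques with counts ``N_i``,
    the expected number of uniques in a uniform without-replacement
    subsample of size ``n`` is ``E[S(n)] = sum_i 1 - C(N-N_i, n)/C(N, n)``
    (hypergeometric expectation), evaluated in log space for stability.
    The curve is non-decreasing and reaches the observed richness at
    full depth.
    """
    counts_arr = np.asarray([c for c in counts if c > 0], dtype=np.int64)
    if counts_arr.size == 0:
        raise ValueError("no nonzero counts")
    n_total = int(counts_arr.sum())
    values = []
    for n in depths:
        if n < 1 or n > n_total:
            raise ValueError(f"depth {n} outside [1, {n_total}]")
        miss = np.zeros(counts_arr.size)
        rest = n_total - counts_arr  # reads not in unique i
        ok = rest >= n  # else C(rest, n) = 0: unique i always seen
        r = rest[ok]
        log_miss = (
            gammaln(r + 1)
            - gammaln(r - n + 1)
            - gammaln(n_total + 1)
            + gammaln(n_total - n + 1)
        )
        miss[ok] = np.exp(log_miss)
        values.append(float(np.sum(1.0 - miss)))
    return RarefactionCurve(
        depths=tuple(int(n) for n in depths),
        expected_uniques=tuple(values),
    )


def default_depths(n_total: int, n_points: int = 20) -> list[int]:
    """Log-spaced depths from 1 to the full read count."""
    if n_total < 1:
        raise ValueError("need at least one read")
    pts = np.unique(
        np.round(np.logspace(0, np.log10(n_total), n_points)).astype(int)
    )
    return [int(p) for p in pts]


def rarefaction_frame(
    uniques: Sequence[UniqueRead],
    sample_env: Mapping[str, str],
    domain: str,
    n_points: int = 20,
) -> pd.DataFrame:
    """Per-environment rarefaction curves for one domain."""
    env_counts: dict[str, dict[str, int]] = {}
    for u in uniques:
        if u.domain != domain:
            continue
        for sample, n in u.counts.items():
            env = sample_env.get(sample, "unknown")
            per_uid = env_counts.setdefault(env, {})
            per_uid[u.uid] = per_uid.get(u.uid, 0) + n
    rows = []
    for env in sorted(env_counts):
        counts = [n for n in env_counts[env].values() if n > 0]
        total = sum(counts)
        if total == 0:
            continue
        curve = rarefaction(counts, default_depths(total, n_points))
        for d, v in zip(curve.depths, curve.expected_uniques):
            rows.append(
                {"environment": env, "domain": domain, "depth": d, "expected_uniques": v}
            )
    return pd.DataFrame(
        rows, columns=["environment", "domain", "depth", "expected_uniques"]
    )


# ----------------------------------------------------------------------
# richness vs sampling effort


@dataclass(frozen=True)
class EffortFit:
    r_squared: float
    p_value: float
    slope: float
    intercept: float
    residuals: tuple[float, ...]


def unique_vs_samples_fit(
    n_samples: Sequence[int], n_uniques: Sequence[int]
) -> EffortFit:
    """Least-squares fit of unique-read richness on sample count.

    One point per environment.  Returns the Pearson r², two-sided
    p-value (t distribution), the fitted line, and residuals so that
    environments more diverse than sampling effort predicts can be
    listed.
    """
    x = np.asarray(n_samples, dtype=float)
    y = np.asarray(n_uniques, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 environments")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero variance in inputs")
    res = stats.linregress(x, y)
    fitted = res.slope * x + res.intercept
    return EffortFit(
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        slope=float(res.slope),
        intercept=float(res.intercept),
        residuals=tuple(float(v) for v in (y - fitted)),
    )


# ----------------------------------------------------------------------
# per-environment roll-up


def percent_reduction(raw: float, normalized: float) -> float:
    """Percent of reads removed by copy-number normalization."""
    if raw <= 0:
        raise ValueError("raw total must be positive")
    return 100.0 * (1.0 - normalized / raw)


def env_summary(
    uniques: Sequence[UniqueRead],
    sample_env: Mapping[str, str],
    db: ReferenceDB,
) -> pd.DataFrame:
    """Per-environment survey roll-up.

    Columns per domain: final (placed) reads, copy-number-normalized
    reads, unique reads, and read-weighted mean map ratio; plus the
    sample count.  Final reads sum across environments to the
    pipeline's total placed reads.
    """
    env_samples: dict[str, set[str]] = {}
    for sample, env in sample_env.items():
        env_samples.setdefault(env, set()).add(sample)
    acc: dict[tuple[str, str], dict] = {}
    seen_uniques: dict[tuple[str, str], set[str]] = {}
    for u in uniques:
        if u.placement is None or u.domain == "unassigned":
            continue
        norm_factor = db.edge_copy[u.placement.edge_id]
        for sample, n in u.counts.items():
            if n == 0:
                continue
            env = sample_env.get(sample, "unknown")
            key = (env, u.domain)
            a = acc.setdefault(
                key, {"reads": 0, "norm": 0.0, "ratio_w": 0.0}
            )
            a["reads"] += n
            a["norm"] += n / norm_factor
            a["ratio_w"] += n * u.placement.map_ratio
            seen_uniques.setdefault(key, set()).add(u.uid)
    rows = []
    for env in sorted(env_samples):
        row = {"environment": env, "n_samples": len(env_samples[env])}
        for domain in ("Bacteria", "Archaea"):
            a = acc.get((env, domain))
            suffix = domain.lower()
            if a is None:
                row[f"final_reads_{suffix}"] = 0
                row[f"normalized_reads_{suffix}"] = 0.0
                row[f"unique_reads_{suffix}"] = 0
                row[f"mean_map_ratio_{suffix}"] = float("nan")
            else:
                row[f"final_reads_{suffix}"] = a["reads"]
                row[f"normalized_reads_{suffix}"] = a["norm"]
                row[f"unique_reads_{suffix}"] = len(seen_uniques[(env, domain)])
                row[f"mean_map_ratio_{suffix}"] = a["ratio_w"] / a["reads"]
        rows.append(row)
    return pd.DataFrame(rows)
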