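"""Run configuration shared by every pipeline stage.

All thresholds live in one :class:`Config` object so that a single TOML
file (or a single set of CLI flags) fully determines a run.  Defaults
follow the conventions of Illumina 16S rRNA amplicon surveys: trim at the
first base below Q20, discard reads shorter than 75 nt, flag samples with
more than 1,000 domain-assigned reads whose mean map ratio falls below
0.8, and flag unique reads whose map ratio falls below
``0.075 * log10(abundance) + 0.4``.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

#: The ten consensus environment labels used for per-environment roll-ups.
CONSENSUS_ENVIRONMENTS = (
    "cryoconite",
    "glacial ice",
    "lake",
    "lake ice",
    "sea ice",
    "seawater",
    "sediment",
    "snow",
    "soil",
    "subglacial lake",
)

#: Metadata labels collapsed onto a consensus environment.  Freshwater,
#: hypersaline and marine sediments are indistinguishable in much run
#: metadata, so every sediment variant maps to plain "sediment".
DEFAULT_ENV_ALIASES = {
    "marine sediment": "sediment",
    "lake sediment": "sediment",
    "hypersaline lake sediment": "sediment",
    "freshwater sediment": "sediment",
    "glacier": "glacial ice",
    "glacier ice": "glacial ice",
    "sea water": "seawater",
    "marine": "seawater",
    "lake water": "lake",
}


@dataclass
class Config:
    """All tunable thresholds for a darkmeter run.

    Parameters
    ----------
    q_min:
        Phred score threshold; reads are truncated at the first base with
        a score strictly below this value.
    len_min:
        Minimum read length (nt) retained after quality trimming.
    min_reads_flag:
        A sample enters the mean-map-ratio distribution (and may be
        flagged) only with *more than* this many domain-assigned reads.
    mean_ratio_flag:
        Samples above the read floor with a mean map ratio below this
        value are flagged for inspection.
    dark_slope, dark_intercept:
        Coefficients of the dark-read rule: a unique read is dark when
        ``map_ratio < dark_slope * log10(abundance) + dark_intercept``.
    match, mismatch, gap_open, gap_extend:
        Semi-global alignment scores (reference terminal overhangs free).
    kmer_size:
        k for the shared-k-mer prefilter in nearest-reference search.
    kmer_tier:
        Candidates whose shared-k-mer count is at least ``kmer_tier``
        times the best count are aligned exactly.
    kmer_min_signal:
        When the best shared-k-mer count falls below this, the k-mer
        ranking is no better than chance and every reference is aligned
        instead, so the prefilter never changes the result.
    domain_cutoff:
        Minimum best panel alignment score, as a fraction of the read's
        maximum attainable score, for a domain call.
    dark_abundance_scope:
        "environment" tallies unique-read abundance within each consensus
        environment before applying the dark-read rule; "global" tallies
        across the whole dataset.
    seed:
        Master RNG seed; stages derive sub-seeds from it.
    """

    q_min: int = 20
    len_min: int = 75
    min_reads_flag: int = 1000
    mean_ratio_flag: float = 0.8
    dark_slope: float = 0.075
    dark_intercept: float = 0.4
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0
    kmer_size: int = 8
    kmer_tier: float = 0.9
    kmer_min_signal: int = 20
    domain_cutoff: float = 0.5
    collapse: bool = True
    collapse_max_mismatch: int = 1
    dark_abundance_scope: str = "environment"
    seed: int = 1
    env_aliases: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_ENV_ALIASES)
    )

    def __post_init__(self) -> None:
        if self.q_min <= 0 or self.len_min <= 0 or self.min_reads_flag <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.mean_ratio_flag <= 1:
            raise ValueError("mean_ratio_flag must be in (0, 1]")
        if self.dark_abundance_scope not in ("environment", "global"):
            raise ValueError(
                "dark_abundance_scope must be 'environment' or 'global'"
            )

    @classmethod
    def from_toml(cls, path: str | Path) -> "Config":
        """Load a configuration from a TOML file.

        Unknown keys raise, so typos in config files fail loudly.
        """
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        aliases = dict(DEFAULT_ENV_ALIASES)
        aliases.update(raw.pop("env_aliases", {}))
        return cls(env_aliases=aliases, **raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
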