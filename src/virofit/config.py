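"""Pipeline configuration.

All thresholds that drive the analysis live in one dataclass with the
defaults used throughout: a BLAST e-value ceiling of 1e-5 keeping the top
25 hits per contig, a 500 nt minimum contig length, the 60% query-coverage
boundary separating confidently annotated taxa from largely novel
sequences, the 75% genome-identity species demarcation used for
circoviruses, and a 10% top-score window for LCA membership.

Configuration files are plain ``key = value`` text; every key is optional
and falls back to the default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

from .errors import FormatError


@dataclass
class ScoringScheme:
    """Nucleotide alignment scoring (megablast-like defaults)."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0

    def validate(self) -> None:
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("mismatch and gap penalties must be negative")


@dataclass
class PipelineConfig:
    """Tunable thresholds of the annotation pipeline.

    Parameters
    ----------
    evalue_max : float
        Maximum e-value for a hit to be retained.
    top_hits : int
        Number of hits kept per query, ranked by bitscore.
    min_contig_len : int
        Contigs shorter than this (nt) are dropped before annotation.
    coverage_boundary : float
        Query-coverage percentage separating high-confidence calls
        (strictly above) from novel calls (at or below).
    demarcation_identity : float
        Genome-wide nucleotide identity (%) below which two genomes are
        called distinct species.
    min_terminal_repeat : int
        Minimum exact terminal direct repeat (nt) accepted as evidence of
        a circular genome.
    lca_score_window : float
        Fraction of the top bitscore within which hits participate in the
        lowest-common-ancestor vote (0.10 keeps hits scoring at least 90%
        of the best).
    related_rank : str
        Rank at or below which a best hit counts as "taxonomically
        related" to the truth in the calibration experiment.
    rng_seed : int
        Seed for every stochastic component.
    """

    evalue_max: float = 1e-5
    top_hits: int = 25
    min_contig_len: int = 500
    coverage_boundary: float = 60.0
    demarcation_identity: float = 75.0
    min_terminal_repeat: int = 20
    lca_score_window: float = 0.10
    related_rank: str = "family"
    rng_seed: int = 0
    scoring: ScoringScheme = dataclasses.field(default_factory=ScoringScheme)

    def __post_init__(self) -> None:
        for name in ("coverage_boundary", "demarcation_identity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100], got {v}")
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")
        if self.top_hits < 1:
            raise ValueError("top_hits must be >= 1")
        if not 0.0 <= self.lca_score_window <= 1.0:
            raise ValueError("lca_score_window must lie in [0, 1]")
        self.scoring.validate()


_SCORING_KEYS = {"match", "mismatch", "gap_open", "gap_extend"}
_INT_KEYS = {"top_hits", "min_contig_len", "min_terminal_repeat", "rng_seed"}
_STR_KEYS = {"related_rank"}


def load_config(path: str | Path) -> PipelineConfig:
    """Read a ``key = value`` config file; unknown keys are an error."""
    known = {f.name for f in dataclasses.fields(PipelineConfig)} - {"scoring"}
    kwargs: dict = {}
    scoring_kwargs: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        try:
            if key in _SCORING_KEYS:
                scoring_kwargs[key] = float(value)
            elif key in _INT_KEYS:
                kwargs[key] = int(value)
            elif key in _STR_KEYS:
                kwargs[key] = value
            elif key in known:
                kwargs[key] = float(value)
            else:
                raise FormatError(f"{path}:{lineno}: unknown key {key!r}")
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: bad value for {key}: {exc}")
    return PipelineConfig(scoring=ScoringScheme(**scoring_kwargs), **kwargs)


def dump_config(config: PipelineConfig) -> str:
    """Serialise a config back to the ``key = value`` dialect."""
    lines = []
    for f in dataclasses.fields(PipelineConfig):
        if f.name == "scoring":
            continue
        lines.append(f"{f.name} = {getattr(config, f.name)}")
    for f in dataclasses.fields(ScoringScheme):
        lines.append(f"{f.name} = {getattr(config.scoring, f.name)}")
    return "\n".join(lines) + "\n"
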