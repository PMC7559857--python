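"""Genome-level procedures for small circular DNA viruses.

Three tools used when a contig looks like a complete CRESS-DNA-style
genome: detection of circularity via an exact terminal direct repeat
(an assembler reads "through" a circular genome, leaving the first k
nucleotides duplicated at the end of the contig); genome-wide pairwise
nucleotide identity against a reference with the <75% circovirus species
demarcation; and in-silico PCR over primer pairs, supporting circular
templates whose products wrap the origin.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio.Seq import Seq

from .align import LabeledSequence, global_align_identity
from .config import PipelineConfig, ScoringScheme
from .errors import FormatError

_VALID = re.compile(r"^[ACGT]+$")


@dataclass(frozen=True)
class CircularityCall:
    contig_id: str
    is_circular: bool
    overlap_length: int
    trimmed_length: int
    trimmed_sequence: str


def detect_circularity(
    contig: LabeledSequence, min_overlap: int = 20
) -> CircularityCall:
    """Detect a terminal direct repeat and trim it.

    Finds the longest k < len/2 with ``prefix(k) == suffix(k)`` (the
    repeat may not overlap itself).  If k >= ``min_overlap`` the contig
    is called circular and the duplicated suffix removed, leaving one
    copy of the repeat at the 5' end; re-appending ``prefix(k)`` to the
    trimmed sequence reproduces the input.
    """
    s = contig.sequence
    n = len(s)
    if n <= 2 * min_overlap:
        raise ValueError(
            f"{contig.seq_id}: contig length {n} must exceed twice the "
            f"minimum overlap ({min_overlap})"
        )
    best = 0
    for k in range((n - 1) // 2, min_overlap - 1, -1):
        if s[:k] == s[n - k :]:
            best = k
            break
    if best >= min_overlap:
        return CircularityCall(
            contig_id=contig.seq_id,
            is_circular=True,
            overlap_length=best,
            trimmed_length=n - best,
            trimmed_sequence=s[: n - best],
        )
    return CircularityCall(contig.seq_id, False, 0, n, s)


def _anchor_rotation(a: str, b: str, k: int = 15) -> int:
    """Offset rotating ``a`` into register with ``b``, by k-mer vote.

    Every exact k-mer shared between the two sequences votes for the
    rotation offset that would superpose its occurrences; the most
    common offset wins (0 when nothing is shared).
    """
    index: dict[str, list[int]] = {}
    for i in range(len(b) - k + 1):
        index.setdefault(b[i : i + k], []).append(i)
    votes: Counter[int] = Counter()
    for i in range(len(a) - k + 1):
        for j in index.get(a[i : i + k], ()):
            votes[(i - j) % len(a)] += 1
    if not votes:
        return 0
    # deterministic tie-break: highest vote, then smallest offset
    return min(votes, key=lambda off: (-votes[off], off))


def genome_identity(
    a: LabeledSequence,
    b: LabeledSequence,
    circular: bool = False,
    scoring: ScoringScheme | None = None,
    anchor_k: int = 15,
    exhaustive_rotation: bool = False,
) -> float:
    """Genome-wide nucleotide identity (%) by global alignment.

    For circular genomes the register of ``a`` relative to ``b`` is
    arbitrary, so ``a`` is first rotated: by default to the offset that
    the most shared ``anchor_k``-mers agree on; with
    ``exhaustive_rotation`` every rotation is aligned and the best
    identity returned (quadratic — small genomes only).
    """
    if not circular:
        # traceback choice among co-optimal alignments is direction
        # dependent; fix the orientation so identity is symmetric
        x, y = sorted((a.sequence, b.sequence))
        return global_align_identity(x, y, scoring)
    if exhaustive_rotation:
        return max(
            global_align_identity(
                a.sequence[i:] + a.sequence[:i], b.sequence, scoring
            )
            for i in range(len(a.sequence))
        )
    off = _anchor_rotation(a.sequence, b.sequence, anchor_k)
    rotated = a.sequence[off:] + a.sequence[:off]
    return global_align_identity(rotated, b.sequence, scoring)


@dataclass(frozen=True)
class DemarcationCall:
    pair: tuple[str, str]
    identity: float
    verdict: str  # "novel_species" | "variant"


def demarcate(
    identity: float,
    config: PipelineConfig | None = None,
    pair: tuple[str, str] = ("", ""),
) -> DemarcationCall:
    """Apply the species-demarcation rule: identity < threshold (default
    75%, strict) means a distinct species; at or above, a variant of the
    reference species."""
    config = config or PipelineConfig()
    if not 0.0 <= identity <= 100.0:
        raise ValueError("identity must lie in [0, 100]")
    verdict = "novel_species" if identity < config.demarcation_identity else "variant"
    return DemarcationCall(pair, identity, verdict)


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward: str
    reverse: str
    max_amplicon: int

    def __post_init__(self) -> None:
        for label, p in (("forward", self.forward), ("reverse", self.reverse)):
            if not p or not _VALID.match(p):
                raise ValueError(f"{self.name}: invalid {label} primer {p!r}")
        if self.max_amplicon < len(self.forward) + len(self.reverse):
            raise ValueError(f"{self.name}: max_amplicon shorter than primers")


def load_primers(path: str | Path) -> list[PrimerPair]:
    """Primers TSV: name, forward, reverse, max_amplicon."""
    df = pd.read_csv(path, sep="\t")
    required = {"name", "forward", "reverse", "max_amplicon"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    return [
        PrimerPair(str(r.name), str(r.forward).upper(), str(r.reverse).upper(),
                   int(r.max_amplicon))
        for r in df.itertuples()
    ]


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def insilico_pcr(
    template: LabeledSequence, primers: PrimerPair, circular: bool = False
) -> list[int]:
    """Predicted amplicon lengths for exact-match primer binding.

    The forward primer binds the plus strand; the reverse primer binds
    the minus strand, i.e. its reverse complement appears downstream on
    the plus strand within ``max_amplicon``.  Amplicon length runs from
    the forward primer's 5' end to the reverse primer's 5' end,
    inclusive.  Circular templates wrap across the origin.  Returns a
    sorted list (empty when there is no product).
    """
    seq = template.sequence
    n = len(seq)
    rv_rc = str(Seq(primers.reverse).reverse_complement())
    search_space = seq + seq[: min(primers.max_amplicon, n)] if circular else seq
    fw_sites = [p for p in _find_all(search_space, primers.forward) if p < n]
    rv_sites = _find_all(search_space, rv_rc)
    products = set()
    for f in fw_sites:
        for r in rv_sites:
            end = r + len(rv_rc)  # one past the reverse primer's 5' end
            length = end - f
            if len(primers.forward) + len(primers.reverse) <= length <= primers.max_amplicon:
                products.add(length)
    return sorted(products)
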