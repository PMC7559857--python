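"""Pairwise nucleotide alignment and exhaustive database search.

This is the BLAST stand-in used for the mutation-calibration experiment
and for generating synthetic hit tables: optimal local (Smith-Waterman
semantics) and global alignment with affine gaps, driven by
``Bio.Align.PairwiseAligner``.  Identity is computed over aligned columns
(gaps count as columns) and coverage as the aligned query span over the
query length, matching the BLAST tabular conventions consumed upstream.

Database search is exhaustive by default — appropriate at desk scale —
with an optional shared-k-mer prescreen that skips subjects sharing no
exact k-mer with the query (BLAST-like seeding) for larger synthetic
databases.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import ScoringScheme
from .errors import FormatError

_VALID = re.compile(r"^[ACGT]+$")

# Karlin-Altschul-style parameters used to synthesise bitscores and
# e-values from raw scores for the generated hit tables.  The values are
# nominal (blastn-like); only monotonicity matters downstream.
_KA_LAMBDA = 0.625
_KA_K = 0.41


@dataclass(frozen=True)
class LabeledSequence:
    """A nucleotide sequence tagged with its source taxon."""

    seq_id: str
    tax_id: int
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.seq_id}: empty sequence")
        if not _VALID.match(self.sequence):
            bad = sorted(set(self.sequence) - set("ACGT"))
            raise ValueError(
                f"{self.seq_id}: sequence contains characters outside "
                f"A/C/G/T (ambiguity codes are not accepted): {bad}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentResult:
    """Summary of one local alignment (query vs one subject)."""

    query_id: str
    subject_id: str
    subject_taxid: int
    score: float
    identity: float          # % identical over aligned columns
    query_coverage: float    # % of query inside the aligned span
    q_span: tuple[int, int]  # 1-based inclusive; (0, 0) for empty alignment
    s_span: tuple[int, int]
    aligned_columns: int = 0
    mismatches: int = 0
    gap_opens: int = 0

    @property
    def bitscore(self) -> float:
        return (_KA_LAMBDA * self.score - math.log(_KA_K)) / math.log(2.0)

    def evalue(self, query_length: int, db_length: int) -> float:
        return query_length * db_length * 2.0 ** (-self.bitscore)


def _aligner(scoring: ScoringScheme, mode: str) -> Align.PairwiseAligner:
    scoring.validate()
    return Align.PairwiseAligner(
        mode=mode,
        match_score=scoring.match,
        mismatch_score=scoring.mismatch,
        open_gap_score=scoring.gap_open,
        extend_gap_score=scoring.gap_extend,
    )


def local_align(
    query: LabeledSequence,
    subject: LabeledSequence,
    scoring: ScoringScheme | None = None,
) -> AlignmentResult:
    """Optimal local alignment of ``query`` against ``subject``.

    Returns an empty result (score 0, 0% identity and coverage) when no
    positively scoring path exists, e.g. for disjoint alphabets.
    """
    scoring = scoring or ScoringScheme()
    aligner = _aligner(scoring, "local")
    score = aligner.score(query.sequence, subject.sequence)
    if score <= 0:
        return AlignmentResult(
            query.seq_id, subject.seq_id, subject.tax_id,
            0.0, 0.0, 0.0, (0, 0), (0, 0),
        )
    aln = aligner.align(query.sequence, subject.sequence)[0]
    return _summarise(query, subject, aln, float(score))


def _summarise(query, subject, aln, score) -> AlignmentResult:
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    segments_q, segments_s = aln.aligned
    q_lo = int(segments_q[0][0]) + 1
    q_hi = int(segments_q[-1][-1])
    s_lo = int(segments_s[0][0]) + 1
    s_hi = int(segments_s[-1][-1])
    gap_opens = max(0, len(segments_q) - 1)
    return AlignmentResult(
        query_id=query.seq_id,
        subject_id=subject.seq_id,
        subject_taxid=subject.tax_id,
        score=score,
        identity=100.0 * counts.identities / columns if columns else 0.0,
        query_coverage=100.0 * (q_hi - q_lo + 1) / len(query),
        q_span=(q_lo, q_hi),
        s_span=(s_lo, s_hi),
        aligned_columns=columns,
        mismatches=counts.mismatches,
        gap_opens=gap_opens,
    )


def global_align_identity(
    a: str,
    b: str,
    scoring: ScoringScheme | None = None,
) -> float:
    """Global (Needleman-Wunsch) identity: matches / alignment columns x 100."""
    scoring = scoring or ScoringScheme()
    aligner = _aligner(scoring, "global")
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return 100.0 * counts.identities / columns


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def build_kmer_index(db: Sequence[LabeledSequence], k: int) -> dict[str, set[int]]:
    """k-mer -> indices of database subjects containing it (prescreen index)."""
    index: dict[str, set[int]] = {}
    for i, subject in enumerate(db):
        for kmer in _kmer_set(subject.sequence, k):
            index.setdefault(kmer, set()).add(i)
    return index


def search_database(
    query: LabeledSequence,
    db: Sequence[LabeledSequence],
    scoring: ScoringScheme | None = None,
    top_n: int = 25,
    seed_kmer: int | None = None,
    db_index: dict[str, set[int]] | None = None,
) -> list[AlignmentResult]:
    """Rank database subjects by optimal local alignment score.

    Results are sorted by descending score (ties by subject_id) and
    truncated to ``top_n``; zero-scoring subjects are omitted.  With
    ``seed_kmer`` set, subjects sharing no exact k-mer with the query are
    skipped without alignment; a precomputed :func:`build_kmer_index`
    avoids rescanning subjects for repeated queries.
    """
    if not db:
        raise ValueError("database is empty")
    scoring = scoring or ScoringScheme()
    aligner = _aligner(scoring, "local")
    if seed_kmer:
        query_kmers = _kmer_set(query.sequence, seed_kmer)
        if db_index is not None:
            candidate_ix: set[int] = set()
            for kmer in query_kmers:
                candidate_ix |= db_index.get(kmer, set())
            candidates = [db[i] for i in sorted(candidate_ix)]
        else:
            candidates = [
                s
                for s in db
                if any(
                    s.sequence[i : i + seed_kmer] in query_kmers
                    for i in range(len(s.sequence) - seed_kmer + 1)
                )
            ]
    else:
        candidates = list(db)

    scored: list[tuple[float, LabeledSequence]] = []
    for subject in candidates:
        s = aligner.score(query.sequence, subject.sequence)
        if s > 0:
            scored.append((float(s), subject))
    scored.sort(key=lambda t: (-t[0], t[1].seq_id))

    results = []
    for score, subject in scored[:top_n]:
        aln = aligner.align(query.sequence, subject.sequence)[0]
        results.append(_summarise(query, subject, aln, score))
    return results


# ---------------------------------------------------------------------------
# FASTA I/O with the ">seq_id|tax_id" labelling convention

def read_labeled_fasta(path: str | Path) -> list[LabeledSequence]:
    """Read FASTA whose headers follow ``>seq_id|tax_id``."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise FormatError(f"{path}: header {rec.id!r} lacks '|tax_id' suffix")
        seq_id, _, taxid = rec.id.rpartition("|")
        try:
            tax_id = int(taxid)
        except ValueError:
            raise FormatError(f"{path}: non-integer tax_id in header {rec.id!r}")
        out.append(LabeledSequence(seq_id, tax_id, str(rec.seq).upper()))
    return out


def write_labeled_fasta(
    seqs: Iterable[LabeledSequence], path: str | Path, descriptions: dict | None = None
) -> None:
    descriptions = descriptions or {}
    records = [
        SeqRecord(
            Seq(s.sequence),
            id=f"{s.seq_id}|{s.tax_id}",
            description=descriptions.get(s.seq_id, ""),
        )
        for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")
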