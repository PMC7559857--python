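"""Tabular homology-hit ingestion, filtering and per-taxon clustering.

Hits arrive as BLAST tabular (outfmt 6) TSV — ``qseqid sseqid pident
length mismatch gapopen qstart qend sstart send evalue bitscore`` —
optionally extended with ``qlen`` and ``staxid`` columns, or accompanied
by sidecar TSVs mapping query ids to lengths and subject ids to taxa.

Filtering applies the pipeline's retention rules: an e-value ceiling
(default 1e-5), the top 25 hits per query by bitscore, a minimum contig
length of 500 nt, and removal of hits to subjects seen in the no-template
control or matching vector/plasmid sequences.  Queries assigned to the
same taxon are then clustered, with unweighted mean percent identity and
mean query coverage summarising each cluster.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import FormatError
from .taxonomy import TaxonomyTree

log = logging.getLogger(__name__)

#: Standard BLAST outfmt-6 column order.
OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]
EXTENDED_COLUMNS = OUTFMT6_COLUMNS + ["qlen", "staxid"]


@dataclass(frozen=True)
class HitRecord:
    """One query-subject local alignment summary (one BLAST table row)."""

    query_id: str
    query_length: int
    subject_id: str
    subject_taxid: int
    percent_identity: float
    align_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def validate(self) -> None:
        if not 1 <= self.q_start <= self.q_end <= self.query_length:
            raise ValueError(
                f"{self.query_id}: bad query span "
                f"{self.q_start}-{self.q_end} on length {self.query_length}"
            )
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(f"{self.query_id}: identity outside [0,100]")
        if self.evalue < 0:
            raise ValueError(f"{self.query_id}: negative e-value")


def query_coverage(hit: HitRecord) -> float:
    """Percentage of the query spanned by the aligned segment."""
    return 100.0 * (hit.q_end - hit.q_start + 1) / hit.query_length


@dataclass
class ExclusionSet:
    """Subjects and taxa excluded from (or flagged in) the analysis.

    ``control_subjects`` are subject ids observed in the no-template
    control; ``vector_subjects`` and ``plasmid_subjects`` match cloning
    artefacts.  ``broad_category_taxa`` (e.g. "uncultured virus") are
    *flagged*, not dropped: richness summaries exclude them by default
    while the confidence analysis retains them.
    """

    control_subjects: set[str] = field(default_factory=set)
    vector_subjects: set[str] = field(default_factory=set)
    plasmid_subjects: set[str] = field(default_factory=set)
    broad_category_taxa: set[int] = field(default_factory=set)

    @property
    def excluded_subjects(self) -> set[str]:
        return self.control_subjects | self.vector_subjects | self.plasmid_subjects

    @classmethod
    def from_control_table(
        cls, hits: Iterable[HitRecord], broad_category_taxa: set[int] | None = None
    ) -> "ExclusionSet":
        """Build an exclusion set from the hits of a no-template control."""
        return cls(
            control_subjects={h.subject_id for h in hits},
            broad_category_taxa=set(broad_category_taxa or ()),
        )


def read_hit_table(
    path: str | Path,
    query_lengths: Mapping[str, int] | str | Path | None = None,
    subject_taxa: Mapping[str, int] | str | Path | None = None,
) -> list[HitRecord]:
    """Parse a BLAST outfmt-6 TSV into :class:`HitRecord` rows.

    The table may carry ``qlen``/``staxid`` as 13th/14th columns; if not,
    both must be supplied via sidecar mappings or sidecar TSV paths
    (``query_id\tlength`` and ``subject_id\ttax_id``).  Rows violating the
    record invariants are dropped and logged with their line numbers.
    """
    qlen_map = _load_sidecar(query_lengths, "query_id", "length")
    taxid_map = _load_sidecar(subject_taxa, "subject_id", "tax_id")

    with open(path) as fh:
        first = fh.readline()
    if not first:
        return []
    ncols = len(first.rstrip("\n").split("\t"))
    has_header = first.split("\t")[0].strip() in ("qseqid", "query_id")
    if ncols == 12:
        names = OUTFMT6_COLUMNS
    elif ncols == 14:
        names = EXTENDED_COLUMNS
    else:
        raise FormatError(f"{path}: expected 12 or 14 columns, found {ncols}")
    df = pd.read_csv(
        path, sep="\t", names=names, header=0 if has_header else None, dtype=str
    )

    records: list[HitRecord] = []
    bad_rows: list[int] = []
    for lineno, row in enumerate(df.itertuples(index=False), 2 if has_header else 1):
        try:
            qid, sid = str(row.qseqid), str(row.sseqid)
            if ncols == 14:
                qlen, staxid = int(row.qlen), int(row.staxid)
            else:
                qlen, staxid = int(qlen_map[qid]), int(taxid_map[sid])
            rec = HitRecord(
                query_id=qid,
                query_length=qlen,
                subject_id=sid,
                subject_taxid=staxid,
                percent_identity=float(row.pident),
                align_length=int(row.length),
                mismatches=int(row.mismatch),
                gap_opens=int(row.gapopen),
                q_start=int(row.qstart),
                q_end=int(row.qend),
                s_start=int(row.sstart),
                s_end=int(row.send),
                evalue=float(row.evalue),
                bitscore=float(row.bitscore),
            )
            rec.validate()
        except KeyError as exc:
            raise FormatError(
                f"{path}: line {lineno}: no sidecar entry for {exc.args[0]!r}"
            ) from exc
        except (ValueError, TypeError) as exc:
            bad_rows.append(lineno)
            log.warning("%s: line %d rejected: %s", path, lineno, exc)
            continue
        records.append(rec)
    if bad_rows:
        log.warning("%s: %d invalid rows rejected", path, len(bad_rows))
    return records


def write_hit_table(records: Iterable[HitRecord], path: str | Path) -> None:
    """Write records as an extended (14-column, headered) hit TSV."""
    rows = [
        (
            r.query_id, r.subject_id, r.percent_identity, r.align_length,
            r.mismatches, r.gap_opens, r.q_start, r.q_end, r.s_start,
            r.s_end, r.evalue, r.bitscore, r.query_length, r.subject_taxid,
        )
        for r in records
    ]
    pd.DataFrame(rows, columns=EXTENDED_COLUMNS).to_csv(path, sep="\t", index=False)


def _load_sidecar(source, key_col, val_col):
    if source is None:
        return {}
    if isinstance(source, (str, Path)):
        df = pd.read_csv(source, sep="\t")
        if not {key_col, val_col} <= set(df.columns):
            raise FormatError(f"{source}: expected columns {key_col}, {val_col}")
        return dict(zip(df[key_col].astype(str), df[val_col].astype(int)))
    return source


def filter_hits(
    hits: Sequence[HitRecord],
    exclusions: ExclusionSet | None = None,
    config: PipelineConfig | None = None,
) -> list[HitRecord]:
    """Apply the retention rules; idempotent by construction.

    Order of operations: drop short queries, drop hits above the e-value
    ceiling, drop hits to excluded subjects, then keep the top
    ``config.top_hits`` per query by bitscore (ties broken by subject_id
    for determinism).  Removal counts per category are logged.
    """
    config = config or PipelineConfig()
    exclusions = exclusions or ExclusionSet()
    excluded_subjects = exclusions.excluded_subjects

    n_short = n_evalue = n_excluded = n_overflow = 0
    per_query: dict[str, list[HitRecord]] = defaultdict(list)
    for h in hits:
        if h.query_length < config.min_contig_len:
            n_short += 1
            continue
        if h.evalue > config.evalue_max:
            n_evalue += 1
            continue
        if h.subject_id in excluded_subjects:
            n_excluded += 1
            continue
        per_query[h.query_id].append(h)

    kept: list[HitRecord] = []
    for qid in sorted(per_query):
        ranked = sorted(per_query[qid], key=lambda h: (-h.bitscore, h.subject_id))
        n_overflow += max(0, len(ranked) - config.top_hits)
        kept.extend(ranked[: config.top_hits])
    log.info(
        "filter_hits: kept %d; removed %d short-query, %d e-value, "
        "%d excluded-subject, %d beyond top-%d",
        len(kept), n_short, n_evalue, n_excluded, n_overflow, config.top_hits,
    )
    return kept


@dataclass
class TaxonCluster:
    """Aggregate of all queries assigned to one taxon."""

    tax_id: int
    member_queries: set[str]
    mean_identity: float
    mean_query_coverage: float
    n_contigs: int
    per_subject_breakdown: dict[str, tuple[float, float]]
    broad_category: bool = False

    def __post_init__(self) -> None:
        if self.n_contigs != len(self.member_queries) or self.n_contigs < 1:
            raise ValueError("n_contigs must equal |member_queries| >= 1")


def cluster_by_taxon(
    best_hits: Mapping[str, tuple[HitRecord, int]],
    exclusions: ExclusionSet | None = None,
) -> list[TaxonCluster]:
    """Cluster per-query assignments by taxon.

    ``best_hits`` maps each query id to its representative hit and
    assigned tax_id.  Cluster means are unweighted arithmetic means over
    member queries; when members hit different subject sequences sharing
    the taxon, a per-subject breakdown of mean identity/coverage is kept.
    """
    broad = exclusions.broad_category_taxa if exclusions else set()
    groups: dict[int, list[tuple[str, HitRecord]]] = defaultdict(list)
    for qid, (hit, tax_id) in best_hits.items():
        groups[tax_id].append((qid, hit))

    clusters = []
    for tax_id in sorted(groups):
        members = groups[tax_id]
        idents = np.array([h.percent_identity for _, h in members])
        covs = np.array([query_coverage(h) for _, h in members])
        by_subject: dict[str, list[int]] = defaultdict(list)
        for i, (_, h) in enumerate(members):
            by_subject[h.subject_id].append(i)
        breakdown = {
            sid: (float(idents[ix].mean()), float(covs[ix].mean()))
            for sid, ix in by_subject.items()
        }
        clusters.append(
            TaxonCluster(
                tax_id=tax_id,
                member_queries={qid for qid, _ in members},
                mean_identity=float(idents.mean()),
                mean_query_coverage=float(covs.mean()),
                n_contigs=len(members),
                per_subject_breakdown=breakdown,
                broad_category=tax_id in broad,
            )
        )
    return clusters


def clusters_to_frame(
    clusters: Sequence[TaxonCluster], tree: TaxonomyTree | None = None
) -> pd.DataFrame:
    """Tabular cluster summary (tax_id, name, n_contigs, means, flags)."""
    rows = []
    for c in clusters:
        name = tree.name(c.tax_id) if tree and c.tax_id in tree else ""
        rows.append(
            (c.tax_id, name, c.n_contigs, c.mean_identity,
             c.mean_query_coverage, "broad" if c.broad_category else "")
        )
    return pd.DataFrame(
        rows,
        columns=["tax_id", "name", "n_contigs", "mean_identity",
                 "mean_query_coverage", "flags"],
    )
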