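"""RPKM abundance per contig and per taxon.

RPKM (reads per kilobase per million mapped reads) normalises read counts
by contig length and per-sample sequencing depth:

    rpkm = mapped_reads / ((length / 1e3) * (total_mapped / 1e6))

The per-sample denominator is the total of reads mapped to any contig of
that sample.  Taxon-level abundance is the unweighted mean RPKM of the
contigs assigned to that taxon.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConsistencyError, FormatError
from .hits import TaxonCluster


@dataclass(frozen=True)
class ContigCounts:
    contig_id: str
    length: int
    mapped_reads: int
    sample_id: str

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.contig_id}: non-positive length")
        if self.mapped_reads < 0:
            raise ValueError(f"{self.contig_id}: negative read count")


def read_counts_table(path: str | Path) -> list[ContigCounts]:
    """Read a counts TSV (sample_id, contig_id, length, mapped_reads)."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "contig_id", "length", "mapped_reads"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    return [
        ContigCounts(str(r.contig_id), int(r.length), int(r.mapped_reads),
                     str(r.sample_id))
        for r in df.itertuples()
    ]


def write_counts_table(counts: Iterable[ContigCounts], path: str | Path) -> None:
    pd.DataFrame(
        [(c.sample_id, c.contig_id, c.length, c.mapped_reads) for c in counts],
        columns=["sample_id", "contig_id", "length", "mapped_reads"],
    ).to_csv(path, sep="\t", index=False)


def rpkm_contig(counts: ContigCounts, total_mapped: int) -> float:
    """RPKM of one contig given its sample's total mapped reads."""
    if total_mapped <= 0:
        raise ConsistencyError(
            f"{counts.sample_id}: total mapped reads must be positive "
            f"to define sequencing depth"
        )
    return counts.mapped_reads / ((counts.length / 1e3) * (total_mapped / 1e6))


def contig_rpkm_table(counts: Sequence[ContigCounts]) -> dict[str, float]:
    """Per-contig RPKM for one sample's counts (shared depth denominator)."""
    samples = {c.sample_id for c in counts}
    if len(samples) > 1:
        raise ConsistencyError(f"counts span multiple samples: {sorted(samples)}")
    total = sum(c.mapped_reads for c in counts)
    return {c.contig_id: rpkm_contig(c, total) for c in counts}


def rpkm_taxon(cluster: TaxonCluster, contig_rpkms: Mapping[str, float]) -> float:
    """Unweighted mean RPKM over a cluster's member contigs."""
    missing = sorted(q for q in cluster.member_queries if q not in contig_rpkms)
    if missing:
        raise ConsistencyError(
            f"taxon {cluster.tax_id}: no RPKM entry for contig(s) {missing}"
        )
    values = [contig_rpkms[q] for q in cluster.member_queries]
    return sum(values) / len(values)


def abundance_table(
    sample_id: str,
    counts: Sequence[ContigCounts],
    clusters: Sequence[TaxonCluster],
) -> pd.DataFrame:
    """Long-format abundance rows: (sample_id, level, id, rpkm).

    Contig-level rows are emitted for every counted contig; taxon-level
    rows for every cluster (mean of member contig RPKMs).
    """
    per_contig = contig_rpkm_table(counts)
    rows = [(sample_id, "contig", cid, r) for cid, r in sorted(per_contig.items())]
    rows += [
        (sample_id, "taxon", str(c.tax_id), rpkm_taxon(c, per_contig))
        for c in clusters
    ]
    return pd.DataFrame(rows, columns=["sample_id", "level", "id", "rpkm"])
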