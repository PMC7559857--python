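"""Cross-pool comparisons: richness, shared "ecosystem signature" taxa,
and host-group summaries.

Sharing between pools is evaluated at the clustered-taxon (tax_id) level
— contig identifiers are assembly-specific and not comparable across
pools.  Broad-category taxa (uncultured/unclassified) are excluded from
richness by default but can be retained with a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .confidence import ConfidenceCall
from .taxonomy import HostGroupMap, TaxonomyTree


@dataclass
class PoolVirome:
    """One pool's annotated virome: taxa with abundance and optional calls."""

    sample_id: str
    site_label: str = ""
    taxa: dict[int, float] = field(default_factory=dict)  # tax_id -> rpkm
    calls: dict[int, ConfidenceCall] = field(default_factory=dict)
    broad_taxa: set[int] = field(default_factory=set)

    def taxon_set(self, include_broad: bool = False) -> set[int]:
        keys = set(self.taxa)
        return keys if include_broad else keys - self.broad_taxa

    @classmethod
    def from_calls(
        cls, sample_id: str, calls: Sequence[ConfidenceCall], site_label: str = ""
    ) -> "PoolVirome":
        return cls(
            sample_id=sample_id,
            site_label=site_label,
            taxa={c.tax_id: c.rpkm for c in calls},
            calls={c.tax_id: c for c in calls},
            broad_taxa={c.tax_id for c in calls if c.broad_category},
        )


@dataclass
class RichnessSummary:
    total_taxa: int
    per_pool: dict[str, int]
    singletons: int  # taxa present in exactly one pool
    level: str


def richness(
    pools: Sequence[PoolVirome],
    tree: TaxonomyTree | None = None,
    level: str = "species",
    include_broad: bool = False,
) -> RichnessSummary:
    """Distinct-taxon counts across pools at the requested rank.

    Taxa are resolved to their ancestor at ``level`` when the tree is
    given; taxa with no ancestor at that rank are counted at their own
    level.  Singletons are taxa detected in exactly one pool.
    """

    def resolve(t: int) -> int:
        if tree is None or t not in tree:
            return t
        anc = tree.ancestor_at_rank(t, level)
        return anc if anc is not None else t

    per_pool_sets = {
        p.sample_id: {resolve(t) for t in p.taxon_set(include_broad)} for p in pools
    }
    counts: dict[int, int] = {}
    for taxa in per_pool_sets.values():
        for t in taxa:
            counts[t] = counts.get(t, 0) + 1
    return RichnessSummary(
        total_taxa=len(counts),
        per_pool={s: len(taxa) for s, taxa in per_pool_sets.items()},
        singletons=sum(1 for n in counts.values() if n == 1),
        level=level,
    )


@dataclass
class SignatureReport:
    pool_pair: tuple[str, str]
    shared_taxa: set[int]
    exclusive_counts: dict[str, int]


def signature_taxa(
    a: PoolVirome, b: PoolVirome, include_broad: bool = False
) -> SignatureReport:
    """Taxa detected in both pools (candidate ecosystem signature viruses)."""
    sa, sb = a.taxon_set(include_broad), b.taxon_set(include_broad)
    shared = sa & sb
    return SignatureReport(
        pool_pair=(a.sample_id, b.sample_id),
        shared_taxa=shared,
        exclusive_counts={a.sample_id: len(sa - sb), b.sample_id: len(sb - sa)},
    )


def host_group_summary(
    pools: Sequence[PoolVirome],
    host_map: HostGroupMap,
    include_broad: bool = True,
) -> pd.DataFrame:
    """Per pool x host group: taxon count and summed RPKM.

    Unmapped taxa fall under "unassigned".  Summed RPKM over groups
    conserves the pool total by construction.
    """
    rows = []
    for p in pools:
        agg: dict[str, list[float]] = {}
        for t in sorted(p.taxon_set(include_broad)):
            g = host_map.group(t)
            agg.setdefault(g, []).append(p.taxa[t])
        for g in sorted(agg):
            rows.append((p.sample_id, g, len(agg[g]), sum(agg[g])))
    return pd.DataFrame(
        rows, columns=["sample_id", "host_group", "n_taxa", "rpkm_sum"]
    )


def presence_absence_matrix(
    pools: Sequence[PoolVirome],
    tree: TaxonomyTree | None = None,
    include_broad: bool = False,
    abundance: bool = False,
) -> pd.DataFrame:
    """Pools x taxa matrix (0/1, or RPKM with ``abundance=True``)."""
    all_taxa = sorted(set().union(*(p.taxon_set(include_broad) for p in pools)))
    data = {}
    for p in pools:
        present = p.taxon_set(include_broad)
        data[p.sample_id] = [
            (p.taxa[t] if abundance else 1.0) if t in present else 0.0
            for t in all_taxa
        ]
    index = [
        tree.name(t) if tree is not None and t in tree else str(t) for t in all_taxa
    ]
    df = pd.DataFrame(data, index=pd.Index(index, name="taxon"))
    df.insert(0, "tax_id", all_taxa)
    return df
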