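"""Goodness-of-assignment classification and CRESS-DNA enrichment.

The central diagnostic: plotting mean percent identity against mean query
coverage separates confidently annotated taxa from hits that match
database sequences only over short stretches and therefore represent
largely novel genomes.  The boundary is strict — a taxon is
``high_confidence`` iff its mean query coverage exceeds the configured
boundary (60% by default), so ">60%" and "0-60%" partition exactly.

A 2x2 chi-square test then asks whether the novel class is enriched in a
designated set of taxa (in the motivating study, CRESS-DNA virus
families).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .errors import ConsistencyError
from .hits import TaxonCluster
from .taxonomy import HostGroupMap, TaxonomyTree

HIGH_CONFIDENCE = "high_confidence"
NOVEL = "novel"


@dataclass(frozen=True)
class ConfidenceCall:
    tax_id: int
    mean_query_coverage: float
    mean_identity: float
    confidence: str  # HIGH_CONFIDENCE or NOVEL
    host_group: str
    rpkm: float
    broad_category: bool = False


def classify(
    clusters: Sequence[TaxonCluster],
    config: PipelineConfig | None = None,
    host_map: HostGroupMap | None = None,
    taxon_rpkm: Mapping[int, float] | None = None,
) -> list[ConfidenceCall]:
    """Label every cluster by the coverage boundary; sort by descending RPKM.

    Broad-category taxa are retained here (they still carry similarity
    information) and flagged so richness summaries can drop them.
    """
    config = config or PipelineConfig()
    host_map = host_map or HostGroupMap()
    taxon_rpkm = taxon_rpkm or {}
    calls = []
    for c in clusters:
        calls.append(
            ConfidenceCall(
                tax_id=c.tax_id,
                mean_query_coverage=c.mean_query_coverage,
                mean_identity=c.mean_identity,
                confidence=(
                    HIGH_CONFIDENCE
                    if c.mean_query_coverage > config.coverage_boundary
                    else NOVEL
                ),
                host_group=host_map.group(c.tax_id),
                rpkm=float(taxon_rpkm.get(c.tax_id, 0.0)),
                broad_category=c.broad_category,
            )
        )
    calls.sort(key=lambda c: (-c.rpkm, c.tax_id))
    return calls


def scatter_table(
    calls: Sequence[ConfidenceCall], tree: TaxonomyTree | None = None
) -> pd.DataFrame:
    """One row per taxon, ready for bubble plotting.

    x = mean query coverage, y = mean identity, size = RPKM, color key =
    host group.  Zero-RPKM taxa are retained with size 0.
    """
    if not calls:
        raise ValueError("no confidence calls to tabulate")
    rows = [
        (
            c.tax_id,
            tree.name(c.tax_id) if tree and c.tax_id in tree else "",
            c.mean_query_coverage,
            c.mean_identity,
            c.rpkm,
            c.host_group,
            c.confidence,
            c.broad_category,
        )
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=["tax_id", "name", "mean_query_coverage", "mean_identity",
                 "rpkm", "host_group", "confidence", "broad_category"],
    )


@dataclass
class EnrichmentResult:
    table: np.ndarray  # 2x2 counts, rows = class, cols = category
    statistic: float
    df: int
    p_value: float

    def to_dict(self) -> dict:
        return {
            "table": self.table.tolist(),
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
        }


def chi_square_2x2(table, yates: bool = False) -> EnrichmentResult:
    """Pearson chi-square test of independence on a 2x2 table.

    The statistic is sum((O - E)^2 / E) with expectations from the
    margins; the p-value is the df-1 chi-square survival function.  No
    continuity correction by default.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2) or (obs < 0).any():
        raise ValueError("expected a 2x2 table of nonnegative counts")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ConsistencyError("degenerate 2x2 table: a margin is zero")
    expected = np.outer(row, col) / obs.sum()
    diff = np.abs(obs - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    statistic = float((diff**2 / expected).sum())
    p = float(stats.chi2.sf(statistic, df=1))
    return EnrichmentResult(obs.astype(int), statistic, 1, p)


def cress_enrichment(
    calls: Sequence[ConfidenceCall],
    cress_taxa: set[int],
    yates: bool = False,
) -> EnrichmentResult:
    """Is the novel (low-coverage) class enriched in CRESS-DNA taxa?

    Builds the 2x2 table (novel vs high_confidence) x (CRESS vs
    non-CRESS) over taxa and delegates to :func:`chi_square_2x2`.
    """
    table = np.zeros((2, 2), dtype=int)
    for c in calls:
        i = 0 if c.confidence == NOVEL else 1
        j = 0 if c.tax_id in cress_taxa else 1
        table[i, j] += 1
    return chi_square_2x2(table, yates=yates)


def class_fractions(
    calls: Sequence[ConfidenceCall], cress_taxa: set[int]
) -> dict[str, float]:
    """CRESS fractions by confidence class, over taxa and over abundance.

    Emitted both ways because a "fraction of CRESS hits" can be counted
    per taxon or weighted by RPKM; both summaries are reported.
    """
    out: dict[str, float] = {}
    for label, subset in (
        ("overall", list(calls)),
        (HIGH_CONFIDENCE, [c for c in calls if c.confidence == HIGH_CONFIDENCE]),
        (NOVEL, [c for c in calls if c.confidence == NOVEL]),
    ):
        n = len(subset)
        k = sum(1 for c in subset if c.tax_id in cress_taxa)
        out[f"{label}_cress_fraction_taxa"] = 100.0 * k / n if n else float("nan")
        w = sum(c.rpkm for c in subset)
        kw = sum(c.rpkm for c in subset if c.tax_id in cress_taxa)
        out[f"{label}_cress_fraction_rpkm"] = 100.0 * kw / w if w else float("nan")
    return out


def write_confidence_table(
    calls: Sequence[ConfidenceCall], path: str | Path, tree: TaxonomyTree | None = None
) -> None:
    scatter_table(calls, tree).to_csv(path, sep="\t", index=False)
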