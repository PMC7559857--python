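"""Stage orchestration: read -> filter -> assign -> cluster -> abundance
-> classify, with a reproducibility manifest.

These functions are the library behind the CLI subcommands; each takes
file paths or in-memory objects and writes the declared stage TSVs under
a run directory with fixed relative names.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .abundance import abundance_table, read_counts_table
from .comparative import (
    PoolVirome,
    host_group_summary,
    presence_absence_matrix,
    richness,
    signature_taxa,
)
from .config import PipelineConfig
from .confidence import classify, scatter_table, write_confidence_table
from .errors import VirofitError
from .hits import (
    ExclusionSet,
    cluster_by_taxon,
    clusters_to_frame,
    filter_hits,
    read_hit_table,
)
from .taxonomy import (
    UNASSIGNED,
    HostGroupMap,
    TaxonomyTree,
    assign_taxon,
    load_taxonomy,
)

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config: dict
    input_checksums: dict[str, str] = field(default_factory=dict)
    stage_rows: dict[str, int] = field(default_factory=dict)
    version: str = __version__
    rng_seed: int = 0
    failed_stage: str | None = None

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class AnnotatedPool:
    sample_id: str
    calls: list
    clusters: list
    taxon_rpkm: dict[int, float]
    n_hits_read: int
    n_hits_filtered: int
    n_queries_assigned: int

    def as_pool_virome(self) -> PoolVirome:
        return PoolVirome.from_calls(self.sample_id, self.calls)


def annotate_pool(
    sample_id: str,
    hits_path: str | Path,
    counts_path: str | Path,
    tree: TaxonomyTree,
    host_map: HostGroupMap,
    config: PipelineConfig,
    exclusions: ExclusionSet | None = None,
    control_hits_path: str | Path | None = None,
    mode: str = "best_hit",
    broad_taxa: set[int] | None = None,
) -> AnnotatedPool:
    """Run the full annotation chain for one pool."""
    hits = read_hit_table(hits_path)
    if exclusions is None:
        if control_hits_path is not None:
            # only significant control hits define contaminants: the raw
            # control table carries the same weak spurious matches as any
            # search output, so it passes the e-value/top-N filter first
            control = filter_hits(read_hit_table(control_hits_path), config=config)
            exclusions = ExclusionSet.from_control_table(control, broad_taxa)
        else:
            exclusions = ExclusionSet(broad_category_taxa=set(broad_taxa or ()))
    filtered = filter_hits(hits, exclusions, config)

    per_query: dict[str, list] = {}
    for h in filtered:
        per_query.setdefault(h.query_id, []).append(h)
    best_hits = {}
    for qid, qhits in per_query.items():
        tax = assign_taxon(qhits, tree, mode=mode, config=config)
        if tax == UNASSIGNED:
            continue
        representative = min(
            qhits, key=lambda h: (-h.bitscore, h.evalue, h.subject_taxid)
        )
        best_hits[qid] = (representative, tax)
    clusters = cluster_by_taxon(best_hits, exclusions)

    counts = [c for c in read_counts_table(counts_path) if c.sample_id == sample_id]
    abund = abundance_table(sample_id, counts, clusters)
    taxon_rows = abund[abund["level"] == "taxon"]
    taxon_rpkm = {int(r.id): float(r.rpkm) for r in taxon_rows.itertuples()}
    calls = classify(clusters, config, host_map, taxon_rpkm)
    return AnnotatedPool(
        sample_id=sample_id,
        calls=calls,
        clusters=clusters,
        taxon_rpkm=taxon_rpkm,
        n_hits_read=len(hits),
        n_hits_filtered=len(filtered),
        n_queries_assigned=len(best_hits),
    )


def run_annotate(
    sample_id: str,
    hits_path: str | Path,
    counts_path: str | Path,
    taxonomy_path: str | Path,
    host_map_path: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    control_hits_path: str | Path | None = None,
    mode: str = "best_hit",
    broad_taxa: set[int] | None = None,
) -> RunManifest:
    """File-level entry point: annotate one pool and write all stage TSVs."""
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=dataclasses.asdict(config), rng_seed=config.rng_seed
    )
    inputs = {
        "hits": hits_path, "counts": counts_path,
        "taxonomy": taxonomy_path, "host_groups": host_map_path,
    }
    if control_hits_path:
        inputs["control_hits"] = control_hits_path
    for name, p in inputs.items():
        if not Path(p).exists():
            raise VirofitError(f"missing input file: {name} = {p}")
        manifest.input_checksums[name] = _checksum(p)

    try:
        tree = load_taxonomy(taxonomy_path)
        host_map = HostGroupMap.load(host_map_path)
        annotated = annotate_pool(
            sample_id, hits_path, counts_path, tree, host_map, config,
            control_hits_path=control_hits_path, mode=mode,
            broad_taxa=broad_taxa,
        )
        clusters_to_frame(annotated.clusters, tree).to_csv(
            out / "clusters.tsv", sep="\t", index=False
        )
        counts = [
            c for c in read_counts_table(counts_path) if c.sample_id == sample_id
        ]
        abund = abundance_table(sample_id, counts, annotated.clusters)
        abund.to_csv(out / "abundance.tsv", sep="\t", index=False)
        write_confidence_table(annotated.calls, out / "confidence.tsv", tree)
        manifest.stage_rows = {
            "hits_read": annotated.n_hits_read,
            "hits_filtered": annotated.n_hits_filtered,
            "queries_assigned": annotated.n_queries_assigned,
            "clusters": len(annotated.clusters),
            "confidence_calls": len(annotated.calls),
        }
    except Exception as exc:
        manifest.failed_stage = type(exc).__name__
        manifest.write(out / "manifest.json")
        raise
    manifest.write(out / "manifest.json")
    return manifest


def run_compare(
    pools: list[AnnotatedPool],
    tree: TaxonomyTree,
    host_map: HostGroupMap,
    out_dir: str | Path,
    include_broad: bool = False,
) -> dict:
    """Comparative reports over >= 2 annotated pools."""
    if len(pools) < 2:
        raise ValueError("comparison requires at least two annotated pools")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    viromes = [p.as_pool_virome() for p in pools]

    rich = richness(viromes, tree, include_broad=include_broad)
    pd.DataFrame(
        [(rich.level, rich.total_taxa, rich.singletons)]
        + [(f"pool:{s}", n, "") for s, n in rich.per_pool.items()],
        columns=["scope", "n_taxa", "singletons"],
    ).to_csv(out / "richness.tsv", sep="\t", index=False)

    sig_rows = []
    for i in range(len(viromes)):
        for j in range(i + 1, len(viromes)):
            rep = signature_taxa(viromes[i], viromes[j], include_broad)
            sig_rows.append(
                (rep.pool_pair[0], rep.pool_pair[1], len(rep.shared_taxa),
                 ",".join(map(str, sorted(rep.shared_taxa))))
            )
    pd.DataFrame(
        sig_rows, columns=["pool_a", "pool_b", "n_shared", "shared_tax_ids"]
    ).to_csv(out / "signature.tsv", sep="\t", index=False)

    host_group_summary(viromes, host_map).to_csv(
        out / "host_groups_summary.tsv", sep="\t", index=False
    )
    presence_absence_matrix(viromes, tree, include_broad).to_csv(
        out / "presence_absence.tsv", sep="\t"
    )
    return {
        "richness": rich,
        "signatures": sig_rows,
    }


def run_report(
    pools: list[AnnotatedPool],
    tree: TaxonomyTree,
    out_dir: str | Path,
    render: bool = True,
) -> dict:
    """Scatter tables, optional bubble-plot images, and a summary JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"pools": {}}
    for p in pools:
        table = scatter_table(p.calls, tree) if p.calls else pd.DataFrame()
        table.to_csv(out / f"scatter_{p.sample_id}.tsv", sep="\t", index=False)
        n_high = sum(1 for c in p.calls if c.confidence == "high_confidence")
        summary["pools"][p.sample_id] = {
            "n_taxa": len(p.calls),
            "n_high_confidence": n_high,
            "n_novel": len(p.calls) - n_high,
        }
        if render and p.calls:
            _render_scatter(table, out / f"scatter_{p.sample_id}.png", p.sample_id)
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary


def _render_scatter(table: pd.DataFrame, path: Path, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    groups = sorted(table["host_group"].unique())
    cmap = plt.get_cmap("tab10")
    for i, g in enumerate(groups):
        sub = table[table["host_group"] == g]
        size = 20 + 200 * sub["rpkm"] / max(table["rpkm"].max(), 1e-9)
        ax.scatter(
            sub["mean_query_coverage"], sub["mean_identity"],
            s=size, alpha=0.6, label=g, color=cmap(i % 10),
        )
    ax.axvline(60, color="grey", ls="--", lw=1)
    ax.set_xlabel("mean query coverage (%)")
    ax.set_ylabel("mean pairwise identity (%)")
    ax.set_xlim(0, 105)
    ax.set_ylim(0, 105)
    ax.set_title(title)
    ax.legend(fontsize=7, loc="lower left")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
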