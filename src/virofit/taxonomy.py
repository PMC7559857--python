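"""Taxonomy tree, lowest-common-ancestor assignment and host-group maps.

The tree is a minimal parent-pointer structure read from a four-column TSV
(``tax_id, parent_id, rank, name``), following the NCBI dump convention
that the root is its own parent.  Two assignment strategies are offered
for a contig's hit list: the single best hit, or a MEGAN-style lowest
common ancestor over all hits scoring within a configurable window of the
top bitscore.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .config import PipelineConfig
from .errors import FormatError, StructureError

#: Sentinel tax_id returned when a query has no surviving hits and label
#: used for taxa absent from a host-group map.
UNASSIGNED = 0
UNASSIGNED_LABEL = "unassigned"

#: Controlled vocabulary of ranks, ordered root-to-leaf.
RANKS = (
    "root",
    "superkingdom",
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
    "no_rank",
)

#: Host-group labels used in the comparative summaries.
HOST_GROUPS = (
    "mosquito",
    "other_arthropod",
    "bat",
    "other_mammal",
    "human",
    "other_vertebrate",
    "plant",
    "bacteriophage",
    "environmental",
    UNASSIGNED_LABEL,
)


@dataclass(frozen=True)
class TaxonomyNode:
    tax_id: int
    parent_id: int
    rank: str
    name: str

    def __post_init__(self) -> None:
        if self.tax_id <= 0:
            raise ValueError(f"tax_id must be positive, got {self.tax_id}")
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}")


class TaxonomyTree:
    """Rooted taxonomy with O(depth) ancestor walks.

    Parameters
    ----------
    nodes : iterable of TaxonomyNode
        Must contain exactly one self-parent node (the root), every
        ``parent_id`` must resolve, and parent pointers must be acyclic.
    """

    def __init__(self, nodes: Iterable[TaxonomyNode]):
        self.nodes: dict[int, TaxonomyNode] = {}
        for node in nodes:
            if node.tax_id in self.nodes:
                raise FormatError(f"duplicate tax_id {node.tax_id}")
            self.nodes[node.tax_id] = node
        roots = [n.tax_id for n in self.nodes.values() if n.parent_id == n.tax_id]
        if len(roots) != 1:
            raise StructureError(f"expected exactly one root, found {len(roots)}")
        self.root = roots[0]
        self._depth: dict[int, int] = {self.root: 0}
        for tax_id in self.nodes:
            self._resolve_depth(tax_id)

    def _resolve_depth(self, tax_id: int) -> int:
        chain = []
        t = tax_id
        while t not in self._depth:
            chain.append(t)
            node = self.nodes.get(t)
            if node is None:
                raise StructureError(f"parent {t} of node chain {chain} is absent")
            if node.parent_id not in self.nodes:
                raise StructureError(
                    f"node {t} has unresolvable parent {node.parent_id}"
                )
            t = node.parent_id
            if len(chain) > len(self.nodes):
                raise StructureError(f"cycle detected through node {tax_id}")
        d = self._depth[t]
        for u in reversed(chain):
            d += 1
            self._depth[u] = d
        return self._depth[tax_id]

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, tax_id: int) -> bool:
        return tax_id in self.nodes

    def depth(self, tax_id: int) -> int:
        self._require(tax_id)
        return self._depth[tax_id]

    def parent(self, tax_id: int) -> int:
        self._require(tax_id)
        return self.nodes[tax_id].parent_id

    def name(self, tax_id: int) -> str:
        self._require(tax_id)
        return self.nodes[tax_id].name

    def rank(self, tax_id: int) -> str:
        self._require(tax_id)
        return self.nodes[tax_id].rank

    def path_to_root(self, tax_id: int) -> list[int]:
        """Ancestors of ``tax_id`` from itself up to and including the root."""
        self._require(tax_id)
        path = [tax_id]
        while path[-1] != self.root:
            path.append(self.nodes[path[-1]].parent_id)
        return path

    def leaves(self) -> list[int]:
        parents = {n.parent_id for n in self.nodes.values()}
        return sorted(t for t in self.nodes if t not in parents)

    def children(self, tax_id: int) -> list[int]:
        self._require(tax_id)
        return sorted(
            t for t, n in self.nodes.items() if n.parent_id == tax_id and t != tax_id
        )

    def ancestor_at_rank(self, tax_id: int, rank: str) -> int | None:
        """The ancestor-or-self of ``tax_id`` carrying ``rank``, if any."""
        for t in self.path_to_root(tax_id):
            if self.nodes[t].rank == rank:
                return t
        return None

    def is_ancestor(self, ancestor: int, tax_id: int) -> bool:
        """True if ``ancestor`` lies on the root path of ``tax_id`` (self counts)."""
        return ancestor in self.path_to_root(tax_id)

    def lca(self, taxa: Iterable[int]) -> int:
        """Deepest node that is an ancestor-or-self of every input taxon."""
        taxa = set(taxa)
        if not taxa:
            raise ValueError("lca of an empty taxon set is undefined")
        it = iter(taxa)
        common = self.path_to_root(next(it))
        common_set = set(common)
        for t in it:
            common_set &= set(self.path_to_root(t))
        # the root path is depth-ordered, so the first surviving entry is deepest
        for t in common:
            if t in common_set:
                return t
        raise StructureError("disconnected tree")  # pragma: no cover

    def related_below_rank(self, a: int, b: int, rank: str) -> bool:
        """True if ``a`` and ``b`` share an ancestor at-or-below ``rank``.

        Used to decide whether a calibration best hit is "taxonomically
        related" to the true source taxon.
        """
        anc = self.lca({a, b})
        max_depth = RANKS.index(rank)
        anc_rank = self.nodes[anc].rank
        if anc_rank == "no_rank":
            # fall back on the nearest ranked ancestor
            for t in self.path_to_root(anc):
                if self.nodes[t].rank != "no_rank":
                    anc_rank = self.nodes[t].rank
                    break
        return RANKS.index(anc_rank) >= max_depth and anc_rank != "root"

    def _require(self, tax_id: int) -> None:
        if tax_id not in self.nodes:
            raise KeyError(f"tax_id {tax_id} not in taxonomy")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(n.tax_id, n.parent_id, n.rank, n.name) for n in self.nodes.values()],
            columns=["tax_id", "parent_id", "rank", "name"],
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_taxonomy(path: str | Path) -> TaxonomyTree:
    """Read a taxonomy TSV (header: tax_id, parent_id, rank, name)."""
    df = pd.read_csv(path, sep="\t", dtype={"tax_id": int, "parent_id": int})
    required = ["tax_id", "parent_id", "rank", "name"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing taxonomy columns {missing}")
    if df["tax_id"].duplicated().any():
        dupes = df.loc[df["tax_id"].duplicated(), "tax_id"].tolist()
        raise FormatError(f"{path}: duplicate tax_id {dupes}")
    return TaxonomyTree(
        TaxonomyNode(int(r.tax_id), int(r.parent_id), str(r.rank), str(r.name))
        for r in df.itertuples()
    )


@dataclass
class HostGroupMap:
    """tax_id -> host-group label; unmapped taxa resolve to "unassigned"."""

    entries: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {v for v in self.entries.values() if v not in HOST_GROUPS}
        if bad:
            raise FormatError(f"unknown host-group labels {sorted(bad)}")

    def group(self, tax_id: int) -> str:
        return self.entries.get(tax_id, UNASSIGNED_LABEL)

    @classmethod
    def load(cls, path: str | Path) -> "HostGroupMap":
        df = pd.read_csv(path, sep="\t", dtype={"tax_id": int})
        if not {"tax_id", "host_group"} <= set(df.columns):
            raise FormatError(f"{path}: expected columns tax_id, host_group")
        return cls(dict(zip(df["tax_id"], df["host_group"])))

    def write(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.entries.items()), columns=["tax_id", "host_group"]
        ).to_csv(path, sep="\t", index=False)


def assign_taxon(
    hits: Sequence,
    tree: TaxonomyTree,
    mode: str = "best_hit",
    config: PipelineConfig | None = None,
) -> int:
    """Assign one query's (pre-filtered) hits to a taxon.

    ``best_hit`` takes the taxon of the maximal-bitscore hit, breaking
    ties by lower e-value then lower tax_id.  ``lca`` takes the lowest
    common ancestor of every hit scoring at least
    ``(1 - lca_score_window)`` times the top bitscore.  An empty hit list
    yields :data:`UNASSIGNED`.
    """
    config = config or PipelineConfig()
    hits = list(hits)
    if not hits:
        return UNASSIGNED
    for h in hits:
        tree._require(h.subject_taxid)
    if mode == "best_hit":
        best = min(hits, key=lambda h: (-h.bitscore, h.evalue, h.subject_taxid))
        return best.subject_taxid
    if mode == "lca":
        top = max(h.bitscore for h in hits)
        floor = (1.0 - config.lca_score_window) * top
        taxa = {h.subject_taxid for h in hits if h.bitscore >= floor}
        return tree.lca(taxa)
    raise ValueError(f"unknown assignment mode {mode!r}")
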