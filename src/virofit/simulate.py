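"""Ground-truthed synthetic virome generator.

Emits every input the annotation pipeline consumes — taxonomy TSV,
host-group TSV, labelled reference genomes (FASTA), per-pool contigs
(FASTA), hit tables (BLAST outfmt-6-style TSV, produced by actually
searching the contigs against the reference database), read-count TSVs
and a no-template-control hit table — together with the ground truth
needed to validate recovery end to end.

The default design emulates the structure of a four-pool mosquito virome
survey: two pools from one environment sharing eight taxa, two pools
from a second environment sharing four, one taxon bridging the
environments; a mixture of host groups dominated by mosquito-associated
viruses; a divergence gradient producing both confidently annotated taxa
(long, mildly diverged alignments) and largely novel ones (a short
conserved island inside otherwise unalignable sequence — the diagnostic
geometry of low-coverage/high-identity hits); planted enrichment of
CRESS-DNA-style families in the novel class; a few circular genomes with
exact terminal repeats; and contaminant subjects present in both sample
and control so the exclusion rule is exercised.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .align import (
    LabeledSequence,
    build_kmer_index,
    search_database,
    write_labeled_fasta,
)
from .abundance import ContigCounts, write_counts_table
from .calibration import mutate_sequence
from .config import PipelineConfig, ScoringScheme
from .errors import DesignError
from .hits import HitRecord, write_hit_table
from .taxonomy import HOST_GROUPS, HostGroupMap, TaxonomyNode, TaxonomyTree

_HIGH = "high_confidence"
_NOVEL = "novel"


@dataclass
class SimulationDesign:
    """Knobs of the synthetic study; defaults are the reference scenario."""

    n_pools: int = 4
    pool_names: tuple[str, ...] = ("AUT_01", "AUT_02", "BRB_ae", "BRB_cp")
    taxa_per_pool: int = 20
    #: planted shared-taxa counts per pool-index pair (disjoint sets)
    shared_pairs: dict[tuple[int, int], int] = field(
        default_factory=lambda: {(0, 1): 8, (2, 3): 4, (0, 3): 1}
    )
    host_group_mix: dict[str, float] = field(
        default_factory=lambda: {
            "mosquito": 0.30,
            "bacteriophage": 0.15,
            "bat": 0.10,
            "other_mammal": 0.10,
            "human": 0.05,
            "other_vertebrate": 0.05,
            "plant": 0.10,
            "environmental": 0.05,
            "other_arthropod": 0.10,
        }
    )
    #: fraction of planted taxa whose contigs are largely novel
    novel_fraction: float = 0.45
    #: (identity mean, identity sd, coverage mean, coverage sd) per class
    divergence_classes: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            _HIGH: (92.0, 3.0, 85.0, 7.0),
            _NOVEL: (85.0, 4.0, 28.0, 10.0),
        }
    )
    #: probability that a taxon drawn for a class is CRESS-DNA-like
    cress_fraction_by_class: dict[str, float] = field(
        default_factory=lambda: {_NOVEL: 0.65, _HIGH: 0.35}
    )
    n_circular: int = 3
    contaminant_subjects: int = 3
    n_broad_taxa: int = 2
    n_short_decoys: int = 2
    n_decoy_taxa: int = 8
    genome_length: tuple[int, int] = (2000, 3000)
    contig_length: tuple[int, int] = (550, 1200)
    min_terminal_repeat_len: int = 50
    max_terminal_repeat_len: int = 200
    mean_reads: float = 200.0
    nb_dispersion: float = 2.0
    rng_seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.host_group_mix.values()) - 1.0) > 1e-6:
            raise DesignError("host_group_mix proportions must sum to 1")
        if any(v < 0 for v in self.host_group_mix.values()):
            raise DesignError("negative host-group proportion")
        bad = set(self.host_group_mix) - set(HOST_GROUPS)
        if bad:
            raise DesignError(f"unknown host groups {sorted(bad)}")
        per_pool_shared = [0] * self.n_pools
        for (i, j), k in self.shared_pairs.items():
            if not (0 <= i < j < self.n_pools):
                raise DesignError(f"bad pool pair {(i, j)}")
            if k < 0:
                raise DesignError("negative shared count")
            per_pool_shared[i] += k
            per_pool_shared[j] += k
        if any(s > self.taxa_per_pool for s in per_pool_shared):
            raise DesignError("planted shared taxa exceed pool size")
        if len(self.pool_names) != self.n_pools:
            raise DesignError("pool_names length must equal n_pools")
        if not 0.0 <= self.novel_fraction <= 1.0:
            raise DesignError("novel_fraction must lie in [0, 1]")


@dataclass
class ContigTruth:
    contig_id: str
    pool: str
    source_taxid: int
    true_class: str          # high_confidence | novel | contaminant | short_decoy
    mutation_rate: float
    circular: bool
    overlap_length: int
    target_coverage: float


@dataclass
class GroundTruth:
    pool_taxa: dict[str, list[int]]
    shared_sets: dict[str, list[int]]        # "POOL_A|POOL_B" -> taxa
    contigs: list[ContigTruth]
    cress_taxa: list[int]
    broad_taxa: list[int]
    contaminant_subjects: list[str]
    host_groups: dict[int, str]
    class_by_taxon: dict[int, str]

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["host_groups"] = {str(k): v for k, v in self.host_groups.items()}
        d["class_by_taxon"] = {str(k): v for k, v in self.class_by_taxon.items()}
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        d["contigs"] = [ContigTruth(**c) for c in d["contigs"]]
        d["host_groups"] = {int(k): v for k, v in d["host_groups"].items()}
        d["class_by_taxon"] = {int(k): v for k, v in d["class_by_taxon"].items()}
        return cls(**d)


# --------------------------------------------------------------------------
# taxonomy and reference database

_ROOT = 1
_VIRUSES = 10
_CONSTRUCTS = 20
_SPECIES_PER_GENUS = 2
_GENERA_PER_FAMILY = 2


def simulate_taxonomy(
    n_cress_species: int, n_other_species: int, n_broad: int = 0
) -> tuple[TaxonomyTree, list[int], list[int], list[int]]:
    """Build a virus taxonomy with CRESS-like and other families.

    Families hold two genera of two species each, so every species has a
    congener — database searches return multiple related subjects and
    LCA assignment has real work to do.  Returns the tree plus the
    CRESS species, other species and broad-category tax_ids.
    """
    nodes = [
        TaxonomyNode(_ROOT, _ROOT, "root", "root"),
        TaxonomyNode(_VIRUSES, _ROOT, "superkingdom", "Viruses"),
        TaxonomyNode(_CONSTRUCTS, _ROOT, "no_rank", "synthetic constructs"),
    ]
    per_family = _SPECIES_PER_GENUS * _GENERA_PER_FAMILY

    def build(n_species: int, cress: bool, fam_offset: int) -> list[int]:
        species_ids = []
        n_families = -(-n_species // per_family)
        made = 0
        for f in range(n_families):
            fam_id = 100 + fam_offset + f
            label = "Cressviridae" if cress else "Otherviridae"
            nodes.append(
                TaxonomyNode(fam_id, _VIRUSES, "family", f"{label}_{fam_offset + f}")
            )
            for g in range(_GENERA_PER_FAMILY):
                gen_id = 1000 + (fam_offset + f) * 10 + g
                nodes.append(
                    TaxonomyNode(gen_id, fam_id, "genus",
                                 f"genus_{fam_offset + f}_{g}")
                )
                for s in range(_SPECIES_PER_GENUS):
                    if made >= n_species:
                        continue
                    sp_id = 10000 + (fam_offset + f) * 100 + g * 10 + s
                    nodes.append(
                        TaxonomyNode(sp_id, gen_id, "species",
                                     f"virus_sp_{sp_id}")
                    )
                    species_ids.append(sp_id)
                    made += 1
        return species_ids

    n_cress_fam = -(-n_cress_species // per_family)
    cress_species = build(n_cress_species, True, 0)
    other_species = build(n_other_species, False, n_cress_fam)
    broad = []
    for b in range(n_broad):
        bid = 90000 + b
        nodes.append(TaxonomyNode(bid, _VIRUSES, "no_rank", f"uncultured virus {b}"))
        broad.append(bid)
    return TaxonomyTree(nodes), cress_species, other_species, broad


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(("A", "C", "G", "T"), size=length))


def simulate_reference_db(
    tree: TaxonomyTree,
    rng: np.random.Generator,
    genome_length: tuple[int, int] = (2000, 3000),
    genus_divergence: float = 0.12,
    species_divergence: float = 0.08,
) -> list[LabeledSequence]:
    """One genome per species/broad leaf, related within families.

    Each family gets an ancestral random genome; genus ancestors diverge
    from it by ``genus_divergence`` substitutions and species by a
    further ``species_divergence``, so congeners share ~80-85% identity.
    Deterministic given the generator state.
    """
    db = []
    for fam in sorted(tree.children(_VIRUSES)):
        if tree.rank(fam) == "no_rank":  # broad-category pseudo-leaf
            length = int(rng.integers(*genome_length))
            db.append(LabeledSequence(f"ref_{fam}", fam, _random_seq(rng, length)))
            continue
        length = int(rng.integers(*genome_length))
        ancestor = LabeledSequence(f"anc_{fam}", fam, _random_seq(rng, length))
        for gen in tree.children(fam):
            gseed = int(rng.integers(2**31 - 1))
            genus_anc = mutate_sequence(ancestor, genus_divergence, gseed)
            for sp in tree.children(gen):
                sseed = int(rng.integers(2**31 - 1))
                genome = mutate_sequence(genus_anc, species_divergence, sseed)
                db.append(LabeledSequence(f"ref_{sp}", sp, genome.sequence))
    return db


# --------------------------------------------------------------------------
# pool construction

def _nb_reads(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    # negative binomial parameterised by mean and dispersion (size)
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def _longest_conserved_run(a: str, b: str) -> int:
    best = run = 0
    for x, y in zip(a, b):
        run = run + 1 if x == y else 0
        best = max(best, run)
    return best


def _make_contig(
    rng: np.random.Generator,
    genome: str,
    rate: float,
    target_coverage: float,
    total_length: int,
    min_conserved_run: int = 20,
) -> tuple[str, float]:
    """A contig containing a mutated genome fragment at ``target_coverage``
    percent of its length, flanked by random sequence.

    Mutations are resampled (same rate) until the fragment retains a
    conserved stretch of at least ``min_conserved_run`` nt, mimicking the
    locally conserved cores of real homologous islands and keeping every
    planted contig discoverable by a word-seeded search.
    """
    core_len = max(60, round(total_length * target_coverage / 100.0))
    core_len = min(core_len, len(genome), total_length)
    start = int(rng.integers(0, len(genome) - core_len + 1))
    core = genome[start : start + core_len]
    core_seq = LabeledSequence("core", 1, core)
    for attempt in range(200):
        mutated = mutate_sequence(
            core_seq, rate, int(rng.integers(2**31 - 1))
        ).sequence
        if _longest_conserved_run(core, mutated) >= min(
            min_conserved_run, core_len
        ):
            break
    n_flank = total_length - core_len
    left = int(rng.integers(0, n_flank + 1))
    seq = _random_seq(rng, left) + mutated + _random_seq(rng, n_flank - left)
    return seq, 100.0 * core_len / total_length


@dataclass
class SimulatedVirome:
    """Everything `simulate_pools` produces, in memory."""

    tree: TaxonomyTree
    host_map: HostGroupMap
    db: list[LabeledSequence]
    contigs: dict[str, list[LabeledSequence]]        # pool -> contigs
    hit_tables: dict[str, list[HitRecord]]           # pool -> hit rows
    control_hits: list[HitRecord]
    counts: list[ContigCounts]
    truth: GroundTruth

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        self.tree.write(out / "taxonomy.tsv")
        paths["taxonomy"] = out / "taxonomy.tsv"
        self.host_map.write(out / "host_groups.tsv")
        paths["host_groups"] = out / "host_groups.tsv"
        write_labeled_fasta(self.db, out / "reference_db.fasta")
        paths["reference_db"] = out / "reference_db.fasta"
        for pool, contigs in self.contigs.items():
            write_labeled_fasta(contigs, out / f"contigs_{pool}.fasta")
            write_hit_table(self.hit_tables[pool], out / f"hits_{pool}.tsv")
            paths[f"contigs_{pool}"] = out / f"contigs_{pool}.fasta"
            paths[f"hits_{pool}"] = out / f"hits_{pool}.tsv"
        write_hit_table(self.control_hits, out / "hits_control.tsv")
        paths["hits_control"] = out / "hits_control.tsv"
        write_counts_table(self.counts, out / "counts.tsv")
        paths["counts"] = out / "counts.tsv"
        (out / "ground_truth.json").write_text(self.truth.to_json())
        paths["ground_truth"] = out / "ground_truth.json"
        return paths


def _alignment_to_hit(res, query: LabeledSequence, db_length: int) -> HitRecord:
    return HitRecord(
        query_id=query.seq_id,
        query_length=len(query),
        subject_id=res.subject_id,
        subject_taxid=res.subject_taxid,
        percent_identity=round(res.identity, 3),
        align_length=res.aligned_columns,
        mismatches=res.mismatches,
        gap_opens=res.gap_opens,
        q_start=res.q_span[0],
        q_end=res.q_span[1],
        s_start=res.s_span[0],
        s_end=res.s_span[1],
        evalue=max(res.evalue(len(query), db_length), 1e-180),
        bitscore=round(res.bitscore, 1),
    )


def simulate_pools(
    design: SimulationDesign | None = None,
    rng_seed: int | None = None,
    scoring: ScoringScheme | None = None,
    seed_kmer: int | None = 13,
    search_top_n: int = 25,
) -> SimulatedVirome:
    """Generate the full synthetic study from a design.

    Hit tables are produced by genuinely searching each contig against
    the reference database (with a shared-k-mer prescreen by default),
    so they carry the same imperfections a real BLAST table would:
    congener hits, alignments extending into random flanks, and spurious
    low-score matches.
    """
    design = design or SimulationDesign()
    design.validate()
    scoring = scoring or ScoringScheme()
    rng = np.random.default_rng(design.rng_seed if rng_seed is None else rng_seed)

    # --- allocate taxa to pools -------------------------------------------
    n_union = design.n_pools * design.taxa_per_pool - sum(
        design.shared_pairs.values()
    )
    classes = [
        _NOVEL if rng.random() < design.novel_fraction else _HIGH
        for _ in range(n_union)
    ]
    cress_flags = [
        rng.random() < design.cress_fraction_by_class[c] for c in classes
    ]
    n_cress = sum(cress_flags) + design.n_decoy_taxa // 2
    n_other = (n_union - sum(cress_flags)) + (
        design.n_decoy_taxa - design.n_decoy_taxa // 2
    )
    tree, cress_species, other_species, broad_taxa = simulate_taxonomy(
        n_cress, n_other, design.n_broad_taxa
    )
    db = simulate_reference_db(tree, rng, design.genome_length)
    genome_by_taxid = {s.tax_id: s.sequence for s in db}

    cress_pool = list(cress_species)
    other_pool = list(other_species)
    union_taxa: list[int] = []
    for cress in cress_flags:
        union_taxa.append((cress_pool if cress else other_pool).pop(0))
    class_by_taxon = dict(zip(union_taxa, classes))

    # shared sets first (disjoint across pairs), then exclusive fill
    cursor = 0
    pool_taxa: dict[int, list[int]] = {i: [] for i in range(design.n_pools)}
    shared_sets: dict[str, list[int]] = {}
    for (i, j), k in sorted(design.shared_pairs.items()):
        chunk = union_taxa[cursor : cursor + k]
        cursor += k
        pool_taxa[i].extend(chunk)
        pool_taxa[j].extend(chunk)
        key = f"{design.pool_names[i]}|{design.pool_names[j]}"
        shared_sets[key] = list(chunk)
    for i in range(design.n_pools):
        need = design.taxa_per_pool - len(pool_taxa[i])
        chunk = union_taxa[cursor : cursor + need]
        cursor += need
        pool_taxa[i].extend(chunk)
    assert cursor == n_union

    # --- host groups -------------------------------------------------------
    labels = sorted(design.host_group_mix)
    probs = np.array([design.host_group_mix[l] for l in labels])
    all_species = cress_species + other_species
    host_entries = {
        t: labels[int(rng.choice(len(labels), p=probs))] for t in all_species
    }
    host_map = HostGroupMap(host_entries)

    # --- contaminant subjects (present in samples AND control) -------------
    contaminants = []
    for c in range(design.contaminant_subjects):
        length = int(rng.integers(*design.genome_length))
        contaminants.append(
            LabeledSequence(f"contam_{c}", _CONSTRUCTS, _random_seq(rng, length))
        )
    db_all = db + contaminants
    db_total_len = sum(len(s) for s in db_all)

    # --- build contigs per pool -------------------------------------------
    hi_id_mu, hi_id_sd, hi_cov_mu, hi_cov_sd = design.divergence_classes[_HIGH]
    no_id_mu, no_id_sd, no_cov_mu, no_cov_sd = design.divergence_classes[_NOVEL]

    # circular contigs live on high-confidence taxa of the first pool(s)
    high_slots = [
        (i, t)
        for i in range(design.n_pools)
        for t in pool_taxa[i]
        if class_by_taxon[t] == _HIGH
    ]
    if len(high_slots) < design.n_circular:
        raise DesignError("not enough high-confidence slots for circular contigs")
    circular_slots = set(high_slots[: design.n_circular])

    contigs: dict[str, list[LabeledSequence]] = {}
    counts: list[ContigCounts] = []
    truths: list[ContigTruth] = []
    for i in range(design.n_pools):
        pool = design.pool_names[i]
        pool_contigs: list[LabeledSequence] = []
        for t in pool_taxa[i]:
            cls = class_by_taxon[t]
            cid = f"{pool}_k{len(pool_contigs):03d}"
            genome = genome_by_taxid[t]
            if (i, t) in circular_slots:
                # full (mutated) genome plus exact terminal direct repeat
                rate = float(
                    np.clip(100.0 - rng.normal(hi_id_mu, hi_id_sd), 0.5, 25)) / 100.0
                base = mutate_sequence(
                    LabeledSequence(cid, t, genome), rate,
                    int(rng.integers(2**31 - 1)),
                )
                rep = int(rng.integers(design.min_terminal_repeat_len,
                                       design.max_terminal_repeat_len + 1))
                seq = base.sequence + base.sequence[:rep]
                pool_contigs.append(LabeledSequence(cid, t, seq))
                truths.append(ContigTruth(cid, pool, t, cls, rate, True, rep, 100.0))
            else:
                if cls == _HIGH:
                    rate = float(np.clip(100.0 - rng.normal(hi_id_mu, hi_id_sd),
                                         0.5, 25)) / 100.0
                    cov = float(np.clip(rng.normal(hi_cov_mu, hi_cov_sd), 66, 99))
                else:
                    rate = float(np.clip(100.0 - rng.normal(no_id_mu, no_id_sd),
                                         0.5, 30)) / 100.0
                    cov = float(np.clip(rng.normal(no_cov_mu, no_cov_sd), 8, 52))
                total = int(rng.integers(*design.contig_length))
                seq, realized = _make_contig(rng, genome, rate, cov, total)
                pool_contigs.append(LabeledSequence(cid, t, seq))
                truths.append(
                    ContigTruth(cid, pool, t, cls, rate, False, 0, realized)
                )
            counts.append(
                ContigCounts(cid, len(pool_contigs[-1]),
                             _nb_reads(rng, design.mean_reads, design.nb_dispersion),
                             pool)
            )
        # contaminant contigs: near-copies of the contaminant subjects
        for c, contam in enumerate(contaminants):
            cid = f"{pool}_contam{c:02d}"
            frag_len = int(rng.integers(*design.contig_length))
            start = int(rng.integers(0, len(contam) - frag_len + 1))
            frag = LabeledSequence(cid, _CONSTRUCTS,
                                   contam.sequence[start : start + frag_len])
            mut = mutate_sequence(frag, 0.02, int(rng.integers(2**31 - 1)))
            pool_contigs.append(LabeledSequence(cid, _CONSTRUCTS, mut.sequence))
            truths.append(ContigTruth(cid, pool, _CONSTRUCTS, "contaminant",
                                      0.02, False, 0, 100.0))
            counts.append(
                ContigCounts(cid, frag_len,
                             _nb_reads(rng, design.mean_reads, design.nb_dispersion),
                             pool)
            )
        # short decoys: below the minimum contig length, must be filtered out
        for s in range(design.n_short_decoys):
            cid = f"{pool}_short{s:02d}"
            t = pool_taxa[i][s % len(pool_taxa[i])]
            frag = genome_by_taxid[t][:450]
            pool_contigs.append(LabeledSequence(cid, t, frag))
            truths.append(ContigTruth(cid, pool, t, "short_decoy",
                                      0.0, False, 0, 100.0))
            counts.append(ContigCounts(cid, 450,
                                       _nb_reads(rng, design.mean_reads,
                                                 design.nb_dispersion), pool))
        contigs[pool] = pool_contigs

    # --- hit tables by real database search --------------------------------
    db_index = build_kmer_index(db_all, seed_kmer) if seed_kmer else None
    hit_tables: dict[str, list[HitRecord]] = {}
    for pool, pool_contigs in contigs.items():
        rows: list[HitRecord] = []
        for contig in pool_contigs:
            for res in search_database(contig, db_all, scoring=scoring,
                                       top_n=search_top_n, seed_kmer=seed_kmer,
                                       db_index=db_index):
                rows.append(_alignment_to_hit(res, contig, db_total_len))
        hit_tables[pool] = rows

    # the no-template control sees only the contaminant subjects
    control_rows: list[HitRecord] = []
    for c, contam in enumerate(contaminants):
        cid = f"CTRL_contam{c:02d}"
        frag_len = min(len(contam), 800)
        frag = LabeledSequence(cid, _CONSTRUCTS, contam.sequence[:frag_len])
        mut = mutate_sequence(frag, 0.01, int(rng.integers(2**31 - 1)))
        query = LabeledSequence(cid, _CONSTRUCTS, mut.sequence)
        for res in search_database(query, db_all, scoring=scoring,
                                   top_n=search_top_n, seed_kmer=seed_kmer,
                                   db_index=db_index):
            control_rows.append(_alignment_to_hit(res, query, db_total_len))

    truth = GroundTruth(
        pool_taxa={design.pool_names[i]: sorted(pool_taxa[i])
                   for i in range(design.n_pools)},
        shared_sets={k: sorted(v) for k, v in shared_sets.items()},
        contigs=truths,
        cress_taxa=sorted(cress_species),
        broad_taxa=sorted(broad_taxa),
        contaminant_subjects=[s.seq_id for s in contaminants],
        host_groups=host_entries,
        class_by_taxon=class_by_taxon,
    )
    return SimulatedVirome(
        tree=tree,
        host_map=host_map,
        db=db_all,
        contigs=contigs,
        hit_tables=hit_tables,
        control_hits=control_rows,
        counts=counts,
        truth=truth,
    )


def audit(virome: SimulatedVirome, config: PipelineConfig | None = None) -> list[str]:
    """Generator self-audit: recompute each planted contig's alignment to
    its own source genome and check consistency with the planted class.

    Returns a list of complaint strings naming offending contigs (empty
    when the emitted data are internally consistent).
    """
    from .align import local_align

    config = config or PipelineConfig()
    genome_by_taxid = {s.tax_id: s for s in virome.db}
    by_id = {
        c.seq_id: c for pool in virome.contigs.values() for c in pool
    }
    complaints = []
    for t in virome.truth.contigs:
        if t.true_class not in (_HIGH, _NOVEL):
            continue
        contig = by_id[t.contig_id]
        source = genome_by_taxid[t.source_taxid]
        res = local_align(contig, source)
        high = res.query_coverage > config.coverage_boundary
        if high != (t.true_class == _HIGH):
            complaints.append(
                f"{t.contig_id}: planted {t.true_class} but realized "
                f"coverage {res.query_coverage:.1f}%"
            )
        if t.circular:
            if not contig.sequence.startswith(
                contig.sequence[len(contig.sequence) - t.overlap_length :]
            ):
                complaints.append(f"{t.contig_id}: terminal repeat broken")
    return complaints
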