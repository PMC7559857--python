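"""Mutation-drift calibration of annotation confidence.

The experiment that motivates the 2D goodness-of-assignment analysis:
take a model sequence of known taxon, introduce random point mutations at
controlled rates (10-50% of positions), search a labelled database, and
record how the best hit's identity, query coverage and taxonomic
assignment degrade.  A best hit is counted as a *misassignment* when it
shares no ancestor with the true source taxon at or below a configured
rank (family by default).

On real data the original experiment ran against the full NCBI nt
database; here the database is user-supplied or synthetic, so the rate at
which drift sets in is a qualitative property of the database, not a
universal constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .align import AlignmentResult, LabeledSequence, search_database
from .config import ScoringScheme
from .taxonomy import TaxonomyTree

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def mutate_sequence(
    seq: LabeledSequence, rate: float, rng_seed: int
) -> LabeledSequence:
    """Substitute ``round(rate * len)`` distinct positions with a different base.

    Positions are drawn uniformly without replacement and each receives a
    uniformly chosen base different from the original, so the Hamming
    distance to the input equals the mutation count exactly.
    Deterministic given the seed.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"mutation rate must lie in [0, 1], got {rate}")
    rng = np.random.default_rng(rng_seed)
    n = len(seq.sequence)
    k = round(rate * n)
    arr = np.frombuffer(seq.sequence.encode(), dtype="S1").copy()
    positions = rng.choice(n, size=k, replace=False)
    for pos in positions:
        alternatives = _BASES[_BASES != arr[pos]]
        arr[pos] = alternatives[rng.integers(3)]
    return LabeledSequence(
        seq_id=f"{seq.seq_id}_mut{rate:g}",
        tax_id=seq.tax_id,
        sequence=arr.tobytes().decode(),
    )


@dataclass
class CalibrationPoint:
    """Aggregates over replicates at one mutation rate."""

    mutation_rate: float
    replicates: int
    mean_best_identity: float
    mean_best_coverage: float
    #: position-wise full-length identity of the mutants to the unmutated
    #: model sequence (100*(1-rate) by construction); the aligner's
    #: best-hit identity exceeds this at high rates because local
    #: alignment trims mismatch-rich ends
    mean_source_identity: float
    misassignment_fraction: float
    borderline: bool  # some but not all replicates misassigned


@dataclass
class CalibrationCurve:
    points: list[CalibrationPoint]
    #: per-replicate best hits, keyed by (rate, replicate index)
    best_hits: dict[tuple[float, int], AlignmentResult]
    #: per-replicate misassignment flags, same keys
    misassigned: dict[tuple[float, int], bool]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (p.mutation_rate, p.replicates, p.mean_best_identity,
                 p.mean_best_coverage, p.mean_source_identity,
                 p.misassignment_fraction, p.borderline)
                for p in self.points
            ],
            columns=["rate", "reps", "mean_best_identity", "mean_best_coverage",
                     "mean_source_identity", "misassignment_fraction",
                     "borderline"],
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def calibration_curve(
    seq: LabeledSequence,
    db: Sequence[LabeledSequence],
    tree: TaxonomyTree,
    rates: Sequence[float] = (0.1, 0.2, 0.25, 0.3, 0.4, 0.5),
    reps: int = 30,
    rng_seed: int = 0,
    scoring: ScoringScheme | None = None,
    related_rank: str = "family",
    seed_kmer: int | None = None,
) -> CalibrationCurve:
    """Run the mutate-and-search experiment over a grid of rates.

    For each rate and replicate the model sequence is independently
    mutated, searched against ``db``, and the single best hit recorded.
    A replicate with no hit at all counts as misassigned (the annotation
    is lost entirely).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if seq.tax_id not in tree:
        raise KeyError(f"true taxon {seq.tax_id} absent from taxonomy")
    scoring = scoring or ScoringScheme()

    seed_root = np.random.default_rng(rng_seed)
    points = []
    best_hits: dict[tuple[float, int], AlignmentResult] = {}
    misassigned: dict[tuple[float, int], bool] = {}
    for rate in rates:
        idents, covs, src_idents, miss = [], [], [], []
        for rep in range(reps):
            rep_seed = int(seed_root.integers(2**31 - 1))
            mutant = mutate_sequence(seq, rate, rep_seed)
            src_idents.append(
                100.0
                * sum(x == y for x, y in zip(mutant.sequence, seq.sequence))
                / len(seq.sequence)
            )
            results = search_database(
                mutant, db, scoring=scoring, top_n=1, seed_kmer=seed_kmer
            )
            if results:
                best = results[0]
                best_hits[(rate, rep)] = best
                idents.append(best.identity)
                covs.append(best.query_coverage)
                bad = not tree.related_below_rank(
                    best.subject_taxid, seq.tax_id, related_rank
                )
            else:
                bad = True
            miss.append(bad)
            misassigned[(rate, rep)] = bad
        frac = float(np.mean(miss))
        points.append(
            CalibrationPoint(
                mutation_rate=float(rate),
                replicates=reps,
                mean_best_identity=float(np.mean(idents)) if idents else 0.0,
                mean_best_coverage=float(np.mean(covs)) if covs else 0.0,
                mean_source_identity=float(np.mean(src_idents)),
                misassignment_fraction=frac,
                borderline=0.0 < frac < 1.0,
            )
        )
    return CalibrationCurve(points, best_hits, misassigned)
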