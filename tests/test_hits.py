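"""Hit-table parsing, filtering rules and per-taxon clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from virofit.config import PipelineConfig
from virofit.hits import (
    ExclusionSet,
    HitRecord,
    cluster_by_taxon,
    filter_hits,
    query_coverage,
    read_hit_table,
    write_hit_table,
)


def make_hit(qid="q1", sid="s1", taxid=5, qlen=1000, qs=1, qe=500,
             evalue=1e-20, bitscore=100.0, pident=90.0):
    return HitRecord(qid, qlen, sid, taxid, pident, qe - qs + 1, 10, 0,
                     qs, qe, 1, qe - qs + 1, evalue, bitscore)


class TestQueryCoverage:
    def test_full_span(self):
        assert query_coverage(make_hit(qs=1, qe=100, qlen=100)) == 100.0

    def test_partial_span(self):
        assert query_coverage(make_hit(qs=21, qe=80, qlen=100)) == 60.0

    @given(
        qlen=st.integers(10, 10_000),
        data=st.data(),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_direct_formula(self, qlen, data):
        qs = data.draw(st.integers(1, qlen))
        qe = data.draw(st.integers(qs, qlen))
        h = make_hit(qs=qs, qe=qe, qlen=qlen)
        assert query_coverage(h) == pytest.approx(100.0 * (qe - qs + 1) / qlen)
        assert 0.0 < query_coverage(h) <= 100.0


class TestReadWrite:
    def test_round_trip_100_rows(self, tmp_path):
        rng = np.random.default_rng(0)
        records = []
        for i in range(100):
            qlen = int(rng.integers(600, 2000))
            qs = int(rng.integers(1, qlen // 2))
            qe = int(rng.integers(qs, qlen))
            records.append(
                make_hit(qid=f"q{i}", sid=f"s{i % 7}", taxid=int(rng.integers(1, 50)),
                         qlen=qlen, qs=qs, qe=qe,
                         evalue=float(10.0 ** -rng.integers(5, 50)),
                         bitscore=float(rng.uniform(40, 900)),
                         pident=float(np.round(rng.uniform(60, 100), 3)))
            )
        p = tmp_path / "hits.tsv"
        write_hit_table(records, p)
        again = read_hit_table(p)
        assert again == records

    def test_sidecar_mapping(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("q1\ts1\t90.0\t500\t10\t0\t1\t500\t1\t500\t1e-20\t100.0\n")
        recs = read_hit_table(p, query_lengths={"q1": 1000}, subject_taxa={"s1": 5})
        assert len(recs) == 1
        assert recs[0].query_length == 1000 and recs[0].subject_taxid == 5

    def test_invalid_row_rejected_and_counted(self, tmp_path, caplog):
        good = make_hit()
        bad = "q2\ts1\t90.0\t500\t10\t0\t1\t5000\t1\t500\t1e-20\t100.0\t1000\t5\n"
        p = tmp_path / "hits.tsv"
        write_hit_table([good], p)
        with open(p, "a") as fh:
            fh.write(bad)
        with caplog.at_level("WARNING"):
            recs = read_hit_table(p)
        assert recs == [good]
        assert any("rejected" in r.message for r in caplog.records)


class TestFilterHits:
    def test_keeps_top_25_of_30(self, config):
        hits = [make_hit(sid=f"s{i}", bitscore=200.0 - i) for i in range(30)]
        kept = filter_hits(hits, config=config)
        assert len(kept) == 25
        assert min(h.bitscore for h in kept) == 200.0 - 24

    def test_evalue_threshold(self, config):
        hits = [make_hit(evalue=1e-4), make_hit(sid="s2", evalue=1e-6)]
        kept = filter_hits(hits, config=config)
        assert [h.subject_id for h in kept] == ["s2"]

    def test_short_queries_dropped(self, config):
        hits = [make_hit(qlen=499, qe=400), make_hit(qid="q2")]
        kept = filter_hits(hits, config=config)
        assert {h.query_id for h in kept} == {"q2"}

    def test_excluded_subjects_match_set_difference_oracle(self, config):
        rng = np.random.default_rng(3)
        subjects = [f"s{i}" for i in range(20)]
        control = set(rng.choice(subjects, size=6, replace=False).tolist())
        hits = [
            make_hit(qid=f"q{i % 5}", sid=subjects[int(rng.integers(20))],
                     bitscore=float(rng.uniform(50, 300)))
            for i in range(120)
        ]
        ex = ExclusionSet(control_subjects=control)
        kept = filter_hits(hits, ex, config)
        # oracle: every surviving subject is outside the control set, and
        # every removed row either hits the control set or overflowed top-N
        assert all(h.subject_id not in control for h in kept)
        survivors_expected = [h for h in hits if h.subject_id not in control]
        assert set(h.subject_id for h in kept) <= set(
            h.subject_id for h in survivors_expected
        )

    def test_idempotent(self, config):
        rng = np.random.default_rng(4)
        hits = [
            make_hit(qid=f"q{i % 3}", sid=f"s{i}", bitscore=float(rng.uniform(50, 300)),
                     evalue=float(10.0 ** -rng.integers(2, 40)))
            for i in range(60)
        ]
        once = filter_hits(hits, config=config)
        twice = filter_hits(once, config=config)
        assert once == twice


class TestClusterByTaxon:
    def test_single_query_cluster(self):
        h = make_hit(qs=1, qe=500, pident=88.0)
        (c,) = cluster_by_taxon({"q1": (h, 5)})
        assert c.tax_id == 5 and c.n_contigs == 1
        assert c.mean_identity == 88.0
        assert c.mean_query_coverage == query_coverage(h)

    def test_two_member_arithmetic(self):
        h1 = make_hit(qid="q1", pident=80.0, qs=1, qe=400, qlen=1000)   # 40%
        h2 = make_hit(qid="q2", pident=90.0, qs=1, qe=600, qlen=1000)   # 60%
        (c,) = cluster_by_taxon({"q1": (h1, 5), "q2": (h2, 5)})
        assert c.mean_identity == 85.0
        assert c.mean_query_coverage == 50.0
        assert c.per_subject_breakdown["s1"] == (85.0, 50.0)

    def test_group_by_oracle_200_assignments(self):
        rng = np.random.default_rng(9)
        best = {}
        rows = []
        for i in range(200):
            taxid = int(rng.integers(1, 20))
            qlen = int(rng.integers(600, 1500))
            qe = int(rng.integers(100, qlen))
            h = make_hit(qid=f"q{i}", sid=f"s{taxid}_{int(rng.integers(2))}",
                         taxid=taxid, qlen=qlen, qs=1, qe=qe,
                         pident=float(rng.uniform(60, 100)))
            best[f"q{i}"] = (h, taxid)
            rows.append((taxid, h.percent_identity, query_coverage(h)))
        clusters = {c.tax_id: c for c in cluster_by_taxon(best)}
        df = pd.DataFrame(rows, columns=["tax", "ident", "cov"])
        oracle = df.groupby("tax").agg(["mean", "count"])
        for tax, c in clusters.items():
            assert c.mean_identity == pytest.approx(oracle.loc[tax, ("ident", "mean")])
            assert c.mean_query_coverage == pytest.approx(oracle.loc[tax, ("cov", "mean")])
            assert c.n_contigs == oracle.loc[tax, ("ident", "count")]
        # conservation: cluster sizes sum to number of assigned queries
        assert sum(c.n_contigs for c in clusters.values()) == 200

    def test_means_bounded_by_member_extremes(self):
        h1 = make_hit(qid="q1", pident=70.0)
        h2 = make_hit(qid="q2", pident=95.0)
        (c,) = cluster_by_taxon({"q1": (h1, 5), "q2": (h2, 5)})
        assert 70.0 <= c.mean_identity <= 95.0
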