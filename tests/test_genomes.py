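"""Circularity detection, species demarcation and in-silico PCR."""

import numpy as np
import pytest
from Bio.Seq import Seq

from virofit.align import LabeledSequence
from virofit.config import PipelineConfig
from virofit.genomes import (
    PrimerPair,
    demarcate,
    detect_circularity,
    genome_identity,
    insilico_pcr,
    load_primers,
)
from virofit.calibration import mutate_sequence

from _oracles import gotoh_score


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _ls(seq, seq_id="s", taxid=1):
    return LabeledSequence(seq_id, taxid, seq)


class TestDetectCircularity:
    def test_constructed_terminal_repeat(self):
        rng = np.random.default_rng(1)
        for k in (20, 77, 141):
            genome = _rand_seq(rng, 1000)
            contig = _ls(genome + genome[:k], seq_id=f"c{k}")
            call = detect_circularity(contig, min_overlap=20)
            assert call.is_circular and call.overlap_length == k
            assert call.trimmed_sequence == genome
            # round trip: re-appending the repeat reproduces the input
            assert call.trimmed_sequence + call.trimmed_sequence[:k] == contig.sequence

    def test_random_sequences_are_linear(self):
        linear = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            call = detect_circularity(_ls(_rand_seq(rng, 1000)), min_overlap=20)
            linear += not call.is_circular
        assert linear == 50

    def test_short_contig_rejected(self):
        with pytest.raises(ValueError):
            detect_circularity(_ls("ACGT" * 10), min_overlap=20)

    def test_sub_threshold_repeat_stays_linear(self):
        rng = np.random.default_rng(2)
        genome = _rand_seq(rng, 500)
        contig = _ls(genome + genome[:10])
        assert not detect_circularity(contig, min_overlap=20).is_circular


class TestGenomeIdentity:
    def test_identical_sequences(self):
        rng = np.random.default_rng(3)
        s = _rand_seq(rng, 300)
        assert genome_identity(_ls(s, "a"), _ls(s, "b")) == 100.0

    def test_symmetric(self):
        rng = np.random.default_rng(4)
        a, b = _ls(_rand_seq(rng, 150), "a"), _ls(_rand_seq(rng, 160), "b")
        assert genome_identity(a, b) == pytest.approx(genome_identity(b, a))

    def test_reverse_complement_is_dissimilar(self):
        count = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            s = _rand_seq(rng, 1000)
            rc = str(Seq(s).reverse_complement())
            count += genome_identity(_ls(s, "a"), _ls(rc, "b")) < 70.0
        assert count == 10

    def test_global_scores_match_dp_oracle(self):
        # the identity path rides on the same global DP; validate scores
        from Bio import Align

        rng = np.random.default_rng(5)
        al = Align.PairwiseAligner(mode="global", match_score=2,
                                   mismatch_score=-3, open_gap_score=-5,
                                   extend_gap_score=-2)
        for _ in range(60):
            a = _rand_seq(rng, int(rng.integers(10, 80)))
            b = _rand_seq(rng, int(rng.integers(10, 80)))
            assert al.score(a, b) == pytest.approx(gotoh_score(a, b, mode="global"))

    def test_circular_rotation_recovered(self):
        rng = np.random.default_rng(6)
        genome = _rand_seq(rng, 800)
        mutated = mutate_sequence(_ls(genome, "g"), 0.1, 5).sequence
        rotated = mutated[300:] + mutated[:300]
        ident = genome_identity(_ls(rotated, "a"), _ls(genome, "b"), circular=True)
        assert ident == pytest.approx(90.0, abs=1.5)
        # without rotation handling the registers disagree badly
        assert genome_identity(_ls(rotated, "a"), _ls(genome, "b")) < ident


class TestDemarcate:
    @pytest.mark.parametrize(
        "identity,verdict",
        [(78.0, "variant"), (74.9, "novel_species"), (75.0, "variant")],
    )
    def test_boundary(self, identity, verdict):
        assert demarcate(identity).verdict == verdict

    def test_custom_threshold(self):
        cfg = PipelineConfig(demarcation_identity=90.0)
        assert demarcate(85.0, cfg).verdict == "novel_species"


class TestInsilicoPcr:
    FW = "ATCCAGCCGTAGAAGTCGTC"
    RV = "CGGAAAATCAAAGCGTGCAC"

    def _template(self, rng, insert_len=20):
        rv_rc = str(Seq(self.RV).reverse_complement())
        middle = _rand_seq(rng, insert_len)
        return self.FW + middle + rv_rc

    def test_constructed_product_length(self):
        rng = np.random.default_rng(7)
        core = self._template(rng, 20)
        template = _ls(_rand_seq(rng, 50) + core + _rand_seq(rng, 50))
        pair = PrimerPair("p", self.FW, self.RV, 200)
        assert insilico_pcr(template, pair) == [len(self.FW) + 20 + len(self.RV)]

    def test_absent_primers_no_product(self):
        rng = np.random.default_rng(8)
        pair = PrimerPair("p", self.FW, self.RV, 200)
        assert insilico_pcr(_ls(_rand_seq(rng, 400)), pair) == []

    def test_scan_oracle_with_planted_sites(self):
        rng = np.random.default_rng(9)
        pair = PrimerPair("p", self.FW, self.RV, 300)
        rv_rc = str(Seq(self.RV).reverse_complement())
        for _ in range(30):
            n_sites = int(rng.integers(0, 4))
            parts = [_rand_seq(rng, 60)]
            for _ in range(n_sites):
                parts.append(self._template(rng, int(rng.integers(5, 40))))
                parts.append(_rand_seq(rng, 80))
            template = "".join(parts)
            got = insilico_pcr(_ls(template), pair)
            # oracle: exhaustive scan over all (fw, rv_rc) position pairs
            fw_pos = [i for i in range(len(template))
                      if template.startswith(self.FW, i)]
            rv_pos = [i for i in range(len(template))
                      if template.startswith(rv_rc, i)]
            expect = sorted({
                r + len(rv_rc) - f
                for f in fw_pos for r in rv_pos
                if len(self.FW) + len(self.RV) <= r + len(rv_rc) - f <= 300
            })
            assert got == expect

    def test_circular_template_rotation_invariant(self):
        rng = np.random.default_rng(10)
        core = self._template(rng, 30)
        genome = core + _rand_seq(rng, 500)
        pair = PrimerPair("p", self.FW, self.RV, 200)
        base = insilico_pcr(_ls(genome), pair, circular=True)
        assert base  # product exists
        for shift in (13, 250, 499):
            rotated = genome[shift:] + genome[:shift]
            assert insilico_pcr(_ls(rotated), pair, circular=True) == base

    def test_wrap_around_product(self):
        rng = np.random.default_rng(11)
        rv_rc = str(Seq(self.RV).reverse_complement())
        # forward primer near the end, reverse site after the origin
        genome = rv_rc + _rand_seq(rng, 400) + self.FW + _rand_seq(rng, 5)
        pair = PrimerPair("p", self.FW, self.RV, 200)
        assert insilico_pcr(_ls(genome), pair, circular=False) == []
        wrapped = insilico_pcr(_ls(genome), pair, circular=True)
        assert wrapped == [len(self.FW) + 5 + len(rv_rc)]

    def test_primer_validation(self):
        with pytest.raises(ValueError):
            PrimerPair("p", "ACGTN", self.RV, 200)
        with pytest.raises(ValueError):
            PrimerPair("p", self.FW, self.RV, 10)

    def test_load_primers(self, tmp_path):
        p = tmp_path / "primers.tsv"
        p.write_text(
            "name\tforward\treverse\tmax_amplicon\n"
            f"pair1\t{self.FW}\t{self.RV}\t200\n"
        )
        pairs = load_primers(p)
        assert pairs[0].name == "pair1" and pairs[0].max_amplicon == 200
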