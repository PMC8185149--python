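"""Candidate filtering, positional classification, coding potential and
the all-predictor consensus."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from droughtlnc.identify import (
    CodingLabelSet,
    classify_by_class_code,
    consensus_noncoding,
    fickett_score,
    filter_candidates,
    hexamer_llr,
    max_orf_codons,
    read_label_tsv,
    score_coding_potential,
    train_hexamer_tables,
    predictor_tally,
)
from droughtlnc.model import ExpressionMatrix, Transcript, ValidationError


def _tx(tid, length=500, n_exons=2, class_code="u"):
    half = length // 2
    exons = (
        ((1, length),)
        if n_exons == 1
        else ((1, half), (half + 101, half + 100 + (length - half)))
    )
    return Transcript(tid, tid, "chr1", exons[0][0], exons[-1][1], "+", exons, class_code)


def _counts(ids, total=100, n_samples=4):
    per = total // n_samples
    rem = total - per * (n_samples - 1)
    row = [per] * (n_samples - 1) + [rem]
    df = pd.DataFrame([row] * len(ids), index=ids,
                      columns=[f"s{i}" for i in range(n_samples)])
    return ExpressionMatrix(df, "counts")


class TestFilters:
    def test_length_exactly_200_rejected(self):
        t = _tx("t1", length=200)
        (res,) = filter_candidates([t], _counts(["t1"]), set())
        assert not res.flags["length"] and not res.passed

    def test_single_exon_rejected_on_exon_rule(self):
        t = _tx("t1", length=500, n_exons=1)
        (res,) = filter_candidates([t], _counts(["t1"]), set())
        assert not res.flags["exons"] and res.flags["length"]

    def test_boundary_retained_length_201_exons_2_reads_5(self):
        t = _tx("t1", length=201)
        (res,) = filter_candidates([t], _counts(["t1"], total=5), set())
        assert res.passed

    def test_known_id_rejected_with_flag(self):
        t = _tx("t1")
        (res,) = filter_candidates([t], _counts(["t1"]), {"t1"})
        assert not res.flags["known"] and res.flags["length"]

    def test_non_uix_class_rejected(self):
        t = _tx("t1", class_code="j")
        (res,) = filter_candidates([t], _counts(["t1"]), set())
        assert not res.flags["class_code"]

    def test_total_vs_every_sample_read_modes(self):
        t = _tx("t1")
        counts = _counts(["t1"], total=8, n_samples=4)  # 2 reads per sample
        (res,) = filter_candidates([t], counts, set(), min_reads=5, read_mode="total")
        assert res.flags["reads"]
        (res,) = filter_candidates(
            [t], counts, set(), min_reads=5, read_mode="every_sample"
        )
        assert not res.flags["reads"]

    def test_missing_transcript_in_counts_is_error(self):
        with pytest.raises(ValidationError, match="t1"):
            filter_candidates([_tx("t1")], _counts(["other"]), set())

    def test_filter_idempotent(self, study):
        first = filter_candidates(study.transcripts, study.counts, study.known_ids)
        survivors = [r.transcript for r in first if r.passed]
        second = filter_candidates(survivors, study.counts, study.known_ids)
        assert all(r.passed for r in second)
        assert [r.transcript for r in second] == survivors

    @given(st.integers(min_value=0, max_value=500))
    @settings(max_examples=20, deadline=None)
    def test_raising_min_reads_never_grows_retained_set(self, extra):
        ids = [f"t{i}" for i in range(6)]
        txs = [_tx(i) for i in ids]
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.integers(0, 40, size=(6, 4)), index=ids,
                          columns=[f"s{i}" for i in range(4)])
        counts = ExpressionMatrix(df, "counts")
        low = {r.transcript.transcript_id
               for r in filter_candidates(txs, counts, set(), min_reads=5)
               if r.passed}
        high = {r.transcript.transcript_id
                for r in filter_candidates(txs, counts, set(), min_reads=5 + extra)
                if r.passed}
        assert high <= low


class TestClassification:
    def test_class_codes_map_to_positional_classes(self):
        lnc = classify_by_class_code([_tx("a", class_code="u"),
                                      _tx("b", class_code="i"),
                                      _tx("c", class_code="x")])
        classes = {c.transcript_id: c.positional_class for c in lnc}
        assert classes == {"a": "lincRNA", "b": "intronic", "c": "antisense"}

    def test_unfiltered_class_code_is_contract_error(self):
        with pytest.raises(ValidationError, match="filtered"):
            classify_by_class_code([_tx("a", class_code="j")])


class TestConsensus:
    def _set(self, name, label):
        return CodingLabelSet(name, {"t1": label})

    def test_all_noncoding_gives_consensus(self):
        lnc = classify_by_class_code([_tx("t1")])
        sets = [self._set(f"p{i}", "noncoding") for i in range(4)]
        lnc = consensus_noncoding(lnc, sets)
        assert lnc.calls["t1"].consensus_noncoding

    def test_one_coding_vote_breaks_consensus(self):
        lnc = classify_by_class_code([_tx("t1")])
        sets = [self._set(f"p{i}", "noncoding") for i in range(3)]
        sets.append(self._set("p3", "coding"))
        lnc = consensus_noncoding(lnc, sets)
        assert not lnc.calls["t1"].consensus_noncoding

    def test_single_predictor_degenerate_and(self):
        lnc = classify_by_class_code([_tx("t1")])
        lnc = consensus_noncoding(lnc, [self._set("only", "noncoding")])
        assert lnc.calls["t1"].consensus_noncoding

    def test_missing_transcript_treated_as_coding_with_warning(self):
        lnc = classify_by_class_code([_tx("t1")])
        with pytest.warns(UserWarning, match="missing"):
            lnc = consensus_noncoding(lnc, [CodingLabelSet("p", {})])
        assert not lnc.calls["t1"].consensus_noncoding

    def test_no_label_sets_is_error(self):
        with pytest.raises(ValidationError):
            consensus_noncoding(classify_by_class_code([_tx("t1")]), [])

    def test_tally_counts_noncoding_per_predictor(self):
        lnc = classify_by_class_code([_tx("t1"), _tx("t2")])
        sets = [CodingLabelSet("a", {"t1": "noncoding", "t2": "noncoding"}),
                CodingLabelSet("b", {"t1": "noncoding", "t2": "coding"})]
        tally = predictor_tally(consensus_noncoding(lnc, sets))
        assert tally == {"a": 2, "b": 1, "consensus": 1}


class TestOrf:
    def test_constructed_orf_length_found(self):
        seq = "ATG" + "GCT" * 150 + "TAA"
        assert max_orf_codons(seq) == 151

    def test_orf_detected_in_any_forward_frame(self):
        core = "ATG" + "GCT" * 120 + "TAA"
        for lead in ("", "C", "CC"):
            assert max_orf_codons(lead + core) == 121

    def test_open_orf_counts_to_sequence_end(self):
        seq = "ATG" + "GCT" * 50  # no stop
        assert max_orf_codons(seq) == 51

    def test_matches_brute_force_scan_on_random_sequences(self):
        rng = np.random.default_rng(11)
        stops = {"TAA", "TAG", "TGA"}
        for _ in range(50):
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
            best = 0
            for frame in range(3):
                codons = [seq[i:i + 3] for i in range(frame, len(seq) - 2, 3)]
                for i, c in enumerate(codons):
                    if c == "ATG":
                        length = 0
                        for c2 in codons[i:]:
                            if c2 in stops and length > 0:
                                break
                            length += 1
                        best = max(best, length)
            assert max_orf_codons(seq) == best


class TestCodingPotential:
    def test_long_orf_labelled_coding(self):
        seqs = {"c1": "ATG" + "GAA" * 150 + "TAA", "n1": "ACGT" * 100}
        labels = score_coding_potential(seqs)
        assert labels.labels["c1"] == "coding"

    def test_random_sequence_without_orf_noncoding(self):
        rng = np.random.default_rng(5)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
        assert max_orf_codons(seq) < 100  # guaranteed by this seed
        labels = score_coding_potential({"x": seq, "c": "ATG" + "GAA" * 120 + "TAA"})
        assert labels.labels["x"] == "noncoding"

    def test_empty_sequence_is_error(self):
        with pytest.raises(ValidationError, match="empty"):
            score_coding_potential({"x": ""})

    def test_non_acgtn_characters_rejected(self):
        with pytest.raises(ValidationError, match="non-ACGTN"):
            score_coding_potential({"x": "ACGTU"})

    def test_fickett_higher_for_periodic_than_random(self):
        rng = np.random.default_rng(0)
        random_seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 600)])
        periodic = "ATGGCA" * 100  # strong 3-periodicity
        assert fickett_score(periodic) > fickett_score(random_seq)

    def test_hexamer_llr_separates_trained_classes(self, study):
        c_tab, b_tab = train_hexamer_tables(study.sequences)
        coding = study.truth.coding_ids[:10]
        noncoding = study.truth.all_lncrna_ids[:10]
        c_scores = [hexamer_llr(study.sequences[i], c_tab, b_tab) for i in coding]
        n_scores = [hexamer_llr(study.sequences[i], c_tab, b_tab) for i in noncoding]
        assert min(c_scores) > np.median(n_scores)

    def test_per_component_returns_three_label_sets(self, study):
        seqs = {i: study.sequences[i]
                for i in study.truth.coding_ids[:5] + study.truth.all_lncrna_ids[:5]}
        sets = score_coding_potential(seqs, per_component=True)
        assert [s.predictor_name for s in sets] == ["orf", "fickett", "hexamer"]
        orf = sets[0].labels
        assert all(orf[i] == "coding" for i in study.truth.coding_ids[:5])

    def test_builtin_separates_fixture_perfectly(self, study):
        labels = score_coding_potential(study.sequences)
        assert all(labels.labels[i] == "coding" for i in study.truth.coding_ids)
        assert all(
            labels.labels[i] == "noncoding" for i in study.truth.all_lncrna_ids
        )


class TestLabelIo:
    def test_label_tsv_reader(self, tmp_path):
        p = tmp_path / "cpc.tsv"
        p.write_text("t1\tnoncoding\nt2\tcoding\n")
        ls = read_label_tsv(p)
        assert ls.predictor_name == "cpc"
        assert ls.labels == {"t1": "noncoding", "t2": "coding"}

    def test_bad_label_value_rejected(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text("t1\tmaybe\n")
        with pytest.raises(ValidationError, match="maybe"):
            read_label_tsv(p)
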