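"""Candidate uORF enumeration, classification, Kozak and isoform collapse."""

import numpy as np
import pytest

from uorfkit.transcript_model import TranscriptModel, TranscriptSequence
from uorfkit.uorf_discovery import (
    DEFAULT_START_CODONS,
    STOP_CODONS,
    classify,
    collapse_isoforms,
    enumerate_candidates,
    kozak_strength,
    translate_orf,
)

from conftest import make_transcript, single_exon_model


def brute_force_candidates(model, seq, start_codons=DEFAULT_START_CODONS, min_len_nt=18):
    """Independent oracle: test every (position, frame) pair separately.

    For each start-codon occurrence upstream of the CDS start, walk codons
    one by one to the first stop; rescue stop-less in-frame ORFs as
    extensions ending at the CDS stop.  Returns (tx_start, tx_end, category)
    triples.
    """
    s = seq.seq if isinstance(seq, TranscriptSequence) else seq
    found = []
    for p in range(model.cds_tx_start):
        if s[p : p + 3] not in start_codons:
            continue
        end = None
        for q in range(p + 3, len(s) - 2, 3):
            if s[q : q + 3] in STOP_CODONS:
                end = q + 3
                break
        if end is None:
            if (p - model.cds_tx_start) % 3 == 0 and (model.cds_tx_end - p) % 3 == 0:
                end = model.cds_tx_end
            else:
                continue
        if end - 3 - p < min_len_nt:
            continue
        if end <= model.cds_tx_start:
            cat = "non_overlapping"
        elif (p - model.cds_tx_start) % 3 == 0:
            cat = "n_terminal_extension"
        else:
            cat = "overlapping_out_of_frame"
        found.append((p, end, cat))
    return found


def random_transcript(rng, utr_max=600, tid="T"):
    utr_len = int(rng.integers(0, utr_max + 1))
    cds_codons = int(rng.integers(10, 60))
    utr3_len = int(rng.integers(0, 100))
    bases = "ACGT"
    utr5 = "".join(bases[i] for i in rng.integers(0, 4, size=utr_len))
    cds = "ATG" + "".join(
        np.random.default_rng(int(rng.integers(0, 2**31))).choice(
            [c for c in _sense_codons()], size=cds_codons - 2
        )
    ) + "TAA"
    utr3 = "".join(bases[i] for i in rng.integers(0, 4, size=utr3_len))
    return make_transcript(utr5, cds, utr3, tid=tid)


def _sense_codons():
    from itertools import product

    return ["".join(c) for c in product("ACGT", repeat=3) if "".join(c) not in STOP_CODONS]


class TestEnumerate:
    def test_no_start_codon_yields_nothing(self):
        model, seq = make_transcript("AAAACCCC", "ATG" + "GCT" * 8 + "TAA")
        assert enumerate_candidates(model, seq) == []

    def test_minimal_non_overlapping_uorf(self):
        """ATG + 5 sense codons + TAA (18 nt coding) fully upstream of CDS."""
        utr5 = "CC" + "ATG" + "GCC" * 5 + "TAA" + "CCCC"
        model, seq = make_transcript(utr5, "ATG" + "GCA" * 10 + "TAA")
        cands = enumerate_candidates(model, seq)
        assert len(cands) == 1
        c = cands[0]
        assert (c.tx_start, c.tx_end) == (2, 23)
        assert c.tx_end - 3 - c.tx_start == 18
        assert c.category == "non_overlapping"

    def test_below_minimum_length_discarded(self):
        utr5 = "CC" + "ATG" + "GCC" * 4 + "TAA" + "CCCC"  # 15 nt coding
        model, seq = make_transcript(utr5, "ATG" + "GCA" * 10 + "TAA")
        assert enumerate_candidates(model, seq) == []

    def test_n_terminal_extension_shares_cds_stop(self):
        """In-frame UTR start with no intervening stop ends at the CDS stop."""
        utr5 = "C" + "ATG" + "GCT" * 6  # 21 nt, in frame with CDS start at 22
        model, seq = make_transcript(utr5, "ATG" + "GCA" * 10 + "TAA")
        cands = enumerate_candidates(model, seq)
        assert len(cands) == 1
        c = cands[0]
        assert c.category == "n_terminal_extension"
        assert c.tx_end == model.cds_tx_end
        assert c.frame_vs_cds == 0

    def test_overlapping_out_of_frame(self):
        """Start 2 nt upstream of the CDS stays out of frame and finds its
        stop inside the CDS (the CDS's +1-shift reads TGA at its 2nd base)."""
        utr5 = "C" * 30 + "ATG" + "GCC" * 5 + "CC"  # start 30, UTR len 50
        cds = "ATG" + "AAA" * 9 + "TAA"  # shifted frame reads "TGA" at cds[1:4]
        model, seq = make_transcript(utr5, cds)
        cands = enumerate_candidates(model, seq, start_codons=("ATG",))
        assert len(cands) == 1
        c = cands[0]
        assert c.category == "overlapping_out_of_frame"
        assert c.tx_end == model.cds_tx_start + 4  # stop TGA ends at cds base 4
        assert c.frame_vs_cds != 0

    def test_out_of_frame_without_stop_discarded(self):
        """An out-of-frame ORF reaching the transcript end with no stop is
        not a start-to-stop ORF."""
        utr5 = "CCC" + "ATG" + "GCC" * 6 + "C"  # start 3, frame +2 vs CDS
        cds = "ATG" + "GCA" * 10 + "TAA"
        model, seq = make_transcript(utr5, cds)  # no 3'UTR
        assert (3 - model.cds_tx_start) % 3 != 0
        shifted_stops = [
            seq.seq[q : q + 3] in STOP_CODONS
            for q in range(6, len(seq.seq) - 2, 3)
        ]
        assert not any(shifted_stops)
        assert enumerate_candidates(model, seq, start_codons=("ATG",)) == []

    def test_no_utr_yields_nothing(self):
        model, seq = make_transcript("", "ATG" + "GCA" * 10 + "TAA")
        assert enumerate_candidates(model, seq) == []

    def test_matches_brute_force_oracle_on_random_transcripts(self):
        """Oracle equivalence over random transcripts, UTR 0-600 nt."""
        rng = np.random.default_rng(7)
        n_with_candidates = 0
        for i in range(150):
            model, seq = random_transcript(rng, tid=f"T{i}")
            got = [(c.tx_start, c.tx_end, c.category) for c in enumerate_candidates(model, seq)]
            expected = brute_force_candidates(model, seq)
            assert got == expected
            n_with_candidates += bool(expected)
        assert n_with_candidates > 50  # the comparison is not vacuous

    def test_atg_only_is_subset_of_full_codon_set(self):
        rng = np.random.default_rng(11)
        for i in range(30):
            model, seq = random_transcript(rng, tid=f"T{i}")
            full = {c.uorf_id for c in enumerate_candidates(model, seq)}
            atg = {c.uorf_id for c in enumerate_candidates(model, seq, start_codons=("ATG",))}
            assert atg <= full

    def test_candidate_invariants_hold(self):
        """Every emitted candidate satisfies the structural invariants."""
        rng = np.random.default_rng(13)
        for i in range(60):
            model, seq = random_transcript(rng, tid=f"T{i}")
            for c in enumerate_candidates(model, seq):
                assert c.tx_start < model.cds_tx_start
                assert (c.tx_end - c.tx_start) % 3 == 0
                assert c.tx_end - c.tx_start >= 21
                assert (c.category == "non_overlapping") == (c.tx_end <= model.cds_tx_start)
                assert (c.category == "n_terminal_extension") == (
                    c.frame_vs_cds == 0 and c.tx_end > model.cds_tx_start
                )
                if c.category != "n_terminal_extension":
                    assert seq.seq[c.tx_end - 3 : c.tx_end] in STOP_CODONS
                assert sum(e - s for s, e in c.genomic_blocks) == c.tx_end - c.tx_start


class TestClassify:
    def test_three_way_partition(self):
        model = single_exon_model(100, 30, 90)
        assert classify(0, 24, model) == "non_overlapping"
        assert classify(0, 30, model) == "non_overlapping"
        assert classify(1, 40, model) == "overlapping_out_of_frame"
        assert classify(0, 90, model) == "n_terminal_extension"

    def test_start_in_cds_rejected(self):
        model = single_exon_model(100, 30, 90)
        with pytest.raises(ValueError):
            classify(30, 60, model)


class TestTranslate:
    def test_standard_codons(self):
        assert translate_orf("ATGGCCTAA", 0, 9) == "MA"

    def test_near_cognate_start_is_initiator_met(self):
        assert translate_orf("CTGGCCGATTTTAAAGGGTAA", 0, 21) == "MADFKG"

    def test_extension_peptide_is_n_extended_cds(self):
        utr5 = "C" + "ATG" + "GCT" * 6
        cds = "ATG" + "GCA" * 10 + "TAA"
        model, seq = make_transcript(utr5, cds)
        (c,) = enumerate_candidates(model, seq)
        cds_pep = translate_orf(seq.seq, model.cds_tx_start, model.cds_tx_end)
        assert c.peptide.endswith(cds_pep[1:])
        assert len(c.peptide) == len(cds_pep) + 7


class TestKozak:
    @pytest.mark.parametrize(
        "minus3, plus4, expected",
        [(m3, p4, exp) for m3 in "ACGT" for p4 in "ACGT"
         for exp in [
             "strong" if m3 in "AG" and p4 == "G"
             else "moderate" if m3 in "AG" or p4 == "G"
             else "weak"
         ]],
    )
    def test_all_16_contexts(self, minus3, plus4, expected):
        seq = "C" + minus3 + "CC" + "ATG" + plus4 + "CCCCC"
        assert kozak_strength(seq, 4, "ATG") == expected

    def test_canonical_motif_examples(self):
        assert kozak_strength("ACCATGG", 3, "ATG") == "strong"
        assert kozak_strength("TTTATGG", 3, "ATG") == "moderate"
        assert kozak_strength("TTTATGC", 3, "ATG") == "weak"

    def test_non_atg_not_applicable(self):
        assert kozak_strength("ACCCTGG", 3, "CTG") == "not_applicable"

    def test_truncated_context_not_applicable(self):
        assert kozak_strength("CCATGGCCC", 2, "ATG") == "not_applicable"


class TestCollapse:
    def _candidate(self, tid, blocks, start=5, end=35):
        from uorfkit.uorf_discovery import CandidateUORF

        return CandidateUORF(
            uorf_id=f"{tid}:{start}-{end}:ATG",
            transcript_id=tid,
            gene_id="G",
            chrom="chr1",
            strand="+",
            tx_start=start,
            tx_end=end,
            start_codon="ATG",
            category="non_overlapping",
            frame_vs_cds=1,
            peptide="M" * 9,
            kozak="weak",
            genomic_blocks=blocks,
            member_transcripts=(tid,),
        )

    def test_shared_genomic_blocks_merge(self):
        a = self._candidate("iso2", ((100, 130),))
        b = self._candidate("iso1", ((100, 130),))
        merged = collapse_isoforms([a, b])
        assert len(merged) == 1
        assert merged[0].member_transcripts == ("iso1", "iso2")
        assert merged[0].uorf_id.startswith("iso1:")

    def test_different_blocks_not_merged(self):
        a = self._candidate("iso1", ((100, 130),))
        b = self._candidate("iso2", ((90, 105), (120, 135)))
        assert len(collapse_isoforms([a, b])) == 2

    def test_single_isoform_identity(self):
        a = self._candidate("iso1", ((100, 130),))
        assert collapse_isoforms([a]) == [a]
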