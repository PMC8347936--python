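"""Motif scanning, co-occurrence distances and promoter-box annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from promtarget import (
    DEFAULT_MOTIFS,
    Motif,
    annotate_promoter,
    cooccurrence_distance,
    distance_histogram,
    motif_frequency,
    reverse_complement,
    scan_motifs,
    tal1_like_promoter,
)
from promtarget.motifs import IUPAC_CODES, tss_relative_position
from promtarget.simulate import (
    TAL1_E3_RESTORED,
    TAL1_MUT_E1,
    TAL1_MUT_E2,
    TAL1_MUT_E3,
)

CACCC = Motif("EKLF", "CACCC")

dna = st.text(alphabet="ACGT", min_size=10, max_size=120)


def naive_scan(seq, motif, both_strands=True):
    """Character-by-character reference matcher (independent of the scanner)."""
    hits = set()
    patterns = [(motif.consensus, "+")]
    rc = reverse_complement(motif.consensus)
    if both_strands and rc != motif.consensus:
        patterns.append((rc, "-"))
    for pattern, strand in patterns:
        for i in range(len(seq) - len(pattern) + 1):
            if all(
                seq[i + j] in IUPAC_CODES[pattern[j]] for j in range(len(pattern))
            ):
                hits.add((i, strand))
    return hits


class TestScan:
    def test_direct_forward_match(self):
        hits = scan_motifs("AACACCCTT", [CACCC])
        assert hits[["start", "strand"]].values.tolist() == [[2, "+"]]

    @pytest.mark.parametrize(
        "fragment", [TAL1_MUT_E1, TAL1_MUT_E2, TAL1_MUT_E3],
        ids=["mutE1", "mutE2", "mutE3"],
    )
    def test_mutated_box_fragments_have_no_hit(self, fragment):
        """The catat-mutated CACCC-box fragments score zero on either strand."""
        assert scan_motifs(fragment, [CACCC], both_strands=True).empty

    def test_restored_box_has_exactly_one_forward_hit(self):
        hits = scan_motifs(TAL1_E3_RESTORED, [CACCC])
        assert len(hits) == 1
        assert hits.loc[0, "start"] == 21 and hits.loc[0, "strand"] == "+"

    @pytest.mark.parametrize(
        "seq,consensus,n",
        [
            ("TGATAA", "WGATAR", 1),   # degenerate codes accept T/A and A/G
            ("AGATAG", "WGATAR", 1),
            ("CGATAA", "WGATAR", 0),
            ("ACGT", "N", 4),
            ("ANGT", "ANGT", 1),       # consensus N matches unknown base
        ],
    )
    def test_iupac_codes(self, seq, consensus, n):
        hits = scan_motifs(seq, [Motif("m", consensus)], both_strands=False)
        assert len(hits) == n

    def test_sequence_n_never_matches_constrained_position(self):
        assert scan_motifs("CANCC", [CACCC]).empty

    def test_reverse_strand_hit_reported_on_forward_coordinates(self):
        # GGGTG at offset 3 is CACCC on the minus strand
        hits = scan_motifs("ATTGGGTGA", [CACCC])
        row = hits[hits["strand"] == "-"].iloc[0]
        assert row["start"] == 3 and row["match"] == "GGGTG"

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError, match="invalid sequence"):
            scan_motifs("ACGU", [CACCC])

    def test_agrees_with_naive_matcher(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(40):
            seq = "".join(bases[rng.integers(0, 4, 80)])
            for motif in DEFAULT_MOTIFS:
                got = {
                    (r.start, r.strand)
                    for r in scan_motifs(seq, [motif]).itertuples()
                }
                assert got == naive_scan(seq, motif)

    @given(seq=dna)
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_strand_symmetry(self, seq):
        """Scanning the reverse complement yields the same number of hits."""
        for motif in (CACCC, Motif("GATA", "WGATAR")):
            n_fwd = len(scan_motifs(seq, [motif]))
            n_rev = len(scan_motifs(reverse_complement(seq), [motif]))
            assert n_fwd == n_rev

    def test_bad_consensus_rejected(self):
        with pytest.raises(ValueError, match="non-IUPAC"):
            Motif("bad", "CACXC")
        with pytest.raises(ValueError, match="empty"):
            Motif("bad", "")


class TestFrequency:
    def _occ(self, pairs):
        return pd.DataFrame(
            [(s, m, 0, pd.NA, "+", "") for s, m in pairs],
            columns=["seq_id", "motif", "start", "position", "strand", "match"],
        )

    def test_presence_count_drives_rank(self):
        pairs = [(f"s{i}", "EKLF") for i in range(90)]
        pairs += [(f"s{i}", "GATA") for i in range(40)]
        pairs += [("s0", "GATA")] * 60  # many hits but fewer sequences
        out = motif_frequency(self._occ(pairs))
        assert out.iloc[0]["motif"] == "EKLF" and out.iloc[0]["rank"] == 1
        assert out.set_index("motif").loc["EKLF", "n_seq_ids"] == 90

    def test_absent_motif_listed_with_zero_and_ranked_last(self):
        out = motif_frequency(
            self._occ([("s0", "EKLF")]), motifs=[CACCC, Motif("TATA", "TATAA")]
        )
        last = out.iloc[-1]
        assert last["motif"] == "TATA"
        assert last["total_hits"] == 0 and last["n_seq_ids"] == 0

    def test_background_presence_rate_matches_closed_form(self, rng):
        # P(>=1 CACCC on either strand of an L-mer) ~ 1 - (1 - 2/4^5)^(L-4)
        bases = np.array(list("ACGT"))
        L, n = 1000, 400
        present = 0
        for _ in range(n):
            seq = "".join(bases[rng.integers(0, 4, L)])
            present += not scan_motifs(seq, [CACCC]).empty
        expect = 1 - (1 - 2 * 0.25**5) ** (L - 4)
        sd = np.sqrt(expect * (1 - expect) / n)
        assert abs(present / n - expect) < 4 * sd


class TestDistances:
    def _occ(self, entries):
        return pd.DataFrame(
            [(s, "m", start, pd.NA, "+", "") for s, start in entries],
            columns=["seq_id", "motif", "start", "position", "strand", "match"],
        )

    def test_nearest_partner_wins(self):
        # reference at -500; partners at -450 and -300 -> representative +50
        ref = self._occ([("s", 400)])
        par = self._occ([("s", 450), ("s", 600)])
        out = cooccurrence_distance(ref, par)
        assert out["distance"].tolist() == [50]

    def test_tie_resolves_upstream(self):
        ref = self._occ([("s", 700), ("s", 800)])
        par = self._occ([("s", 750)])
        out = cooccurrence_distance(ref, par)
        assert out["distance"].tolist() == [-50]

    def test_sequences_missing_either_motif_are_skipped(self):
        out = cooccurrence_distance(self._occ([("a", 10)]), self._occ([("b", 20)]))
        assert out.empty

    def test_role_swap_negates_representatives(self, rng):
        entries_a = [(f"s{i}", int(rng.integers(0, 900))) for i in range(30)]
        entries_b = [(f"s{i}", int(rng.integers(0, 900))) for i in range(30)]
        fwd = cooccurrence_distance(self._occ(entries_a), self._occ(entries_b))
        rev = cooccurrence_distance(self._occ(entries_b), self._occ(entries_a))
        merged = fwd.merge(rev, on="seq_id", suffixes=("_f", "_r"))
        assert (merged["distance_f"] == -merged["distance_r"]).all()


class TestHistogram:
    def test_empty_input_gives_zero_bins(self):
        hist = distance_histogram([])
        assert hist.bins["count"].sum() == 0 and hist.out_of_range == 0

    def test_single_bin_collects_identical_records(self):
        hist = distance_histogram([25] * 10)
        assert hist.bins["count"].max() == 10
        row = hist.bins[hist.bins["count"] == 10].iloc[0]
        assert row["bin_start"] == 0 and row["bin_end"] == 50

    def test_non_positive_bin_width_rejected(self):
        with pytest.raises(ValueError):
            distance_histogram([1, 2], bin_width=0)

    @given(
        st.lists(st.integers(min_value=-3000, max_value=3000), max_size=200)
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_conservation(self, distances):
        hist = distance_histogram(distances)
        assert hist.bins["count"].sum() + hist.out_of_range == len(distances)


class TestAnnotatePromoter:
    def test_fixture_reproduces_box_map_exactly(self):
        seq, tss = tal1_like_promoter()
        ann = annotate_promoter(seq, tss)
        assert [(r.box, r.position) for r in ann.itertuples()] == [
            ("CACCC", -788),
            ("CACCC", -710),
            ("CACCC", -185),
            ("CCAAT", -133),
            ("CCAAT", -57),
            ("TATA", -28),
        ]

    def test_shifting_tss_shifts_every_position(self):
        seq, tss = tal1_like_promoter()
        base = annotate_promoter(seq, tss)
        shifted = annotate_promoter(seq, tss + 100)
        assert (shifted["position"].to_numpy() == base["position"].to_numpy() - 100).all()

    def test_boxless_sequence_yields_empty_annotation(self):
        assert annotate_promoter("AGAGAGAGAGAG", 6).empty

    def test_out_of_bounds_tss_rejected(self):
        with pytest.raises(ValueError, match="tss_index"):
            annotate_promoter("ACGTACGT", 9)


def test_tss_coordinates_skip_zero():
    assert tss_relative_position(899, 900) == -1
    assert tss_relative_position(900, 900) == 1
    positions = [tss_relative_position(i, 3) for i in range(6)]
    assert positions == [-3, -2, -1, 1, 2, 3]
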