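import numpy as np
import pytest
from Bio import Align
from hypothesis import given, settings
from hypothesis import strategies as st

from lampdiag.panel_profile import (
    AlignmentError,
    DiagnosticWindow,
    MultipleAlignment,
    build_msa,
    find_windows,
    global_align,
    mirror_profile,
    revcomp,
    site_profile,
)
from lampdiag.seq_io import GenomeRecord, SpeciesPanel

dna = st.text(alphabet="ACGT", min_size=1, max_size=80)


def reference_aligner():
    """Independent affine-gap global aligner with the same gap costs
    (gap of length L costs 4 + L)."""
    aln = Align.PairwiseAligner()
    aln.mode = "global"
    aln.match_score = 1
    aln.mismatch_score = -1
    aln.open_gap_score = -5
    aln.extend_gap_score = -1
    return aln


class TestRevcomp:
    def test_examples(self):
        assert revcomp("ACGT") == "ACGT"
        assert revcomp("AAGCT") == "AGCTT"

    @given(dna)
    @settings(max_examples=50, deadline=None)
    def test_involution(self, s):
        assert revcomp(revcomp(s)) == s

    def test_invalid_character(self):
        with pytest.raises(ValueError):
            revcomp("ACGU")


class TestGlobalAlign:
    def test_self_alignment_is_identity(self):
        aln = global_align("ACGTACGTAA", "ACGTACGTAA")
        assert aln.identity_pct == 100.0

    def test_single_substitution(self):
        aln = global_align("ACGTACGT", "ACGAACGT")
        assert aln.identity_pct == pytest.approx(87.5)

    def test_empty_sequence_rejected(self):
        with pytest.raises(AlignmentError):
            global_align("", "ACGT")

    def test_band_too_small_suggests_larger(self):
        with pytest.raises(AlignmentError, match="band"):
            global_align("A" * 50, "A" * 10, band=5)

    def test_matches_full_dp_oracle_on_random_pairs(self):
        rng = np.random.default_rng(7)
        oracle = reference_aligner()
        for _ in range(25):
            n, m = rng.integers(30, 200, size=2)
            a = "".join(rng.choice(list("ACGT"), n))
            b = "".join(rng.choice(list("ACGT"), m))
            ours = global_align(a, b)
            assert ours.score == pytest.approx(oracle.score(a, b))

    def test_banded_matches_oracle_on_similar_pairs(self):
        # a narrow band still finds the optimum when the two sequences
        # differ only by scattered substitutions and short indels
        rng = np.random.default_rng(11)
        oracle = reference_aligner()
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT"), 500))
            b = list(a)
            for pos in rng.choice(500, size=10, replace=False):
                b[pos] = "ACGT"[rng.integers(4)]
            del b[100:103]
            b = "".join(b)
            ours = global_align(a, b, band=30)
            assert ours.score == pytest.approx(oracle.score(a, b))

    def test_identity_is_symmetric(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            a = "".join(rng.choice(list("ACGT"), 120))
            b = "".join(rng.choice(list("ACGT"), 115))
            assert global_align(a, b).identity_pct == pytest.approx(
                global_align(b, a).identity_pct
            )

    def test_gap_costs_are_affine(self):
        # one long gap (cost 4+6) beats two short ones (cost 2*(4+3))
        aln = global_align("AAAATTTTTTGGGG", "AAAAGGGG", band=10)
        assert aln.aligned_b.count("-") == 6
        gap_runs = [r for r in aln.aligned_b.split("A") if "-" in r]
        assert max(len(run) for run in gap_runs) >= 6


def _panel(seqs_by_species):
    records = [
        GenomeRecord(f"{sp}_{i}", sp, seq)
        for sp, seqs in seqs_by_species.items()
        for i, seq in enumerate(seqs, 1)
    ]
    return SpeciesPanel(records)


class TestBuildMsa:
    def test_identical_sequences_give_gapless_alignment(self):
        panel = _panel({"a": ["ACGTACGTAC"], "b": ["ACGTACGTAC"]})
        msa = build_msa(panel, "a_1")
        assert msa.column_count == 10
        assert set(msa.rows["b_1"]) <= set("ACGT")

    def test_single_substitution_produces_one_mismatch_column(self):
        panel = _panel({"a": ["ACGTACGTAC"], "b": ["ACGTTCGTAC"]})
        msa = build_msa(panel, "a_1")
        diffs = [
            c
            for c in range(msa.column_count)
            if msa.rows["a_1"][c] != msa.rows["b_1"][c]
        ]
        assert diffs == [4]

    def test_identity_floor_rejects_divergent_record_by_name(self):
        rng = np.random.default_rng(0)
        a = "".join(rng.choice(list("ACGT"), 300))
        b = "".join(rng.choice(list("ACGT"), 300))
        panel = _panel({"a": [a], "b": [b]})
        with pytest.raises(AlignmentError, match="b_1"):
            build_msa(panel, "a_1", band=300)

    def test_column_count_tracks_reference_length(self, canonical_panel):
        msa = build_msa(canonical_panel, "BAW_like_1")
        ref_len = len(canonical_panel["BAW_like_1"])
        assert abs(msa.column_count - ref_len) <= 0.01 * ref_len


class TestSiteProfile:
    def test_single_species_panel_all_invariant_nothing_discriminated(self):
        panel = _panel({"a": ["ACGTACGT", "ACGTACGT"]})
        prof = site_profile(build_msa(panel, "a_1"), panel, "a")
        assert prof.target_invariant.all()
        assert all(d == frozenset() for d in prof.discriminating)
        assert prof.diagnostic_columns.size == 0

    def test_invariant_column_discriminates_differing_species(self):
        panel = _panel({"t": ["AAAA", "AAAA"], "x": ["AGAA", "AGAA"]})
        prof = site_profile(build_msa(panel, "t_1", min_identity=0), panel, "t")
        assert list(prof.diagnostic_columns) == [1]
        assert prof.discriminating[1] == frozenset({"x"})

    def test_nontarget_polymorphic_but_never_matching_still_discriminates(self):
        panel = _panel({"t": ["AAAA"], "x": ["AGAA", "ACAA"]})
        prof = site_profile(build_msa(panel, "t_1", min_identity=0), panel, "t")
        assert 1 in prof.diagnostic_columns

    def test_nontarget_row_matching_target_base_blocks_discrimination(self):
        panel = _panel({"t": ["AAAA"], "x": ["AGAA", "AAAA"]})
        prof = site_profile(build_msa(panel, "t_1", min_identity=0), panel, "t")
        assert prof.diagnostic_columns.size == 0

    def test_target_polymorphism_blocks_invariance(self):
        panel = _panel({"t": ["AAAA", "ATAA"], "x": ["AGAA"]})
        prof = site_profile(build_msa(panel, "t_1", min_identity=0), panel, "t")
        assert not prof.target_invariant[1]
        assert prof.discriminating[1] == frozenset()

    def test_unknown_target_rejected(self):
        panel = _panel({"a": ["ACGT"]})
        msa = build_msa(panel, "a_1")
        with pytest.raises(ValueError):
            site_profile(msa, panel, "nope")

    def test_row_order_permutation_invariance(self, canonical_panel):
        msa = build_msa(canonical_panel, "TCW_like_1")
        prof = site_profile(msa, canonical_panel, "TCW_like")
        shuffled = SpeciesPanel(list(reversed(canonical_panel.records)))
        msa2 = MultipleAlignment(msa.reference_id, dict(reversed(msa.rows.items())))
        prof2 = site_profile(msa2, shuffled, "TCW_like")
        assert np.array_equal(prof.diagnostic_mask, prof2.diagnostic_mask)

    def test_mirror_profile_reverses_and_complements(self):
        panel = _panel({"t": ["AAGA"], "x": ["AACA"]})
        prof = site_profile(build_msa(panel, "t_1", min_identity=0), panel, "t")
        mirrored = mirror_profile(prof)
        assert mirrored.target_base == ["T", "C", "T", "T"]
        assert list(mirrored.diagnostic_columns) == [
            len(prof.target_base) - 1 - c for c in reversed(prof.diagnostic_columns)
        ]


class TestFindWindows:
    def _profile(self, n, diag_cols):
        panel = _panel({"t": ["A" * n], "x": ["A" * n]})
        prof = site_profile(build_msa(panel, "t_1", min_identity=0), panel, "t")
        mask = np.zeros(n, dtype=bool)
        mask[list(diag_cols)] = True
        prof.__dict__["diagnostic_mask"] = mask
        prof.__dict__.pop("diagnostic_columns", None)
        return prof

    def test_no_diagnostic_columns_gives_no_windows(self):
        assert find_windows(self._profile(600, []), min_sites=1) == []

    def test_single_cluster_yields_one_window_with_all_sites(self):
        cols = [100, 120, 140, 160, 180]
        wins = find_windows(self._profile(600, cols), min_sites=3, window_len=500)
        assert len(wins) == 1
        assert wins[0].diagnostic_columns == tuple(cols)
        assert (wins[0].start, wins[0].end, wins[0].score) == (100, 181, 5)

    def test_two_clusters_sorted_by_score_then_start(self):
        prof = self._profile(3000, [100, 110, 120, 2000, 2010, 2020, 2030])
        wins = find_windows(prof, min_sites=3, window_len=500)
        assert [w.score for w in wins] == [4, 3]
        assert wins[0].start == 2000

    def test_parameter_validation(self):
        prof = self._profile(600, [10])
        with pytest.raises(ValueError):
            find_windows(prof, min_sites=0)
        with pytest.raises(ValueError):
            find_windows(prof, window_len=10)

    def test_window_invariants_hold(self):
        wins = find_windows(
            self._profile(2000, [5, 200, 210, 600, 610, 620]), min_sites=2,
            window_len=100,
        )
        for w in wins:
            assert w.start < w.end
            assert all(w.start <= c < w.end for c in w.diagnostic_columns)
            assert w.score == len(w.diagnostic_columns)


def test_diagnostic_window_rejects_inverted_interval():
    with pytest.raises(AssertionError):
        DiagnosticWindow(10, 10, (), 0)
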