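import numpy as np
import pytest

from lampdiag.designer import LampPrimerSet, Primer, design_sets
from lampdiag.insilico import (
    BindingModel,
    find_binding_sites,
    predict_lamp,
    predict_lamp_components,
    predict_pcr,
    specificity_matrix,
)
from lampdiag.panel_profile import revcomp
from lampdiag.seq_io import GenomeRecord, SpeciesPanel


def _random_genome(rng, n=600, circular=True, gid="g", species="sp"):
    return GenomeRecord(
        gid, species, "".join(rng.choice(list("ACGT"), n)), circular=circular
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


class TestFindBindingSites:
    def test_exact_substring_gives_single_clean_site(self, rng):
        g = _random_genome(rng)
        primer = g.sequence[100:122]
        sites = find_binding_sites(primer, g)
        plus = [s for s in sites if s.strand == "+"]
        assert len(plus) == 1
        assert plus[0].mismatch_count == 0
        assert plus[0].footprint_start == 100
        assert plus[0].position == 121  # 3' end coordinate

    def test_minus_strand_site_found_via_revcomp(self, rng):
        g = _random_genome(rng)
        primer = revcomp(g.sequence[200:222])
        sites = [s for s in find_binding_sites(primer, g) if s.strand == "-"]
        assert sites and sites[0].footprint_start == 200
        assert sites[0].position == 200  # minus-strand 3' maps to left edge

    def test_3prime_mismatch_abolishes_binding(self, rng):
        g = _random_genome(rng)
        primer = g.sequence[100:122]
        mutated = primer[:-1] + {"A": "C", "C": "A", "G": "T", "T": "G"}[primer[-1]]
        plus = [s for s in find_binding_sites(mutated, g) if s.strand == "+"
                and s.footprint_start == 100]
        assert plus == []

    def test_internal_mismatches_tolerated_up_to_model_budget(self, rng):
        g = _random_genome(rng)
        primer = list(g.sequence[100:124])
        for pos in (3, 10):
            primer[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[primer[pos]]
        hits = [s for s in find_binding_sites("".join(primer), g)
                if s.footprint_start == 100]
        assert hits and hits[0].mismatch_count == 2
        assert hits[0].mismatch_positions == (3, 10)
        primer[15] = {"A": "C", "C": "A", "G": "T", "T": "G"}[primer[15]]
        assert [s for s in find_binding_sites("".join(primer), g)
                if s.footprint_start == 100] == []

    def test_site_straddling_circular_origin_found_after_rotation(self, rng):
        g = _random_genome(rng, n=500)
        primer = g.sequence[100:125]
        k = 110  # rotate so the site spans the origin
        rotated = GenomeRecord("rot", "sp", g.sequence[k:] + g.sequence[:k])
        sites = [s for s in find_binding_sites(primer, rotated) if s.strand == "+"]
        assert len(sites) == 1
        assert sites[0].footprint_start == (100 - k) % 500

    def test_rotation_never_changes_site_count(self, rng):
        g = _random_genome(rng, n=400)
        primer = g.sequence[50:72]
        baseline = len(find_binding_sites(primer, g))
        for k in (1, 57, 399):
            rotated = GenomeRecord("r", "sp", g.sequence[k:] + g.sequence[:k])
            assert len(find_binding_sites(primer, rotated)) == baseline

    def test_short_primer_rejected(self, rng):
        with pytest.raises(ValueError):
            find_binding_sites("ACGTACGT", _random_genome(rng))


class TestPredictPcr:
    def test_no_binding_no_amplicons(self, rng):
        g = GenomeRecord("g", "sp", "AT" * 300)
        assert predict_pcr("GCGCGCGCGCGCGCGCGC", "CGCGCGCGCGCGCGCGCG", g) == []

    def test_planted_pair_gives_expected_length(self, rng):
        g = _random_genome(rng, n=800)
        f = g.sequence[100:122]
        r = revcomp(g.sequence[378:400])  # 5' ends at 100 and 399: length 300
        amps = predict_pcr(f, r, g, max_len=500)
        assert len(amps) == 1
        assert amps[0].length == 300

    def test_strand_symmetry(self, rng):
        g = _random_genome(rng, n=800)
        f = g.sequence[100:122]
        r = revcomp(g.sequence[378:400])
        flipped = GenomeRecord("rc", "sp", revcomp(g.sequence))
        a = sorted(x.length for x in predict_pcr(f, r, g, max_len=600))
        b = sorted(x.length for x in predict_pcr(r, f, flipped, max_len=600))
        assert a == b

    def test_amplicon_across_circular_origin(self, rng):
        g = _random_genome(rng, n=600)
        f = g.sequence[450:472]
        r = revcomp(g.sequence[28:50])  # product wraps the origin
        amps = predict_pcr(f, r, g, max_len=300)
        assert len(amps) == 1
        assert amps[0].length == (49 - 450) % 600 + 1


def _set_from_template(template, species="sp"):
    """Carve a minimal six-region set out of a template sequence."""
    f3 = Primer("F3", "F3", template[0:20], 0, 20, "+")
    f2 = Primer("F2", "F2", template[25:45], 25, 45, "+")
    f1c = Primer("F1c", "F1c", revcomp(template[70:90]), 70, 90, "-")
    b1 = Primer("B1", "B1", template[95:115], 95, 115, "+")
    b2c = Primer("B2c", "B2c", revcomp(template[140:160]), 140, 160, "-")
    b3 = Primer("B3", "B3", revcomp(template[165:185]), 165, 185, "-")
    return LampPrimerSet(
        target_species=species, f3=f3, f2=f2, f1c=f1c, b1=b1, b2c=b2c, b3=b3
    )


class TestPredictLamp:
    def test_positive_on_own_template(self, rng):
        g = _random_genome(rng, n=400)
        s = _set_from_template(g.sequence)
        call = predict_lamp(s, g)
        assert call.lamp_positive and not call.missing_or_misordered
        assert call.pcr_positive

    def test_positive_on_reverse_complemented_template(self, rng):
        g = _random_genome(rng, n=400)
        s = _set_from_template(g.sequence)
        flipped = GenomeRecord("rc", "sp", revcomp(g.sequence))
        assert predict_lamp(s, flipped).lamp_positive

    def test_rotation_never_changes_the_call(self, rng):
        g = _random_genome(rng, n=400)
        s = _set_from_template(g.sequence)
        for k in (37, 180, 399):
            rotated = GenomeRecord("r", "sp", g.sequence[k:] + g.sequence[:k])
            assert predict_lamp(s, rotated).lamp_positive

    def test_f_side_only_genome_reports_missing_b_roles(self, rng):
        g = _random_genome(rng, n=400)
        s = _set_from_template(g.sequence)
        f_side_only = GenomeRecord(
            "half", "sp", g.sequence[:95] + "".join(rng.choice(list("ACGT"), 305))
        )
        call = predict_lamp(s, f_side_only)
        assert not call.lamp_positive
        assert set(call.missing_or_misordered) >= {"B2c", "B3"}

    def test_loop_binding_on_negative_genome_raises_risk_flag(self, rng):
        g = _random_genome(rng, n=400)
        s = _set_from_template(g.sequence)
        lb_region = g.sequence[120:140]
        s = LampPrimerSet(
            target_species="sp", f3=s.f3, f2=s.f2, f1c=s.f1c, b1=s.b1,
            b2c=s.b2c, b3=s.b3,
            lb=Primer("LB", "LB", lb_region, 120, 140, "+"),
        )
        other = GenomeRecord(
            "other", "x",
            "".join(np.random.default_rng(1).choice(list("ACGT"), 200))
            + lb_region
            + "".join(np.random.default_rng(2).choice(list("ACGT"), 200)),
        )
        call = predict_lamp(s, other)
        assert not call.lamp_positive
        assert call.loop_risk and call.loop_binders == ["LB"]
        assert call.cell == "-!loop"

    def test_components_with_unknown_split_reach_same_verdict(self, rng):
        g = _random_genome(rng, n=400)
        s = _set_from_template(g.sequence)
        comp = {
            "F3": s.f3.sequence, "B3": s.b3.sequence,
            "FIP": s.fip.sequence, "BIP": s.bip.sequence,
        }
        assert predict_lamp_components(comp, g).lamp_positive
        other = _random_genome(np.random.default_rng(9), n=400, gid="o")
        assert not predict_lamp_components(comp, other).lamp_positive

    def test_missing_core_role_rejected(self, rng):
        with pytest.raises(ValueError):
            predict_lamp_components(
                {"F3": "ACGT" * 5, "B3": "ACGT" * 5}, _random_genome(rng)
            )


class TestMismatchMonotonicity:
    def test_raising_tolerance_never_loses_sites(self, rng):
        g = _random_genome(rng, n=600)
        primer = g.sequence[300:322]
        strict = BindingModel(max_mismatches=0)
        loose = BindingModel(max_mismatches=3)
        s_strict = {(s.strand, s.footprint_start) for s in find_binding_sites(primer, g, strict)}
        s_loose = {(s.strand, s.footprint_start) for s in find_binding_sites(primer, g, loose)}
        assert s_strict <= s_loose

    def test_adding_3prime_mismatches_only_removes_sites(self, rng):
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
        for trial in range(20):
            local = np.random.default_rng(trial)
            g = _random_genome(local, n=500)
            primer = g.sequence[200:224]
            before = {
                (s.strand, s.footprint_start) for s in find_binding_sites(primer, g)
            }
            mutated = primer[:-1] + flip[primer[-1]]
            after = {
                (s.strand, s.footprint_start)
                for s in find_binding_sites(mutated, g)
            }
            assert ("+", 200) in before
            assert ("+", 200) not in after  # the 3' mismatch kills the site


class TestSpecificityMatrix:
    def test_empty_set_list_gives_empty_matrix(self, canonical_panel):
        mat = specificity_matrix([], canonical_panel)
        assert mat.calls == {} and mat.diagonal_ok

    def test_canonical_panel_is_diagonal(self, canonical_panel):
        sets = []
        for sp in ("BAW_like", "TCW_like"):
            sets += design_sets(canonical_panel, sp, top_k=1)
        assert len(sets) == 2
        mat = specificity_matrix(sets, canonical_panel)
        assert mat.diagonal_ok
        assert mat.off_target == []
        df = mat.to_frame()
        assert df.shape == (2, len(canonical_panel))
        assert set(df.loc["BAW_like_set1"]) <= {"+", "-", "-!loop"}

    def test_intra_species_variants_all_amplify(self, canonical_panel):
        sets = design_sets(canonical_panel, "ACL_like", top_k=1)
        assert sets
        for rec in canonical_panel.records_for("ACL_like"):
            assert predict_lamp(sets[0], rec).lamp_positive
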