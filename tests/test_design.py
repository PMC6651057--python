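"""Search engine: placements, mismatch derivation, primers, off-targets, ranking."""

import pytest

from dpacs.design import (
    DesignParams,
    Infeasible,
    Placement,
    decompose,
    enumerate_placements,
    pair_panels,
    required_mismatches,
    search,
)
from dpacs.enzymes import Enzyme, digest
from dpacs.fixtures import ECO_RI, PLE_I, RSA_I, XCM_I
from dpacs.seqcore import make_allele_pair, revcomp
from dpacs.synth import SyntheticPairSpec, generate_pair

ECORI = ECO_RI
HINFI = Enzyme("HinfI", "GANTC", -4, -1)


def triples(cands):
    return {c.triple() for c in cands}


class TestEnumeratePlacements:
    def test_psba_plei_includes_junction_placement(self, psba):
        params = DesignParams()
        placements = enumerate_placements(PLE_I, psba.pair, params)
        assert Placement(41, "+") in placements

    def test_pattern_too_long_for_region(self):
        pair = make_allele_pair("ACGTACGTA", "ACGTTCGTA")
        assert enumerate_placements(XCM_I, pair, DesignParams()) == []

    def test_palindromic_pattern_single_strand(self, psba):
        placements = enumerate_placements(ECORI, psba.pair, DesignParams())
        assert placements and all(p.strand == "+" for p in placements)

    def test_every_placement_overlaps_a_diagnostic_position(self, psba):
        region = decompose(psba.pair)
        diag = region.diag_positions["wild"]
        for p in enumerate_placements(PLE_I, psba.pair, DesignParams()):
            span = set(range(p.start - 1, p.start - 1 + PLE_I.site_len))
            assert span & diag


class TestRequiredMismatches:
    def test_psba_plei_one_per_primer(self, psba):
        muts = required_mismatches(Placement(41, "+"), PLE_I, psba.pair, "wild")
        assert len(muts) == 2
        sides = sorted(m.primer_side for m in muts)
        assert sides == ["forward", "reverse"]
        fw = next(m for m in muts if m.primer_side == "forward")
        assert (fw.position_from_3prime, fw.template_base, fw.primer_base) == (1, "T", "G")

    def test_zero_mismatches_for_naturally_created_site(self):
        # wild allele carries GAATTC across the junction untouched
        pair = generate_pair(
            SyntheticPairSpec(seed=5, flank_len=12, n_diff=1, planted_enzyme=ECORI)
        )
        zero_mismatch = []
        for p in enumerate_placements(ECORI, pair, DesignParams()):
            try:
                zero_mismatch.append(required_mismatches(p, ECORI, pair, "wild"))
            except Infeasible:
                continue
        assert [] in zero_mismatch

    def test_change_on_diagnostic_column_infeasible(self):
        # placing EcoRI so its final C falls on the T/A diagnostic column
        # demands a change the primers cannot reach
        pair = make_allele_pair("TTTTTGAATTGTTTTT", "TTTTTGAATAGTTTTT")
        with pytest.raises(Infeasible):
            required_mismatches(Placement(5, "+"), ECORI, pair, "wild")

    def test_no_discrimination_infeasible(self):
        # both alleles would carry the engineered site: only column 6 differs
        # but the pattern does not read it
        pair = make_allele_pair("TTTTTATTTTTT", "TTTTTCTTTTTT")
        # RsaI GTAC placed right of the SNP cannot overlap it
        with pytest.raises(Infeasible):
            required_mismatches(Placement(7, "+"), RSA_I, pair, "wild")


class TestBuildPrimersViaSearch:
    def test_psba_forward_primer_reproduced_verbatim(self, psba, mini_db):
        params = DesignParams(
            primer_len_min=41, primer_len_max=41, budget_fw=1, budget_rv=1
        )
        cands = search(psba.pair, mini_db, params)
        plei = [c for c in cands if c.enzyme.name == "PleI"]
        assert len(plei) == 1
        assert plei[0].fw_primer == psba.fw_primer
        rv = next(
            m for m in plei[0].discriminating_mutations if m.primer_side == "reverse"
        )
        assert (rv.template_base, rv.primer_base) == ("A", "G")
        assert rv.position_from_3prime <= 3

    def test_minimal_primer_growth(self, psba, mini_db):
        params = DesignParams(budget_fw=1, budget_rv=1)  # default 35..55
        cands = search(psba.pair, mini_db, params)
        plei = [c for c in cands if c.enzyme.name == "PleI"]
        assert plei and len(plei[0].fw_primer) == 35 and len(plei[0].rv_primer) == 35

    def test_zero_mutation_primer_equals_template_flank(self, tiny_params):
        pair = generate_pair(
            SyntheticPairSpec(seed=5, flank_len=12, n_diff=1, planted_enzyme=ECORI)
        )
        cands = search(pair, [ECORI], tiny_params)
        top = cands[0]
        assert top.n_forced == 0
        region = decompose(pair)
        assert top.fw_primer == region.F[-len(top.fw_primer):]
        assert top.rv_primer == revcomp(region.R[: len(top.rv_primer)])

    def test_ambiguous_template_instantiated_not_forced(self, tiny_params):
        # EcoRI spans GAAT + diagnostic T + flank Y: the reverse primer pins
        # the variable base (R in primer sense) to G — an instantiation of
        # the template's own bases, not a forced mismatch
        pair = make_allele_pair("TTTTTGAATTYTTTT", "TTTTTGAATAYTTTT")
        cands = search(pair, [ECORI], tiny_params)
        assert cands
        top = cands[0]
        assert top.n_forced == 0
        assert any(i.template_code == "R" and i.primer_base == "G"
                   for i in top.instantiations)


class TestOffTargets:
    def _planted_pair_with_extra_site(self):
        # wild allele gains EcoRI across the junction; a second EcoRI site
        # is planted deep in the forward flank of both alleles
        pair = generate_pair(
            SyntheticPairSpec(seed=5, flank_len=12, n_diff=1, planted_enzyme=ECORI)
        )
        wild = pair.wild_aligned
        mut = pair.mutant_aligned
        wild2 = "GAATTC" + wild[6:]
        mut2 = "GAATTC" + mut[6:]
        return make_allele_pair(wild2, mut2)

    def test_offtarget_blocks_candidate_without_budget(self):
        pair = self._planted_pair_with_extra_site()
        params = DesignParams(
            primer_len_min=12, primer_len_max=12, budget_fw=2, budget_rv=2,
            min_resolvability=1, extra_budget=0,
        )
        assert search(pair, [ECORI], params) == []

    def test_offtarget_fixed_with_extra_budget(self):
        pair = self._planted_pair_with_extra_site()
        params = DesignParams(
            primer_len_min=12, primer_len_max=12, budget_fw=2, budget_rv=2,
            min_resolvability=1, extra_budget=1,
        )
        cands = search(pair, [ECORI], params)
        zero = [c for c in cands if not c.discriminating_mutations]
        assert zero, "expected the planted zero-mismatch site to survive"
        cand = zero[0]
        assert len(cand.offtarget_fixes) == 1
        assert len(digest(cand.enzyme, cand.amplicons["wild"]).fragments) == 2
        assert len(digest(cand.enzyme, cand.amplicons["mutant"]).fragments) == 1
        # the chosen fix certainly breaks the planted flank site
        assert cand.amplicons["wild"][:6] != "GAATTC"

    def test_fix_is_farthest_from_three_prime(self):
        pair = self._planted_pair_with_extra_site()
        params = DesignParams(
            primer_len_min=12, primer_len_max=12, budget_fw=2, budget_rv=2,
            min_resolvability=1, extra_budget=1,
        )
        cands = search(pair, [ECORI], params)
        cand = [c for c in cands if c.offtarget_fixes][0]
        fix = cand.offtarget_fixes[0]
        # off-target occupies fw positions 1..6; the farthest primer-coverable
        # base from the forward 3' end is position 1 (distance 11)
        assert fix.primer_side == "forward"
        assert fix.position_from_3prime == 12


class TestSearchProperties:
    def test_planted_zero_mismatch_enzyme_ranks_first(self, tiny_params, mini_db):
        pair = generate_pair(
            SyntheticPairSpec(seed=5, flank_len=12, n_diff=1, planted_enzyme=ECORI)
        )
        cands = search(pair, mini_db, tiny_params)
        assert cands[0].n_forced == 0
        assert cands[0].enzyme.recognition == "GAATTC"

    def test_budgets_zero_without_natural_site_empty(self, tiny_params):
        pair = make_allele_pair("ACCACCACCACC", "ACCACCTCCACC")
        params = DesignParams(
            primer_len_min=3, primer_len_max=10, budget_fw=0, budget_rv=0,
            min_resolvability=1, extra_budget=0,
        )
        assert search(pair, [ECORI, PLE_I], params) == []

    @pytest.mark.parametrize("seed", [1, 2, 3, 4])
    def test_budget_monotonicity(self, seed, tiny_params):
        pair = generate_pair(SyntheticPairSpec(seed=seed, flank_len=10, n_diff=1))
        db = [ECORI, RSA_I, HINFI]
        previous = set()
        for k in (0, 1, 2):
            params = DesignParams(
                primer_len_min=5, primer_len_max=20, budget_fw=k, budget_rv=k,
                min_resolvability=1, extra_budget=0,
            )
            current = triples(search(pair, db, params))
            assert previous <= current
            previous = current

    @pytest.mark.parametrize("seed", [1, 5, 9])
    def test_wild_mutant_symmetry(self, seed, tiny_params):
        pair = generate_pair(SyntheticPairSpec(seed=seed, flank_len=10, n_diff=1))
        db = [ECORI, RSA_I, HINFI]
        fwd = search(pair, db, tiny_params)
        params_m = DesignParams(
            primer_len_min=5, primer_len_max=25, budget_fw=2, budget_rv=2,
            min_resolvability=1, extra_budget=0, detect_allele="mutant",
        )
        mirrored = search(pair.swapped(), db, params_m)
        assert triples(fwd) == triples(mirrored)

    @pytest.mark.parametrize("seed", [2, 6])
    def test_indel_amplicon_length_bookkeeping(self, seed, tiny_params):
        pair = generate_pair(
            SyntheticPairSpec(seed=seed, flank_len=12, n_diff=1, indel_len=3)
        )
        db = [ECORI, RSA_I, HINFI, PLE_I]
        for cand in search(pair, db, tiny_params):
            assert (
                len(cand.amplicons["mutant"]) - len(cand.amplicons["wild"]) == 3
            )

    def test_every_candidate_passes_independent_digestion(self, psba, mini_db):
        params = DesignParams(budget_fw=1, budget_rv=1)
        for cand in search(psba.pair, mini_db, params):
            cut = digest(cand.enzyme, cand.amplicons[cand.cut_allele])
            other = "mutant" if cand.cut_allele == "wild" else "wild"
            uncut = digest(cand.enzyme, cand.amplicons[other])
            assert len(cut.fragments) >= 2
            assert len(uncut.fragments) == 1

    def test_ranking_is_deterministic_and_ordered(self, psba, mini_db):
        params = DesignParams(budget_fw=1, budget_rv=1)
        a = search(psba.pair, mini_db, params)
        b = search(psba.pair, mini_db, params)
        assert [c.triple() for c in a] == [c.triple() for c in b]
        scores = [c.score for c in a]
        assert scores == sorted(scores)


class TestPanels:
    def test_two_enzyme_panel_on_one_primer_pair(self, tiny_params):
        pair = generate_pair(
            SyntheticPairSpec(seed=5, flank_len=12, n_diff=1, planted_enzyme=ECORI)
        )
        db = [ECORI, RSA_I, HINFI, PLE_I]
        params = DesignParams(
            primer_len_min=5, primer_len_max=25, budget_fw=2, budget_rv=2,
            min_resolvability=1, extra_budget=0, detect_allele="both",
        )
        cands = search(pair, db, params)
        wild_c = [c for c in cands if c.cut_allele == "wild"]
        mut_c = [c for c in cands if c.cut_allele == "mutant"]
        panels = pair_panels(pair, wild_c, mut_c, params)
        if panels:  # pairing is not guaranteed for every instance
            p = panels[0]
            for cand, allele, other in (
                (p.wild_candidate, "wild", "mutant"),
                (p.mutant_candidate, "mutant", "wild"),
            ):
                region = decompose(pair)
                amp_t = p.fw_primer + region.window[allele] + revcomp(p.rv_primer)
                amp_o = p.fw_primer + region.window[other] + revcomp(p.rv_primer)
                assert len(digest(cand.enzyme, amp_t).fragments) >= 2
                assert len(digest(cand.enzyme, amp_o).fragments) == 1
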