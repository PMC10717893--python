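import dataclasses

import numpy as np
import pytest

from mrbidir.gwas_io import InputError, SummaryStatSet
from mrbidir.harmonization import (HarmonizationConfig, harmonize_all,
                                   harmonize_pair)
from mrbidir.mr_estimators import ivw
from mrbidir.synthetic_data import (SimulationParams,
                                    perturb_for_harmonization,
                                    simulate_gwas_pair)

from conftest import make_variant


CFG = HarmonizationConfig()


class TestHarmonizePair:
    def test_identical_alleles_kept_as_is(self):
        exp = make_variant("rs1", "A", "G", beta=0.1)
        out = make_variant("rs1", "A", "G", beta=0.05)
        inst = harmonize_pair(exp, out, CFG)
        assert inst.action == "kept_as_is"
        assert inst.beta_out == 0.05

    def test_swapped_alleles_flip_sign_and_frequency(self):
        exp = make_variant("rs1", "A", "G", beta=0.1)
        out = make_variant("rs1", "G", "A", beta=0.05, eaf=0.3)
        inst = harmonize_pair(exp, out, CFG)
        assert inst.action == "flipped"
        assert inst.beta_out == -0.05
        assert inst.eaf_out == pytest.approx(0.7)

    def test_strand_complement_resolves_to_identity(self):
        exp = make_variant("rs1", "A", "G", beta=0.1)
        out = make_variant("rs1", "T", "C", beta=0.05)  # same variant, other strand
        inst = harmonize_pair(exp, out, CFG)
        assert inst.action == "kept_as_is"
        assert inst.beta_out == 0.05

    def test_strand_complement_plus_swap_flips(self):
        exp = make_variant("rs1", "A", "G", beta=0.1)
        out = make_variant("rs1", "C", "T", beta=0.05, eaf=0.3)
        inst = harmonize_pair(exp, out, CFG)
        assert inst.action == "flipped"
        assert inst.beta_out == -0.05

    def test_irreconcilable_alleles_dropped(self):
        exp = make_variant("rs1", "A", "G")
        out = make_variant("rs1", "A", "C")
        inst = harmonize_pair(exp, out, CFG)
        assert inst.action == "dropped"
        assert inst.drop_reason == "allele_mismatch"

    def test_palindrome_same_side_frequencies_aligned(self):
        exp = make_variant("rs1", "A", "T", beta=0.1, eaf=0.20)
        out = make_variant("rs1", "A", "T", beta=0.05, eaf=0.22)
        inst = harmonize_pair(exp, out, CFG)
        assert inst.action == "palindrome_aligned"
        assert inst.beta_out == 0.05

    def test_palindrome_opposite_side_frequencies_flipped(self):
        exp = make_variant("rs1", "A", "T", beta=0.1, eaf=0.20)
        out = make_variant("rs1", "A", "T", beta=0.05, eaf=0.78)
        inst = harmonize_pair(exp, out, CFG)
        assert inst.action == "palindrome_aligned"
        assert inst.beta_out == -0.05
        assert inst.eaf_out == pytest.approx(0.22)

    def test_palindrome_near_half_frequency_dropped(self):
        exp = make_variant("rs1", "A", "T", eaf=0.49)
        out = make_variant("rs1", "A", "T", eaf=0.51)
        inst = harmonize_pair(exp, out, CFG)
        assert inst.action == "dropped"
        assert inst.drop_reason == "palindrome_ambiguous"

    def test_palindrome_missing_frequency_dropped_not_guessed(self):
        exp = make_variant("rs1", "C", "G", eaf=None)
        out = make_variant("rs1", "C", "G", eaf=0.2)
        inst = harmonize_pair(exp, out, CFG)
        assert inst.action == "dropped"
        assert inst.drop_reason == "palindrome_ambiguous"

    def test_snp_id_mismatch_raises(self):
        with pytest.raises(InputError):
            harmonize_pair(make_variant("rs1"), make_variant("rs2"), CFG)


class TestHarmonizeAll:
    def test_missing_in_outcome_dropped_and_counted(self):
        exp = SummaryStatSet("e", "quantitative",
                             [make_variant("rs1"), make_variant("rs2"),
                              make_variant("rs3")])
        out = SummaryStatSet("o", "binary",
                             [make_variant("rs1"), make_variant("rs3")])
        insts, report = harmonize_all(exp, out, CFG)
        kept = [i for i in insts if i.kept]
        assert len(kept) == 2
        assert report.drop_reasons["rs2"] == "missing_in_outcome"
        assert report.action_counts["dropped"] == 1

    def test_all_ambiguous_palindromes_error(self):
        exp = SummaryStatSet("e", "quantitative",
                             [make_variant("rs1", "A", "T", eaf=0.5)])
        out = SummaryStatSet("o", "binary",
                             [make_variant("rs1", "A", "T", eaf=0.5)])
        with pytest.raises(InputError, match="no usable instruments"):
            harmonize_all(exp, out, CFG)

    def test_planted_perturbations_recovered_exactly(self):
        exposure, outcome, _ = simulate_gwas_pair(SimulationParams(seed=11))
        exp_p, out_p, truth = perturb_for_harmonization(
            exposure, outcome, flip_fraction=0.5, palindrome_fraction=0.3,
            seed=4)
        insts, _ = harmonize_all(exp_p, out_p, CFG)
        for inst in insts:
            assert inst.action == truth.expected_action[inst.snp_id]

    def test_round_trip_ivw_identity(self):
        exposure, outcome, _ = simulate_gwas_pair(SimulationParams(seed=11))
        base_insts, _ = harmonize_all(exposure, outcome, CFG)
        base = ivw(base_insts)

        exp_p, out_p, _ = perturb_for_harmonization(
            exposure, outcome, flip_fraction=0.6, palindrome_fraction=0.2,
            seed=9)
        insts, _ = harmonize_all(exp_p, out_p, CFG)
        kept_ids = {i.snp_id for i in insts if i.kept}
        # ambiguous palindromes (if any) are excluded on both sides
        base_kept = [i for i in base_insts if i.snp_id in kept_ids]
        assert ivw(insts).beta == pytest.approx(ivw(base_kept).beta, abs=1e-12)
        assert ivw(insts).se == pytest.approx(ivw(base_kept).se, abs=1e-12)
        # with no forced-ambiguous palindromes nothing should be dropped
        assert kept_ids == set(exposure.snp_ids)
        assert ivw(insts).beta == pytest.approx(base.beta, abs=1e-12)

    def test_forced_half_frequency_palindromes_all_dropped(self):
        exposure, outcome, _ = simulate_gwas_pair(SimulationParams(seed=11))
        exp_p, out_p, truth = perturb_for_harmonization(
            exposure, outcome, flip_fraction=0.0, palindrome_fraction=1.0,
            seed=4, palindrome_eaf=0.5)
        with pytest.raises(InputError, match="no usable instruments"):
            harmonize_all(exp_p, out_p, CFG)
        assert all(a == "dropped" for a in truth.expected_action.values())

    def test_harmonization_is_idempotent(self):
        exposure, outcome, _ = simulate_gwas_pair(SimulationParams(seed=11))
        exp_p, out_p, _ = perturb_for_harmonization(
            exposure, outcome, flip_fraction=0.5, palindrome_fraction=0.2, seed=2)
        insts, _ = harmonize_all(exp_p, out_p, CFG)
        # rebuild an outcome set in the harmonized orientation and rerun
        out2 = out_p.replace_records([
            dataclasses.replace(
                exp_p.get(i.snp_id), beta=i.beta_out, se=i.se_out,
                eaf=i.eaf_out, pvalue=i.pvalue_out)
            for i in insts if i.kept])
        exp2 = exp_p.subset([i.snp_id for i in insts if i.kept])
        insts2, _ = harmonize_all(exp2, out2, CFG)
        for a, b in zip((i for i in insts if i.kept), insts2):
            assert b.kept
            assert b.beta_out == pytest.approx(a.beta_out, abs=0)
            # non-palindromic survivors must come back untouched
            if not exp2.get(b.snp_id).is_palindromic():
                assert b.action == "kept_as_is"

    def test_orientation_invariance_of_downstream_estimate(self):
        exposure, outcome, _ = simulate_gwas_pair(SimulationParams(seed=11))
        insts, _ = harmonize_all(exposure, outcome, CFG)
        flipped_out = outcome.replace_records([
            dataclasses.replace(r, effect_allele=r.other_allele,
                                other_allele=r.effect_allele, beta=-r.beta,
                                eaf=1.0 - r.eaf)
            for r in outcome])
        insts_f, _ = harmonize_all(exposure, flipped_out, CFG)
        est, est_f = ivw(insts), ivw(insts_f)
        assert est_f.beta == pytest.approx(est.beta, abs=1e-15)
        assert est_f.se == pytest.approx(est.se, abs=1e-15)
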