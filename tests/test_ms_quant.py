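"""Peptide-family construction, PTM relative abundance, IP/input enrichment,
and histone-variant stoichiometry."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from variantscape.ms_quant import (PEPTIDE_COLUMNS, build_families,
                                   h2a_variant_fractions, h3_variant_fractions,
                                   log2_enrichment, ptm_relative_abundance)
from variantscape.synthetic_data import (generate_nucleosome_pool,
                                         generate_peptide_table, heterotypic,
                                         homotypic)


def tab(rows):
    return pd.DataFrame(rows, columns=PEPTIDE_COLUMNS)


H3_2740 = ("H3", 27, 40, "KSAPATGGVKKPHR")
H4_TAIL = ("H4", 4, 17, "GKGGKGLGKGGAKR")


class TestBuildFamilies:
    def test_modified_and_unmodified_forms_share_one_family(self):
        fams = build_families(tab([("s", *H3_2740, "K27me3", 3.0),
                                   ("s", *H3_2740, "", 1.0)]))
        assert len(fams) == 1
        assert fams[0].forms == {"K27me3": 3.0, "": 1.0}
        assert fams[0].total == 4.0

    def test_sample_is_part_of_the_family_key(self):
        fams = build_families(tab([("a", *H3_2740, "", 1.0),
                                   ("b", *H3_2740, "", 1.0)]))
        assert len(fams) == 2

    def test_duplicate_records_are_summed(self):
        fams = build_families(tab([("s", *H3_2740, "K27me3", 2.0),
                                   ("s", *H3_2740, "K27me3", 2.0)]))
        assert fams[0].forms == {"K27me3": 4.0}

    def test_mod_string_canonicalization_merges_reorderings(self):
        fams = build_families(tab([("s", *H4_TAIL, "K8acK5ac", 1.0),
                                   ("s", *H4_TAIL, "K5acK8ac", 1.0)]))
        assert fams[0].forms == {"K5acK8ac": 2.0}

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            build_families(tab([("s", *H3_2740, "", -1.0)]))


class TestPTMRelativeAbundance:
    def test_printed_worked_example_k27me3(self):
        # 18% of the 27-40 family on the modified form
        fams = build_families(tab([("s", *H3_2740, "K27me3", 18.0),
                                   ("s", *H3_2740, "", 82.0)]))
        out = ptm_relative_abundance(fams)
        assert out.loc[out["mark"] == "H3K27me3", "abundance"].item() == \
            pytest.approx(0.18, abs=1e-12)

    def test_matches_manual_enumeration_on_toy_table(self):
        # forms: K5acK8ac 2, K5ac 1, unmod 1 -> family total 4.
        # single K5ac counts every form carrying it: (2 + 1)/4 = 0.75;
        # single K8ac: 2/4 = 0.5; combination K5acK8ac exact match: 2/4 = 0.5.
        fams = build_families(tab([("s", *H4_TAIL, "K5acK8ac", 2.0),
                                   ("s", *H4_TAIL, "K5ac", 1.0),
                                   ("s", *H4_TAIL, "", 1.0)]))
        out = ptm_relative_abundance(fams).set_index("mark")["abundance"]
        assert out["H4K5ac"] == pytest.approx(0.75)
        assert out["H4K8ac"] == pytest.approx(0.5)
        assert out["H4K5acK8ac"] == pytest.approx(0.5)

    def test_unmodified_only_family_gives_zero_for_requested_marks(self):
        fams = build_families(tab([("s", *H3_2740, "", 10.0)]))
        out = ptm_relative_abundance(fams, marks=["H3K27me3"])
        assert out["abundance"].item() == 0.0

    def test_absent_family_reported_missing_not_zero(self):
        fams = build_families(tab([("s", *H3_2740, "", 10.0)]))
        out = ptm_relative_abundance(fams, marks=["H4K16ac"])
        assert out.empty

    def test_fractions_within_family_sum_to_one(self):
        fams = build_families(tab([("s", *H4_TAIL, "K5ac", 3.0),
                                   ("s", *H4_TAIL, "K16ac", 2.0),
                                   ("s", *H4_TAIL, "", 5.0)]))
        out = ptm_relative_abundance(
            fams, marks=["H4K5ac", "H4K16ac"])["abundance"]
        assert out.sum() == pytest.approx(0.5)  # unmod carries the rest
        assert ((out >= 0) & (out <= 1)).all()


class TestLog2Enrichment:
    @staticmethod
    def _ab(sample, value):
        return pd.DataFrame({"sample": [sample], "mark": ["H3K27me3"],
                             "kind": ["single"], "abundance": [value]})

    def test_threefold_enrichment_of_printed_abundances(self):
        out = log2_enrichment(self._ab("ip", 0.18), self._ab("in", 0.06),
                              pseudocount=1e-12)
        assert out["log2_ratio"].item() == pytest.approx(np.log2(3), abs=1e-6)

    def test_equal_abundances_give_zero(self):
        out = log2_enrichment(self._ab("ip", 0.1), self._ab("in", 0.1))
        assert out["log2_ratio"].item() == 0.0

    def test_double_zero_gives_zero_for_any_pseudocount(self):
        for p in (1e-8, 1e-4, 0.5):
            out = log2_enrichment(self._ab("ip", 0.0), self._ab("in", 0.0), p)
            assert out["log2_ratio"].item() == 0.0

    def test_disjoint_marks_rejected(self):
        other = self._ab("in", 0.1).assign(mark="H4K16ac")
        with pytest.raises(ValueError, match="no shared"):
            log2_enrichment(self._ab("ip", 0.1), other)


REFS = [("H2A", 4, 11, "GKQGGKAR"), ("H2A", 12, 17, "AKAKTR"),
        ("H2A", 21, 29, "AGLQFPVGR"), ("H2A", 82, 88, "HLQLAIR")]
CAN, MACRO = ("H2A", 36, 42, "KGNYAER"), ("macroH2A", 4, 14, "GGKKKSTKTSR")
H2AZ = ("H2A.Z", 1, 19, "AGGKAGKDSGKAKTKAVSR")


def h2a_table(ref=10.0, can=6.0, z=2.0, macro=2.0, sample="s"):
    rows = [(sample, *r, "", ref) for r in REFS]
    rows += [(sample, *CAN, "", can), (sample, *H2AZ, "", z),
             (sample, *MACRO, "", macro)]
    return tab(rows)


class TestVariantFractions:
    def test_hand_arithmetic_ratios(self):
        # ratios 0.6 / 0.2 / 0.2 against every reference -> same fractions
        out = h2a_variant_fractions(build_families(h2a_table()))["s"]
        assert out.fractions == pytest.approx(
            {"H2A": 0.6, "H2A.Z": 0.2, "macroH2A": 0.2})
        assert out.per_reference_ratios[("H2A.Z", "H2Ac_1")] == pytest.approx(0.2)

    def test_all_canonical_pool(self):
        out = h2a_variant_fractions(
            build_families(h2a_table(can=10.0, z=0.0, macro=0.0)))["s"]
        assert out.fractions == pytest.approx(
            {"H2A": 1.0, "H2A.Z": 0.0, "macroH2A": 0.0})

    def test_zero_reference_rejected(self):
        table = h2a_table()
        table.loc[0, "intensity"] = 0.0
        with pytest.raises(ValueError, match="reference"):
            h2a_variant_fractions(build_families(table))

    def test_missing_variant_requires_flag(self):
        table = h2a_table()
        table = table[table["sequence"] != H2AZ[3]]
        fams = build_families(table)
        with pytest.raises(ValueError, match="missing"):
            h2a_variant_fractions(fams)
        out = h2a_variant_fractions(fams, allow_missing=True)["s"]
        assert out.fractions["H2A.Z"] == 0.0

    def test_h3_one_to_three_ratio(self):
        fams = build_families(tab([("s", *H3_2740, "", 30.0),
                                   ("s", "H3", 27, 40, "KSAPSTGGVKKPHR", "",
                                    10.0)]))
        out = h3_variant_fractions(fams)["s"]
        assert out.fractions == pytest.approx({"H3": 0.75, "H3.3": 0.25})

    def test_h3_absent_variant_and_degenerate_input(self):
        fams = build_families(tab([("s", *H3_2740, "", 30.0)]))
        assert h3_variant_fractions(fams)["s"].fractions["H3.3"] == 0.0
        zero = build_families(tab([("s", *H3_2740, "", 0.0)]))
        with pytest.raises(ValueError, match="zero"):
            h3_variant_fractions(zero)

    def test_modified_forms_count_toward_family_totals(self):
        # 18% of the canonical 27-40 family carries K27me3; stoichiometry
        # must be unchanged because totals sum all forms
        fams = build_families(tab([("s", *H3_2740, "K27me3", 5.4),
                                   ("s", *H3_2740, "", 24.6),
                                   ("s", "H3", 27, 40, "KSAPSTGGVKKPHR", "",
                                    10.0)]))
        out = h3_variant_fractions(fams)["s"]
        assert out.fractions["H3.3"] == pytest.approx(0.25)


class TestInvariantsAndRoundTrip:
    @given(c=st.floats(min_value=1e-3, max_value=1e6))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_scale_invariance(self, c):
        base = h2a_table()
        scaled = base.assign(intensity=base["intensity"] * c)
        f0 = h2a_variant_fractions(build_families(base))["s"].fractions
        f1 = h2a_variant_fractions(build_families(scaled))["s"].fractions
        assert f1 == pytest.approx(f0, abs=1e-12)

    @pytest.mark.parametrize("mixture,family", [
        ({heterotypic("H2A.Z"): 1.0}, "H2A"),
        ({homotypic("H2A"): 1.0}, "H2A"),
        ({heterotypic("macroH2A"): 0.5, homotypic("H2A"): 0.5}, "H2A"),
        ({heterotypic("H3.3"): 1.0}, "H3"),
        ({homotypic("H3.1"): 0.5, heterotypic("H3.3"): 0.5}, "H3"),
    ])
    def test_noise_free_tables_invert_exactly(self, mixture, family):
        pool = generate_nucleosome_pool(mixture, 2000, seed=3)
        fams = build_families(generate_peptide_table(pool, seed=3))
        truth = pool.copy_fractions(family)
        if family == "H2A":
            got = h2a_variant_fractions(fams)["sample"].fractions
        else:
            got = h3_variant_fractions(fams)["sample"].fractions
            truth = {"H3": truth["H3.1"] + truth["H3.2"],
                     "H3.3": truth["H3.3"]}
        assert got == pytest.approx(truth, abs=1e-9)

    def test_response_factor_bias_is_visible(self):
        # doubling the H2A.Z peptide's ionization response inflates its
        # apparent fraction -- the bias the ratio method inherits
        pool = generate_nucleosome_pool({heterotypic("H2A.Z"): 1.0}, 1000)
        biased = generate_peptide_table(
            pool, response_factors={"AGGKAGKDSGKAKTKAVSR": 2.0})
        out = h2a_variant_fractions(build_families(biased))["sample"]
        assert out.fractions["H2A.Z"] > 0.5 + 0.1
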