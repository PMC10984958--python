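"""Star-allele enumeration, acetylator phenotype, risk flags, DILI criteria."""

import itertools

import numpy as np
import pytest

from pgxdili.io_core import MISSING
from pgxdili.star_allele import (
    ATP7B_CLASSES,
    CYP2E1_CLASSES,
    AlleleDefinitionTable,
    StarAlleleCall,
    acetylator_phenotype,
    call_biallelic_class,
    call_cohort,
    call_nat2,
    classify_dili,
    enumerate_diplotypes,
    estimate_haplotype_frequencies,
    flag_combined_risk,
)
from pgxdili.synthetic_cohort import SimulationConfig, simulate_cohort

DEFS = AlleleDefinitionTable()


def brute_force_pairs(dosages):
    """Independent exhaustive oracle over all allele pairs."""
    out = set()
    for h1, h2 in itertools.product(DEFS.alleles, repeat=2):
        summed = [x + y for x, y in zip(DEFS.vectors[h1], DEFS.vectors[h2])]
        if all(d == MISSING or d == s for d, s in zip(dosages, summed)):
            out.add(tuple(sorted((h1, h2))))
    return sorted(out)


def test_reference_homozygote_is_star4():
    assert enumerate_diplotypes((0, 0, 0, 0, 0), DEFS) == [("*4", "*4")]


def test_het_282_590_includes_4_6():
    pairs = enumerate_diplotypes((1, 0, 1, 0, 0), DEFS)
    assert ("*4", "*6") in pairs
    assert pairs == brute_force_pairs((1, 0, 1, 0, 0))


def test_ua_example_diplotype_6_7():
    # 282 T/T, 590 G/A, 857 G/A
    assert enumerate_diplotypes((2, 0, 1, 0, 1), DEFS) == [("*6", "*7")]


def test_enumeration_matches_brute_force_with_missing_site():
    dos = (1, MISSING, 1, 0, 0)
    assert enumerate_diplotypes(dos, DEFS) == brute_force_pairs(dos)


def test_inconsistent_genotype_gives_no_call():
    # 341 C/C + 857 A/A requires two *5 and two *7 simultaneously
    assert enumerate_diplotypes((0, 2, 0, 0, 2), DEFS) == []
    call = call_nat2((0, 2, 0, 0, 2), DEFS)
    assert call.phenotype == "unknown"


@pytest.mark.parametrize(
    "diplotype,expected",
    [
        (("*4", "*4"), "RA"),
        (("*4", "*5"), "IA"),
        (("*4", "*6"), "IA"),
        (("*4", "*7"), "IA"),
        (("*12", "*4"), "IA"),
        (("*5", "*6"), "SA"),
        (("*5", "*7"), "SA"),
        (("*6", "*6"), "UA"),
        (("*6", "*7"), "UA"),
        (("*7", "*7"), "UA"),
    ],
)
def test_printed_phenotype_mapping(diplotype, expected):
    phenotype, extended = acetylator_phenotype(diplotype)
    assert phenotype == expected
    assert not extended


@pytest.mark.parametrize(
    "diplotype,expected",
    [(("*5", "*5"), "SA"), (("*12", "*12"), "RA"), (("*12", "*6"), "IA"), (("*12", "*5"), "IA")],
)
def test_extended_rule_classification_is_flagged(diplotype, expected):
    phenotype, extended = acetylator_phenotype(diplotype)
    assert phenotype == expected
    assert extended


def test_phenotype_total_over_all_enumerable_diplotypes():
    for h1, h2 in itertools.combinations_with_replacement(DEFS.alleles, 2):
        phenotype, _ = acetylator_phenotype((h1, h2))
        assert phenotype in ("RA", "IA", "SA", "UA")


def test_unambiguous_call_is_frequency_independent():
    dos = (2, 0, 1, 0, 1)  # unique (*6,*7)
    from pgxdili.star_allele import HaplotypeFrequencies

    skewed = HaplotypeFrequencies({"*4": 0.96, "*5": 0.01, "*6": 0.01, "*7": 0.01, "*12": 0.01})
    c1 = call_nat2(dos, DEFS, None)
    c2 = call_nat2(dos, DEFS, skewed)
    assert c1.diplotype == c2.diplotype == ("*6", "*7")
    assert c1.phenotype == c2.phenotype == "UA"
    assert not c1.ambiguous


def test_em_equals_direct_counting_when_unambiguous():
    cfg = SimulationConfig(n_cases=2, n_controls=2, n_population=0, n_null_variants=0, seed=1)
    g, _, _ = simulate_cohort(cfg)
    # force an unambiguous two-sample *4/*4 cohort
    g4 = g.subset(samples=g.sample_ids[:2])
    g4.dosage[:, :5] = 0
    freqs = estimate_haplotype_frequencies(g4)
    assert freqs["*4"] == pytest.approx(1.0, abs=1e-8)


def test_em_recovers_generating_frequencies():
    cfg = SimulationConfig(
        n_cases=0,
        n_controls=2000,
        n_population=0,
        n_null_variants=0,
        nat2_freqs={"*4": 0.6, "*5": 0.05, "*6": 0.25, "*7": 0.10, "*12": 0.0},
        seed=42,
    )
    g, _, truth = simulate_cohort(cfg)
    freqs = estimate_haplotype_frequencies(g.subset(variants=g.variant_ids[:5]))
    for allele, f_true in cfg.nat2_freqs.items():
        assert freqs[allele] == pytest.approx(f_true, abs=0.02)


def test_em_no_consistent_sample_raises():
    cfg = SimulationConfig(n_cases=1, n_controls=1, n_population=0, n_null_variants=0, seed=2)
    g, _, _ = simulate_cohort(cfg)
    g2 = g.subset(samples=g.sample_ids[:1], variants=g.variant_ids[:5])
    g2.dosage[0, :] = (0, 2, 0, 0, 2)  # impossible combination
    with pytest.raises(ValueError, match="no sample"):
        estimate_haplotype_frequencies(g2)


def test_biallelic_classes():
    assert call_biallelic_class(2, ATP7B_CLASSES) == "R/R"
    assert call_biallelic_class(0, ATP7B_CLASSES) == "K/K"
    assert call_biallelic_class(0, CYP2E1_CLASSES) == "*1A/*1A"
    assert call_biallelic_class(MISSING, ATP7B_CLASSES) == "unknown"


@pytest.mark.parametrize(
    "phenotype,atp7b,expected",
    [("UA", "R/R", True), ("UA", "K/R", False), ("SA", "R/R", False)],
)
def test_combined_risk_flag(phenotype, atp7b, expected):
    call = StarAlleleCall("s", ("*6", "*7"), phenotype, atp7b=atp7b)
    assert flag_combined_risk(call) is expected


def test_combined_risk_unknown_sets_uncertainty():
    call = StarAlleleCall("s", None, "unknown", atp7b="R/R")
    assert flag_combined_risk(call) is False
    assert call.risk_flag_uncertain


@pytest.mark.parametrize(
    "kwargs,expected",
    [
        (dict(alt=200, alt_uln=40), "DILI"),  # ALT 5x ULN
        (dict(alt=160, alt_uln=40, bilirubin=1.2, bilirubin_uln=1.2, alp=120, alp_uln=120), "no-DILI"),
        (dict(alt=120, alt_uln=40, bilirubin=2.4, bilirubin_uln=1.2), "DILI"),  # 3x + 2x
        (dict(alp=240, alp_uln=120), "DILI"),  # ALP 2x ULN
        (dict(bilirubin=5.0, bilirubin_uln=1.2), "no-DILI"),  # bilirubin alone insufficient
        (dict(), "no-DILI"),  # all missing: every criterion false
    ],
)
def test_classify_dili(kwargs, expected):
    assert classify_dili(**kwargs) == expected


def test_call_cohort_matches_latent_truth(small_cohort):
    _, g, pheno, truth = small_cohort
    calls = call_cohort(g)
    n_checked = n_match = 0
    for _, row in calls.iterrows():
        true_pair = tuple(truth["diplotypes"][row["sample_id"]])
        if not row["ambiguous"]:
            n_checked += 1
            n_match += row["diplotype"] == "/".join(true_pair)
    assert n_checked > 0
    assert n_match / n_checked >= 0.99
    # combined risk consistent with latent ATP7B dosage and UA phenotype
    for _, row in calls.iterrows():
        is_rr = truth["atp7b_dosage"][row["sample_id"]] == 2
        assert row["combined_risk"] == (row["phenotype"] == "UA" and is_rr)
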