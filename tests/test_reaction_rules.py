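"""Reactivity matrix, product prediction, and mass-shift consistency."""

import itertools

import pytest

from derivid import (
    AMINE_SMILES,
    ExpectedKind,
    FunctionalGroup,
    OutcomeKind,
    ProductMode,
    ReagentId,
    RuleSet,
    SiteOverflowError,
    default_rule_set,
    expected_outcome,
    parse_structure,
    predict_products,
)

G = FunctionalGroup
R = ReagentId


def test_matrix_is_complete_and_unambiguous(rules):
    rules.validate()
    for reagent, group in itertools.product(R, G):
        rule = rules.rule_for(reagent, group)
        assert rule.outcome in OutcomeKind


@pytest.mark.parametrize(
    ("reagent", "group", "delta"),
    [
        (R.TMSH, G.OH, 14),
        (R.TMSH, G.COOH, 14),
        (R.TMSH, G.CHO, 46),
        (R.TMSCHN2, G.OH, 14),
        (R.DMF_DMA, G.COOH, 14),
        (R.DMF_DMA, G.CHO, 46),
        (R.TFAA, G.OH, 96),
    ],
)
def test_per_site_shifts_derived_from_transforms(rules, reagent, group, delta):
    assert rules.rule_for(reagent, group).delta_m_nominal == delta


@pytest.mark.parametrize(
    ("reagent", "group"),
    [
        (R.TFAA, G.ETHER),
        (R.TFAA, G.KETONE),
        (R.TMSH, G.ETHER),
        (R.TMSH, G.ESTER),
        (R.DMF_DMA, G.OH),
        (R.DMF_DMA, G.KETONE),
        (R.NH4OH, G.ETHER),
    ],
)
def test_nonreactive_cells(rules, reagent, group):
    assert rules.rule_for(reagent, group).outcome is OutcomeKind.NONE


def test_nh4oh_cleaves_esters(rules):
    assert rules.rule_for(R.NH4OH, G.ESTER).outcome is OutcomeKind.CLEAVAGE


def test_dmf_dma_accepts_plus18_alternate(rules):
    assert 18 in rules.rule_for(R.DMF_DMA, G.COOH).alternate_shifts


def test_unresolved_ketone_rule_has_shift_set_but_no_structure(rules):
    rule = rules.rule_for(R.TMSH, G.KETONE)
    assert rule.transform is None
    assert rule.shift_choices() == (14, 18)


def test_delta_m_vs_graph_edit_oracle(rules, all_records):
    """Two routes to every shift agree: the tabulated per-site Δm sum and the
    mass of the actually edited product graph."""
    checked = 0
    for record in all_records:
        for reagent in R:
            for product in predict_products(
                record.structure, reagent, rules, ProductMode.ALL_PARTIAL
            ):
                if product.fragments:
                    continue
                assert (
                    product.structure.nominal_mass
                    == record.structure.nominal_mass + product.total_delta_m_nominal
                )
                assert product.structure.monoisotopic_mass == pytest.approx(
                    record.structure.monoisotopic_mass
                    + product.total_delta_m_monoisotopic,
                    abs=1e-6,
                )
                checked += 1
    assert checked > 30  # every shift rule is exercised across the fixtures


def test_cleavage_mass_conservation(rules, all_records):
    """Hydrolysis fragments sum to educt mass plus one water per cleaved site."""
    esters = [r for r in all_records if r.truth.n_ester]
    assert esters
    for record in esters:
        (product,) = predict_products(record.structure, R.NH4OH, rules)
        total = sum(f.structure.nominal_mass for f in product.fragments)
        n_sites = record.truth.n_ester
        assert total == record.structure.nominal_mass + 18 * n_sites


def test_naphthyl_acetate_hydrolysis_fragments(rules):
    s = parse_structure("CC(=O)Oc1cccc2ccccc12")
    (product,) = predict_products(s, R.NH4OH, rules)
    roles = {f.role: f for f in product.fragments}
    assert roles["alcohol"].structure.nominal_mass == 144  # naphthalen-1-ol
    assert roles["alcohol"].gc_visible
    assert not roles["acid"].gc_visible  # acetic acid is not observed by GC-MS


def test_diol_methylation_full_and_partial(rules):
    s = parse_structure("Oc1ccccc1-c1ccccc1O")
    products = predict_products(s, R.TMSH, rules, ProductMode.ALL_PARTIAL)
    by_delta = {p.total_delta_m_nominal: p for p in products}
    assert set(by_delta) == {14, 28}
    assert by_delta[14].completeness == "PARTIAL"
    assert by_delta[28].completeness == "FULL"
    assert by_delta[28].structure.nominal_mass == 214


def test_tfaa_forces_exhaustive_derivatization(rules):
    s = parse_structure("Oc1ccccc1-c1ccccc1O")
    products = predict_products(s, R.TFAA, rules, ProductMode.ALL_PARTIAL)
    assert len(products) == 1
    assert products[0].total_delta_m_nominal == 192
    assert products[0].completeness == "FULL"


@pytest.mark.parametrize(
    ("smiles", "n_oh"),
    [
        ("Oc1ccccc1", 1),
        ("Oc1ccccc1-c1ccccc1O", 2),
        ("Oc1cc(O)cc(O)c1", 3),
    ],
)
def test_tfaa_shift_is_96_per_hydroxyl(rules, smiles, n_oh):
    outcome = expected_outcome(parse_structure(smiles), R.TFAA, rules)
    assert outcome.acceptable_shifts == (96 * n_oh,)
    assert outcome.full_shift_nominal == 96 * n_oh


def test_ether_only_structures_are_inert_to_every_reagent(rules):
    for smiles in ("COc1ccccc1", "c1ccc(Oc2ccccc2)cc1", "CCOCC"):
        s = parse_structure(smiles)
        for reagent in R:
            assert (
                expected_outcome(s, reagent, rules).kind is ExpectedKind.NO_REACTION
            ), (smiles, reagent)


def test_pure_ether_yields_no_products(rules):
    assert predict_products(parse_structure("COc1ccccc1"), R.TMSH, rules) == []


def test_unresolved_ketone_has_shift_set_but_no_product(rules):
    s = parse_structure("CCCCC(=O)c1ccccc1")  # valerophenone
    assert predict_products(s, R.TMSH, rules, ProductMode.ALL_PARTIAL) == []
    outcome = expected_outcome(s, R.TMSH, rules)
    assert outcome.kind is ExpectedKind.SHIFT_SET
    assert outcome.acceptable_shifts == (14, 18)


def test_site_overflow_is_reported(rules):
    nine_ols = parse_structure("OCC(O)C(O)C(O)C(O)C(O)C(O)C(O)CO")
    with pytest.raises(SiteOverflowError):
        predict_products(nine_ols, R.TMSH, rules, ProductMode.ALL_PARTIAL)


@pytest.mark.parametrize(
    ("smiles", "reagent", "shifts"),
    [
        ("COc1ccc(C=O)c2ccccc12", R.TMSH, (46,)),
        ("OC(=O)Cc1ccc2ccccc2c1", R.DMF_DMA, (14, 18)),
    ],
)
def test_expected_outcome_shift_sets(rules, smiles, reagent, shifts):
    outcome = expected_outcome(parse_structure(smiles), reagent, rules)
    assert outcome.kind is ExpectedKind.SHIFT_SET
    assert outcome.acceptable_shifts == shifts


def test_benzophenone_inert_to_tfaa(rules):
    outcome = expected_outcome(parse_structure("O=C(c1ccccc1)c1ccccc1"), R.TFAA, rules)
    assert outcome.kind is ExpectedKind.NO_REACTION


def test_methoxy_carbaldehyde_tmsh_product_ion(rules):
    s = parse_structure("COc1ccc(C=O)c2ccccc12")
    (product,) = predict_products(s, R.TMSH, rules)
    assert product.total_delta_m_nominal == 46
    assert s.nominal_mass + product.total_delta_m_nominal == 232


@pytest.mark.parametrize(
    "amine", ["benzylamine", "aniline", "2,4-difluorobenzylamine"]
)
def test_imine_shift_computed_from_amine(amine):
    """Imine Δm equals amine mass minus water — an independent arithmetic route."""
    rules = default_rule_set(amine=amine)
    rule = rules.rule_for(R.BORATE_AMINE, G.CHO)
    expected = parse_structure(AMINE_SMILES[amine]).nominal_mass - 18
    assert rule.delta_m_nominal == expected
    assert not rule.reliable


def test_benzylamine_imine_product(rules):
    s = parse_structure("O=Cc1ccccc1")
    (product,) = predict_products(s, R.BORATE_AMINE, rules)
    assert product.total_delta_m_nominal == 89
    assert product.structure.nominal_mass == s.nominal_mass + 89


def test_good_leaving_group_option_restricts_cleavage():
    restricted = default_rule_set(good_leaving_group_only=True)
    alkyl_ester = parse_structure("COC(=O)c1cccc2ccccc12")  # methyl naphthoate
    aryl_ester = parse_structure("CC(=O)Oc1cccc2ccccc12")
    assert (
        expected_outcome(alkyl_ester, R.NH4OH, restricted).kind
        is ExpectedKind.NO_REACTION
    )
    assert (
        expected_outcome(aryl_ester, R.NH4OH, restricted).kind
        is ExpectedKind.CLEAVAGE_PEAKS
    )


def test_rule_set_json_round_trip(rules):
    text = rules.to_json()
    restored = RuleSet.from_json(text)
    assert restored == rules
    assert restored.to_json() == text
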