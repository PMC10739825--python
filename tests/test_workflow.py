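"""Decision-pathway classification and multiset enumeration."""

import itertools

import pytest

from derivid import (
    Confidence,
    FunctionalGroup,
    Observation,
    ObservationKind,
    ObservationSet,
    ReagentId,
    RetentionDirection,
    SimConfig,
    classify,
    consistent_group_multisets,
    simulate_observations,
)

from derivid import default_rule_set

G = FunctionalGroup
R = ReagentId
K = ObservationKind
RULES = default_rule_set()


def obs_set(parent=186.0, **per_reagent):
    observations = []
    for key, value in per_reagent.items():
        rid = R[key]
        if value == "no_change":
            observations.append(Observation(rid, K.NO_CHANGE))
        elif isinstance(value, tuple) and value[0] == "peak":
            observations.append(
                Observation(rid, K.NEW_SMALLER_PEAK, new_peak_mz=value[1])
            )
        else:
            direction = RetentionDirection.UNKNOWN
            if isinstance(value, tuple):
                value, direction = value
            observations.append(
                Observation(
                    rid, K.SHIFT, observed_delta_m=value, retention_direction=direction
                )
            )
    return ObservationSet(parent_mz=parent, observations=tuple(observations))


def inferred(result):
    return sorted(
        g.value for g, n in result.inferred_groups.items() for _ in range(n)
    )


def test_ether_confirmed_by_elimination():
    result = classify(obs_set(TMSH="no_change", NH4OH="no_change"), rules=RULES)
    assert inferred(result) == ["ETHER"]
    (call,) = [c for c in result.calls if c.group is G.ETHER]
    assert call.confidence is Confidence.EXCLUDED_BY_ELIMINATION


def test_aldehyde_identified_from_tmsh_alone():
    result = classify(obs_set(TMSH=46), RULES)
    assert inferred(result) == ["CHO"]


def test_diol_counted_from_tfaa_shift():
    result = classify(
        obs_set(TMSH=28, TFAA=(192, RetentionDirection.EARLIER)), RULES
    )
    assert result.inferred_groups[G.OH] == 2
    (call,) = [c for c in result.calls if c.group is G.OH]
    assert call.confidence is Confidence.CONFIRMED


def test_carboxylic_acid_via_dmf_dma():
    result = classify(
        obs_set(TMSH=14, TFAA="no_change", DMF_DMA=14), RULES
    )
    assert inferred(result) == ["COOH"]


def test_ester_branch_new_smaller_peak():
    result = classify(obs_set(TMSH="no_change", NH4OH=("peak", 144)), RULES)
    assert inferred(result) == ["ESTER"]


def test_ketone_from_residual_shift_and_silent_dmf():
    result = classify(
        obs_set(TMSH=14, TFAA="no_change", DMF_DMA="no_change"), RULES
    )
    assert inferred(result) == ["KETONE"]


def test_hydroxy_ketone_combination_resolved():
    result = classify(
        obs_set(TMSH=28, TFAA=(96, RetentionDirection.EARLIER), DMF_DMA="no_change"),
        RULES,
    )
    assert inferred(result) == ["KETONE", "OH"]


def test_missing_tmsh_yields_inconclusive_everything():
    result = classify(obs_set(TFAA=96), RULES)
    assert result.inferred_groups == {}
    assert all(c.confidence is Confidence.INCONCLUSIVE for c in result.calls)


def test_missing_nh4oh_leaves_ether_ester_open():
    result = classify(obs_set(TMSH="no_change"), RULES)
    assert result.inferred_groups == {}
    open_groups = {c.group for c in result.calls}
    assert open_groups == {G.ETHER, G.ESTER}


def test_contradiction_is_structured_not_raised():
    result = classify(obs_set(TMSH="no_change", TFAA=96), RULES)
    assert result.contradiction == (R.TMSH, R.TFAA)
    assert result.inferred_groups == {}


def test_retention_mismatch_downgrades_not_flips():
    agree = classify(obs_set(TMSH=28, TFAA=(192, RetentionDirection.EARLIER)), RULES)
    clash = classify(obs_set(TMSH=28, TFAA=(192, RetentionDirection.LATER)), RULES)
    assert agree.inferred_groups == clash.inferred_groups
    conf = {c.group: c.confidence for c in clash.calls}
    assert conf[G.OH] is Confidence.SUPPORTED


def test_order_invariance():
    observations = (
        Observation(R.TMSH, K.SHIFT, observed_delta_m=14),
        Observation(R.TFAA, K.NO_CHANGE),
        Observation(R.DMF_DMA, K.SHIFT, observed_delta_m=14),
        Observation(R.TMSCHN2, K.SHIFT, observed_delta_m=14),
    )
    results = [
        classify(ObservationSet(186.0, perm), RULES)
        for perm in itertools.permutations(observations)
    ]
    assert all(r == results[0] for r in results)


def test_supportive_reagents_never_change_inferred_groups():
    base = obs_set(TMSH=14, TFAA="no_change", DMF_DMA=14)
    with_support = obs_set(TMSH=14, TFAA="no_change", DMF_DMA=14, TMSCHN2=14)
    with_clash = obs_set(TMSH=14, TFAA="no_change", DMF_DMA=14, TMSCHN2="no_change")
    r0, r1, r2 = (classify(o, RULES) for o in (base, with_support, with_clash))
    assert r0.inferred_groups == r1.inferred_groups == r2.inferred_groups
    conf = {c.group: c.confidence for c in r2.calls}
    assert conf[G.COOH] is Confidence.SUPPORTED  # disagreement downgrades only


def test_trace_cites_only_supplied_observations():
    obs = obs_set(TMSH=28, TFAA=(192, RetentionDirection.EARLIER))
    result = classify(obs, RULES)
    supplied = {o.reagent_id for o in obs.observations}
    cited = {t.reagent_id for t in result.decision_trace if t.reagent_id}
    assert cited <= supplied
    assert set(result.unused_observations) == supplied - cited


def test_duplicate_reagent_rejected():
    with pytest.raises(ValueError):
        ObservationSet(
            186.0,
            (
                Observation(R.TMSH, K.NO_CHANGE),
                Observation(R.TMSH, K.SHIFT, observed_delta_m=14),
            ),
        )


def test_shift_observation_requires_delta():
    with pytest.raises(ValueError):
        Observation(R.TMSH, K.SHIFT)


def test_new_peak_must_be_smaller_than_parent():
    with pytest.raises(ValueError):
        ObservationSet(
            100.0,
            (Observation(R.NH4OH, K.NEW_SMALLER_PEAK, new_peak_mz=150.0),),
        )


# --- multiset enumeration --------------------------------------------------


def test_pure_ether_multiset_is_consistent():
    obs = obs_set(TMSH="no_change", NH4OH="no_change", TFAA="no_change")
    result = consistent_group_multisets(obs, RULES)
    assert (G.ETHER,) in result
    assert (G.ESTER,) not in result  # hydrolysis silence excludes esters


def test_vanillin_like_pattern_contains_cho_plus_oh():
    obs = obs_set(parent=152.0, TMSH=46, TFAA=96, DMF_DMA=46)
    result = consistent_group_multisets(obs, RULES)
    assert (G.CHO, G.OH) in result
    assert (G.CHO,) not in result  # TFAA shift requires a hydroxyl


def test_contradictory_observations_admit_no_multiset():
    obs = obs_set(TMSH="no_change", TFAA=96)
    assert consistent_group_multisets(obs, RULES) == []


def test_multisets_sorted_by_size_then_lexicographically():
    obs = obs_set(TMSH=14, TFAA=96)
    result = consistent_group_multisets(obs, RULES, max_groups=3)
    sizes = [len(ms) for ms in result]
    assert sizes == sorted(sizes)
    for a, b in zip(result, result[1:]):
        if len(a) == len(b):
            assert tuple(g.value for g in a) < tuple(g.value for g in b)


def test_round_trip_soundness(rules, all_records):
    """Full-conversion simulation → classification infers a sub-multiset of
    the truth, and enumeration recovers the exact truth multiset."""
    for record in all_records:
        obs = simulate_observations(record.structure, rules, SimConfig(seed=11))
        result = classify(obs, rules)
        assert not result.is_contradictory, record.name
        truth = record.truth.as_multiset()
        got = inferred(result)
        for g in set(got):
            assert got.count(g) <= [t.value for t in truth].count(g), record.name
        assert truth in consistent_group_multisets(obs, rules, max_groups=3), record.name
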