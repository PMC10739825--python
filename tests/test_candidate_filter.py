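"""Consistency scoring and candidate-list reduction."""

import itertools

import pytest

from derivid import (
    CandidateRecord,
    FilterMode,
    Observation,
    ObservationKind,
    ObservationSet,
    ReagentId,
    RetentionDirection,
    SimConfig,
    Verdict,
    filter_candidates,
    parse_structure,
    score_candidate,
    simulate_observations,
)

R = ReagentId
K = ObservationKind


def _obs(*observations, parent=186.0):
    return ObservationSet(parent_mz=parent, observations=tuple(observations))


DIOL_OBS = _obs(
    Observation(R.TMSH, K.SHIFT, observed_delta_m=28,
                retention_direction=RetentionDirection.LATER),
    Observation(R.TFAA, K.SHIFT, observed_delta_m=192,
                retention_direction=RetentionDirection.EARLIER),
    Observation(R.DMF_DMA, K.NO_CHANGE),
)

ACETATE_OBS = _obs(
    Observation(R.TMSH, K.NO_CHANGE),
    Observation(R.NH4OH, K.NEW_SMALLER_PEAK, new_peak_mz=144.0),
)


def test_diol_pattern_retains_exactly_the_five_diols(rules, isomers):
    report = filter_candidates(isomers.as_candidates(), DIOL_OBS, rules)
    assert sorted(report.retained_ids, key=int) == ["1", "3", "4", "16", "17"]
    assert report.reduction >= 0.72


def test_acetate_pattern_retains_the_two_naphthyl_acetates(rules, isomers):
    report = filter_candidates(isomers.as_candidates(), ACETATE_OBS, rules)
    assert sorted(report.retained_ids, key=int) == ["7", "8"]


def test_score_candidate_match_and_mismatch(rules):
    acetate = CandidateRecord("8", "naphthalen-1-yl acetate",
                              parse_structure("CC(=O)Oc1cccc2ccccc12"))
    diol = CandidateRecord("1", "biphenyl-2,2'-diol",
                           parse_structure("Oc1ccccc1-c1ccccc1O"))
    s_acetate = score_candidate(acetate, ACETATE_OBS, rules)
    assert (s_acetate.n_match, s_acetate.n_tested) == (2, 2)
    assert s_acetate.retained
    s_diol = score_candidate(diol, ACETATE_OBS, rules)
    assert s_diol.verdict_for(R.TMSH) is Verdict.MISMATCH
    assert not s_diol.retained


def test_empty_observation_set_is_vacuously_consistent(rules):
    candidate = CandidateRecord("x", "benzaldehyde", parse_structure("O=Cc1ccccc1"))
    score = score_candidate(candidate, _obs(parent=106.0), rules)
    assert score.n_tested == 0
    assert score.retained and score.not_tested


def test_parent_mass_mismatch_is_scored_not_dropped(rules):
    wrong_mass = CandidateRecord(
        "bp", "benzophenone", parse_structure("O=C(c1ccccc1)c1ccccc1")
    )  # nominal 182 vs parent 186
    score = score_candidate(wrong_mass, _obs(parent=186.0), rules)
    assert not score.parent_match
    assert not score.retained


def test_unreliable_rules_excluded_from_strict_scoring(rules):
    benzaldehyde = CandidateRecord("20", "benzaldehyde", parse_structure("O=Cc1ccccc1"))
    obs = _obs(
        Observation(R.TMSH, K.SHIFT, observed_delta_m=46),
        Observation(R.BORATE_AMINE, K.NO_CHANGE),
        parent=106.0,
    )
    score = score_candidate(benzaldehyde, obs, rules)
    assert score.verdict_for(R.BORATE_AMINE) is Verdict.UNRELIABLE_RULE
    assert score.n_tested == 1
    assert score.retained


def test_self_retention_for_all_fixtures(rules, isomers, validation_mix):
    for fixture in (isomers, validation_mix):
        candidates = fixture.as_candidates()
        for record in fixture.records:
            obs = simulate_observations(record.structure, rules, SimConfig(seed=5))
            report = filter_candidates(candidates, obs, rules)
            assert str(record.index) in report.retained_ids, record.name


def test_monotone_pruning_under_added_observations(rules, isomers):
    """Adding one more observation never grows the strictly retained set."""
    candidates = isomers.as_candidates()
    observations = DIOL_OBS.observations
    for k in range(len(observations)):
        for subset in itertools.combinations(observations, k):
            smaller = filter_candidates(candidates, _obs(*subset), rules)
            for extra in set(observations) - set(subset):
                larger = filter_candidates(candidates, _obs(*subset, extra), rules)
                assert set(larger.retained_ids) <= set(smaller.retained_ids)


def test_ranking_is_deterministic(rules, isomers):
    candidates = isomers.as_candidates()
    a = filter_candidates(candidates, DIOL_OBS, rules)
    b = filter_candidates(list(candidates), DIOL_OBS, rules)
    assert [s.candidate_id for s in a.scores] == [s.candidate_id for s in b.scores]
    assert all(0.0 <= s.score <= 1.0 for s in a.scores)


def test_ranking_sorted_retained_then_score_then_id(rules, isomers):
    report = filter_candidates(isomers.as_candidates(), DIOL_OBS, rules)
    keys = [(not s.retained, -s.score, s.candidate_id) for s in report.scores]
    assert keys == sorted(keys)


def test_lenient_mode_threshold(rules, isomers):
    # one deliberately wrong observation out of three: strict drops the diols,
    # lenient at 2/3 keeps them
    noisy = _obs(
        Observation(R.TMSH, K.SHIFT, observed_delta_m=28),
        Observation(R.TFAA, K.SHIFT, observed_delta_m=192),
        Observation(R.DMF_DMA, K.SHIFT, observed_delta_m=14),  # spurious
    )
    strict = filter_candidates(isomers.as_candidates(), noisy, rules)
    lenient = filter_candidates(
        isomers.as_candidates(), noisy, rules, mode=FilterMode.LENIENT, threshold=0.6
    )
    assert "1" not in strict.retained_ids
    assert "1" in lenient.retained_ids


def test_empty_candidate_list_rejected(rules):
    with pytest.raises(ValueError):
        filter_candidates([], DIOL_OBS, rules)
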