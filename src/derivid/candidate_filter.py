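"""Consistency-based filtering of candidate isomer lists.

In non-target screening a molecular formula typically admits dozens to
hundreds of constitutional isomers. Given the per-reagent derivatization
observations for the unknown, each candidate structure is forward-predicted
under the same reagents and scored: a candidate survives only if every
tested, reliable prediction agrees with what was seen. Candidates whose
predicted chemistry is indistinguishable remain together — the filter
returns equivalence classes of survivors, it never forces a unique answer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import pandas as pd

from .chem_core import Structure
from .reaction_rules import (
    ExpectedKind,
    ReagentId,
    RuleSet,
    expected_outcome,
)
from .workflow import DEFAULT_TOLERANCE, Observation, ObservationKind, ObservationSet


class Verdict(str, Enum):
    MATCH = "MATCH"
    MISMATCH = "MISMATCH"
    NOT_TESTED = "NOT_TESTED"
    UNRELIABLE_RULE = "UNRELIABLE_RULE"


class FilterMode(str, Enum):
    STRICT = "STRICT"
    LENIENT = "LENIENT"


@dataclass(frozen=True)
class CandidateRecord:
    id: str
    name: str
    structure: Structure


@dataclass(frozen=True)
class ConsistencyScore:
    candidate_id: str
    name: str
    verdicts: tuple[tuple[ReagentId, Verdict], ...]
    parent_match: bool
    n_match: int
    n_tested: int
    score: float
    retained: bool
    not_tested: bool = False

    def verdict_for(self, reagent_id: ReagentId) -> Verdict:
        for rid, v in self.verdicts:
            if rid is reagent_id:
                return v
        return Verdict.NOT_TESTED


def _compare(
    observation: Observation, expected, tolerance: float
) -> Verdict:
    if not expected.reliable:
        return Verdict.UNRELIABLE_RULE
    tol = max(observation.tolerance, tolerance)
    if observation.kind is ObservationKind.NO_CHANGE:
        return (
            Verdict.MATCH
            if expected.kind is ExpectedKind.NO_REACTION
            else Verdict.MISMATCH
        )
    if observation.kind is ObservationKind.SHIFT:
        if expected.kind is not ExpectedKind.SHIFT_SET:
            return Verdict.MISMATCH
        ok = any(
            abs(observation.observed_delta_m - s) <= tol
            for s in expected.acceptable_shifts
        )
        return Verdict.MATCH if ok else Verdict.MISMATCH
    # NEW_SMALLER_PEAK
    if expected.kind is not ExpectedKind.CLEAVAGE_PEAKS:
        return Verdict.MISMATCH
    ok = any(
        abs(observation.new_peak_mz - m) <= tol for m in expected.cleavage_peak_masses
    )
    return Verdict.MATCH if ok else Verdict.MISMATCH


def score_candidate(
    candidate: CandidateRecord,
    obs: ObservationSet,
    rules: RuleSet,
    mode: FilterMode = FilterMode.STRICT,
    threshold: float = 0.75,
    tolerance: float = DEFAULT_TOLERANCE,
) -> ConsistencyScore:
    """Score one candidate against the observation set.

    Reagent-level verdicts compare the observation with the candidate's
    forward-predicted outcome; rules flagged unreliable yield
    UNRELIABLE_RULE and are excluded from strict scoring. The parent-mass
    check is reported separately so a formula-inconsistent candidate is
    explained, not silently dropped.
    """
    parent_match = abs(candidate.structure.nominal_mass - obs.parent_mz) <= max(
        tolerance, DEFAULT_TOLERANCE
    )
    verdicts: list[tuple[ReagentId, Verdict]] = []
    n_match = n_tested = 0
    for o in obs.observations:
        expected = expected_outcome(candidate.structure, o.reagent_id, rules)
        v = _compare(o, expected, tolerance)
        verdicts.append((o.reagent_id, v))
        if v in (Verdict.MATCH, Verdict.MISMATCH):
            n_tested += 1
            if v is Verdict.MATCH:
                n_match += 1
    score = n_match / n_tested if n_tested else 0.0
    if mode is FilterMode.STRICT:
        retained = parent_match and n_match == n_tested
    else:
        retained = parent_match and (n_tested == 0 or score >= threshold)
    return ConsistencyScore(
        candidate_id=candidate.id,
        name=candidate.name,
        verdicts=tuple(verdicts),
        parent_match=parent_match,
        n_match=n_match,
        n_tested=n_tested,
        score=score,
        retained=retained,
        not_tested=n_tested == 0,
    )


@dataclass(frozen=True)
class FilterReport:
    scores: tuple[ConsistencyScore, ...]
    n_input: int
    n_retained: int
    mode: FilterMode
    threshold: float

    @property
    def reduction(self) -> float:
        """Fraction of candidates eliminated."""
        return 1.0 - self.n_retained / self.n_input if self.n_input else 0.0

    @property
    def retained_ids(self) -> tuple[str, ...]:
        return tuple(s.candidate_id for s in self.scores if s.retained)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.scores:
            row = {
                "id": s.candidate_id,
                "name": s.name,
                "parent_match": s.parent_match,
            }
            for rid, v in s.verdicts:
                row[rid.value] = v.value
            row.update(
                n_match=s.n_match,
                n_tested=s.n_tested,
                score=s.score,
                retained=s.retained,
            )
            rows.append(row)
        return pd.DataFrame(rows)

    def summary_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "n_retained": self.n_retained,
                "reduction": self.reduction,
                "mode": self.mode.value,
                "threshold": self.threshold,
                "retained_ids": list(self.retained_ids),
            },
            indent=2,
        )


def filter_candidates(
    candidates: Sequence[CandidateRecord],
    obs: ObservationSet,
    rules: RuleSet,
    mode: FilterMode = FilterMode.STRICT,
    threshold: float = 0.75,
    tolerance: float = DEFAULT_TOLERANCE,
) -> FilterReport:
    """Score and rank every candidate; sorted (retained, score, id)."""
    if not candidates:
        raise ValueError("empty candidate list")
    scores = [
        score_candidate(c, obs, rules, mode=mode, threshold=threshold, tolerance=tolerance)
        for c in candidates
    ]
    scores.sort(key=lambda s: (not s.retained, -s.score, s.candidate_id))
    return FilterReport(
        scores=tuple(scores),
        n_input=len(scores),
        n_retained=sum(1 for s in scores if s.retained),
        mode=mode,
        threshold=threshold,
    )
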