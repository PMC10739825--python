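"""Decision-tree classification of O-functionalities from derivatization data.

The classifier walks the four-step decision pathway for an unknown of known
molecular mass:

1. **TMSH** (methylation). No peak shift → the unknown carries an ether or a
   carboxylic ester; a shift of ≈ +46·k identifies k aldehyde groups at once;
   any other shift points to hydroxyl / carboxylic acid / ketone chemistry.
2. **NH4OH** (hydrolysis) separates the no-shift branch: ethers stay silent,
   esters produce a new smaller-mass peak (the liberated alcohol).
3. **TFAA** (acylation) is hydroxyl-selective: a shift of +96·k counts k OH
   groups (retention moves earlier); no shift excludes OH.
4. **DMF-DMA** methylates carboxylic acids only (+14/+18), separating COOH
   from ketones; its +46 response doubles as aldehyde support.

TMSCHN2 and the borate/amine imine route are supportive: they can raise or
lower confidence but never flip a branch. Ether presence is only ever
established by elimination. Mutually impossible observations (e.g. TMSH
silent but TFAA shifted) yield a structured CONTRADICTION result, not an
exception.

For multifunctional unknowns the linear pathway is generalized by
:func:`consistent_group_multisets`, which enumerates every functional-group
multiset whose predicted response under each observed reagent matches the
data within tolerance.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

from .chem_core import FunctionalGroup
from .reaction_rules import (
    OutcomeKind,
    ReagentId,
    RetentionDirection,
    RuleSet,
)

#: Default mass tolerance in Da — unit-mass (single-quadrupole) data.
DEFAULT_TOLERANCE = 0.5

_SUPPORTIVE = (ReagentId.TMSCHN2, ReagentId.BORATE_AMINE)
_CORE = (ReagentId.TMSH, ReagentId.NH4OH, ReagentId.TFAA, ReagentId.DMF_DMA)


class ObservationKind(str, Enum):
    NO_CHANGE = "NO_CHANGE"
    SHIFT = "SHIFT"
    NEW_SMALLER_PEAK = "NEW_SMALLER_PEAK"


@dataclass(frozen=True)
class Observation:
    """One reagent's experimental outcome for a single unknown."""

    reagent_id: ReagentId
    kind: ObservationKind
    observed_delta_m: float | None = None
    new_peak_mz: float | None = None
    retention_direction: RetentionDirection = RetentionDirection.UNKNOWN
    tolerance: float = DEFAULT_TOLERANCE

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValueError("tolerance must be non-negative")
        if self.kind is ObservationKind.SHIFT and self.observed_delta_m is None:
            raise ValueError("SHIFT observation requires observed_delta_m")
        if self.kind is ObservationKind.NEW_SMALLER_PEAK and self.new_peak_mz is None:
            raise ValueError("NEW_SMALLER_PEAK observation requires new_peak_mz")


@dataclass(frozen=True)
class ObservationSet:
    """Per-reagent observations for one unknown with parent molecular ion."""

    parent_mz: float
    observations: tuple[Observation, ...]

    def __post_init__(self) -> None:
        if self.parent_mz <= 0:
            raise ValueError("parent_mz must be positive")
        seen: set[ReagentId] = set()
        for o in self.observations:
            if o.reagent_id in seen:
                raise ValueError(f"duplicate observation for {o.reagent_id}")
            seen.add(o.reagent_id)
            if (
                o.kind is ObservationKind.NEW_SMALLER_PEAK
                and o.new_peak_mz >= self.parent_mz
            ):
                raise ValueError("new peak must be smaller than the parent m/z")
        # canonical order removes any sensitivity to input ordering
        object.__setattr__(
            self,
            "observations",
            tuple(sorted(self.observations, key=lambda o: o.reagent_id.value)),
        )

    def get(self, reagent_id: ReagentId) -> Observation | None:
        for o in self.observations:
            if o.reagent_id is reagent_id:
                return o
        return None

    def without(self, reagent_id: ReagentId) -> "ObservationSet":
        return ObservationSet(
            self.parent_mz,
            tuple(o for o in self.observations if o.reagent_id is not reagent_id),
        )


class Confidence(str, Enum):
    CONFIRMED = "CONFIRMED"
    SUPPORTED = "SUPPORTED"
    EXCLUDED_BY_ELIMINATION = "EXCLUDED_BY_ELIMINATION"
    INCONCLUSIVE = "INCONCLUSIVE"


@dataclass(frozen=True)
class GroupCall:
    group: FunctionalGroup
    count: int | None  # None when present but uncounted / undecided
    confidence: Confidence
    reason: str


@dataclass(frozen=True)
class TraceStep:
    step: str
    reagent_id: ReagentId | None
    branch: str
    detail: str


@dataclass(frozen=True)
class ClassificationResult:
    inferred_groups: Mapping[FunctionalGroup, int]
    calls: tuple[GroupCall, ...]
    decision_trace: tuple[TraceStep, ...]
    contradiction: tuple[ReagentId, ReagentId] | None = None
    unused_observations: tuple[ReagentId, ...] = ()

    @property
    def is_contradictory(self) -> bool:
        return self.contradiction is not None

    def to_json(self) -> str:
        return json.dumps(
            {
                "inferred_groups": {g.value: n for g, n in self.inferred_groups.items()},
                "calls": [
                    {
                        "group": c.group.value,
                        "count": c.count,
                        "confidence": c.confidence.value,
                        "reason": c.reason,
                    }
                    for c in self.calls
                ],
                "decision_trace": [
                    {
                        "step": t.step,
                        "reagent": t.reagent_id.value if t.reagent_id else None,
                        "branch": t.branch,
                        "detail": t.detail,
                    }
                    for t in self.decision_trace
                ],
                "contradiction": (
                    [r.value for r in self.contradiction] if self.contradiction else None
                ),
                "unused_observations": [r.value for r in self.unused_observations],
            },
            indent=2,
        )

    def text_report(self) -> str:
        lines = ["Decision pathway:"]
        for t in self.decision_trace:
            reagent = t.reagent_id.value if t.reagent_id else "-"
            lines.append(f"  [{t.step}] {reagent}: {t.branch} — {t.detail}")
        if self.contradiction:
            a, b = self.contradiction
            lines.append(f"CONTRADICTION between {a.value} and {b.value} observations")
        lines.append("Group calls:")
        for c in self.calls:
            count = "" if c.count is None else f" ×{c.count}"
            lines.append(f"  {c.group.value}{count}: {c.confidence.value} ({c.reason})")
        return "\n".join(lines)


def _near(value: float, target: float, tol: float) -> bool:
    return abs(value - target) <= tol


def _multiple_of(value: float, unit: int, tol: float, kmax: int = 8) -> int | None:
    """Return k when value ≈ unit·k for some k ≥ 1, else None."""
    for k in range(1, kmax + 1):
        if _near(value, unit * k, tol):
            return k
    return None


def _group_choice_sets(
    rules: RuleSet,
) -> dict[ReagentId, dict[FunctionalGroup, tuple[tuple[int, ...], bool, OutcomeKind]]]:
    """Per (reagent, group): (per-site Δm choices, reliable, outcome kind).

    Structure-free view of the rule matrix, used when reasoning about group
    multisets without a candidate structure (unconditional rules only)."""
    table: dict[ReagentId, dict[FunctionalGroup, tuple[tuple[int, ...], bool, OutcomeKind]]] = {}
    for reagent in ReagentId:
        row = {}
        for group in FunctionalGroup:
            rule = rules.rule_for(reagent, group)
            row[group] = (rule.shift_choices(), rule.reliable, rule.outcome)
        table[reagent] = row
    return table


# ---------------------------------------------------------------------------
# classify — the linear decision pathway
# ---------------------------------------------------------------------------


class _Builder:
    def __init__(self) -> None:
        self.calls: list[GroupCall] = []
        self.trace: list[TraceStep] = []
        self.used: set[ReagentId] = set()

    def step(self, step: str, reagent: ReagentId | None, branch: str, detail: str) -> None:
        self.trace.append(TraceStep(step, reagent, branch, detail))
        if reagent is not None:
            self.used.add(reagent)

    def call(
        self,
        group: FunctionalGroup,
        count: int | None,
        confidence: Confidence,
        reason: str,
    ) -> None:
        self.calls.append(GroupCall(group, count, confidence, reason))


def _finish(b: _Builder, obs: ObservationSet, contradiction=None) -> ClassificationResult:
    inferred: dict[FunctionalGroup, int] = {}
    for c in b.calls:
        if c.confidence in (Confidence.CONFIRMED, Confidence.SUPPORTED,
                            Confidence.EXCLUDED_BY_ELIMINATION) and c.count:
            inferred[c.group] = inferred.get(c.group, 0) + c.count
    unused = tuple(
        o.reagent_id for o in obs.observations if o.reagent_id not in b.used
    )
    return ClassificationResult(
        inferred_groups=inferred,
        calls=tuple(b.calls),
        decision_trace=tuple(b.trace),
        contradiction=contradiction,
        unused_observations=unused,
    )


def _retention_consistent(o: Observation, expected: RetentionDirection) -> bool:
    if o.retention_direction is RetentionDirection.UNKNOWN:
        return True
    return o.retention_direction is expected


def _adjust_confidence(
    b: _Builder, groups: tuple[FunctionalGroup, ...], upgrade: bool
) -> None:
    for i, c in enumerate(b.calls):
        if c.group not in groups or not c.count:
            continue
        if upgrade and c.confidence is Confidence.SUPPORTED:
            b.calls[i] = GroupCall(c.group, c.count, Confidence.CONFIRMED,
                                   c.reason + "; corroborated by a supportive reagent")
        elif not upgrade and c.confidence is Confidence.CONFIRMED:
            b.calls[i] = GroupCall(c.group, c.count, Confidence.SUPPORTED,
                                   c.reason + "; supportive reagent disagreed")


def _apply_supportive(b: _Builder, obs: ObservationSet) -> None:
    """Supportive reagents adjust confidence only — they never flip a branch."""
    methylatable = (FunctionalGroup.OH, FunctionalGroup.COOH)
    n_meth = sum(c.count for c in b.calls if c.group in methylatable and c.count)
    tm = obs.get(ReagentId.TMSCHN2)
    if tm is not None and n_meth:
        if tm.kind is ObservationKind.SHIFT:
            agrees = any(
                _near(tm.observed_delta_m, 14 * k, tm.tolerance)
                for k in range(1, n_meth + 1)
            )
            b.step("supportive", ReagentId.TMSCHN2, "shift",
                   f"TMSCHN2 shift {tm.observed_delta_m:+.0f} "
                   f"{'supports' if agrees else 'does not match'} the methylation count")
            _adjust_confidence(b, methylatable, upgrade=agrees)
        elif tm.kind is ObservationKind.NO_CHANGE:
            b.step("supportive", ReagentId.TMSCHN2, "no change",
                   "TMSCHN2 silent despite methylatable groups")
            _adjust_confidence(b, methylatable, upgrade=False)
    bo = obs.get(ReagentId.BORATE_AMINE)
    if bo is not None and bo.kind is ObservationKind.SHIFT:
        if any(c.group is FunctionalGroup.CHO and c.count for c in b.calls):
            b.step("supportive", ReagentId.BORATE_AMINE, "shift",
                   f"imine shift {bo.observed_delta_m:+.0f} supports CHO")
            _adjust_confidence(b, (FunctionalGroup.CHO,), upgrade=True)
        # an absent imine response is uninformative: the rule is unreliable


def classify(obs: ObservationSet, rules: RuleSet) -> ClassificationResult:
    """Infer present O-functional groups from per-reagent observations.

    Deterministic and order-independent; missing downstream observations give
    INCONCLUSIVE calls rather than errors. Requires at minimum the TMSH
    observation to make any call.
    """
    b = _Builder()
    tmsh = obs.get(ReagentId.TMSH)
    if tmsh is None:
        b.step("1", None, "missing", "no TMSH observation; pathway cannot start")
        for g in FunctionalGroup:
            b.call(g, None, Confidence.INCONCLUSIVE, "no TMSH observation")
        return _finish(b, obs)

    tol = tmsh.tolerance

    if tmsh.kind is ObservationKind.NO_CHANGE:
        # Contradiction screen: a methylation-silent unknown cannot shift
        # under the other derivatizations of the same chemistry.
        for rid in (ReagentId.TFAA, ReagentId.DMF_DMA, ReagentId.TMSCHN2):
            other = obs.get(rid)
            if other is not None and other.kind is ObservationKind.SHIFT:
                b.step("1", ReagentId.TMSH, "no change", "no methylation response")
                b.step("conflict", rid, "shift",
                       f"{rid.value} shift is impossible for a TMSH-silent unknown")
                return _finish(b, obs, contradiction=(ReagentId.TMSH, rid))
        b.step("1", ReagentId.TMSH, "no change",
               "no methylation response: ether or carboxylic ester")
        nh = obs.get(ReagentId.NH4OH)
        if nh is None:
            b.step("2", None, "missing", "NH4OH observation absent")
            b.call(FunctionalGroup.ETHER, None, Confidence.INCONCLUSIVE,
                   "cannot separate ether from ester without hydrolysis data")
            b.call(FunctionalGroup.ESTER, None, Confidence.INCONCLUSIVE,
                   "cannot separate ester from ether without hydrolysis data")
        elif nh.kind is ObservationKind.NO_CHANGE:
            b.step("2", ReagentId.NH4OH, "no change", "hydrolysis-silent")
            b.call(FunctionalGroup.ETHER, 1, Confidence.EXCLUDED_BY_ELIMINATION,
                   "inert to methylation and hydrolysis; all other classes excluded")
        elif nh.kind is ObservationKind.NEW_SMALLER_PEAK:
            b.step("2", ReagentId.NH4OH, "new smaller peak",
                   f"hydrolysis product at m/z {nh.new_peak_mz:g} (liberated alcohol)")
            b.call(FunctionalGroup.ESTER, 1, Confidence.CONFIRMED,
                   "ester cleaved by hydrolysis")
        else:
            b.step("2", ReagentId.NH4OH, "shift", "unexpected NH4OH shift")
            return _finish(b, obs, contradiction=(ReagentId.TMSH, ReagentId.NH4OH))
        _apply_supportive(b, obs)
        return _finish(b, obs)

    # --- TMSH shifted ------------------------------------------------------
    dm = tmsh.observed_delta_m
    retention_ok = _retention_consistent(tmsh, RetentionDirection.LATER)
    k_cho = _multiple_of(dm, 46, tol, kmax=4)
    if k_cho is not None:
        conf = Confidence.CONFIRMED if retention_ok else Confidence.SUPPORTED
        b.step("1", ReagentId.TMSH, "shift +46k",
               f"Δm {dm:+.0f} ≈ 46×{k_cho}: aldehyde-specific methylation")
        b.call(FunctionalGroup.CHO, k_cho, conf,
               f"TMSH Δm {dm:+.0f} matches the +46/site aldehyde pathway")
        _apply_supportive(b, obs)
        return _finish(b, obs)

    b.step("1", ReagentId.TMSH, "shift",
           f"Δm {dm:+.0f}: hydroxyl / carboxylic acid / ketone chemistry")

    # Step 3 — TFAA counts hydroxyl groups.
    tfaa = obs.get(ReagentId.TFAA)
    n_oh: int | None = None
    if tfaa is None:
        b.step("3", None, "missing", "TFAA observation absent")
        b.call(FunctionalGroup.OH, None, Confidence.INCONCLUSIVE,
               "hydroxyl count requires the TFAA acylation step")
    elif tfaa.kind is ObservationKind.SHIFT:
        k_oh = _multiple_of(tfaa.observed_delta_m, 96, tfaa.tolerance)
        if k_oh is None:
            b.step("3", ReagentId.TFAA, "shift",
                   f"Δm {tfaa.observed_delta_m:+.0f} is not a multiple of 96")
            b.call(FunctionalGroup.OH, None, Confidence.INCONCLUSIVE,
                   "TFAA shift does not match +96 per hydroxyl site")
        else:
            n_oh = k_oh
            conf = (
                Confidence.CONFIRMED
                if _retention_consistent(tfaa, RetentionDirection.EARLIER)
                else Confidence.SUPPORTED
            )
            b.step("3", ReagentId.TFAA, "shift +96k",
                   f"Δm {tfaa.observed_delta_m:+.0f} ≈ 96×{k_oh}: {k_oh} hydroxyl group(s)")
            b.call(FunctionalGroup.OH, k_oh, conf,
                   f"TFAA acylation shift counts {k_oh} OH site(s)")
    else:
        n_oh = 0
        b.step("3", ReagentId.TFAA, "no change", "no acylation: hydroxyl excluded")

    # Residual methylation shift once hydroxyl methylation is accounted for.
    residual: float | None = None
    if n_oh is not None:
        candidates = {dm}
        if n_oh:
            sums = {
                sum(p)
                for p in itertools.product((14, 18), repeat=n_oh)
            }
            candidates = {dm - s for s in sums}

        def _explainability(r: float) -> tuple[int, float]:
            # prefer a residual that is itself interpretable: zero first,
            # then a known per-site shift multiple, then smallest magnitude
            if _near(r, 0, tol):
                return (0, abs(r))
            if any(_multiple_of(r, u, tol) for u in (14, 18, 46)):
                return (1, abs(r))
            return (2, abs(r))

        residual = min(candidates, key=_explainability)

    # Step 4 — DMF-DMA separates COOH from ketones (and re-flags CHO).
    dmf = obs.get(ReagentId.DMF_DMA)
    if dmf is None:
        b.step("4", None, "missing", "DMF-DMA observation absent")
        if residual is None or not _near(residual, 0, tol):
            b.call(FunctionalGroup.COOH, None, Confidence.INCONCLUSIVE,
                   "COOH/ketone distinction requires the DMF-DMA step")
            b.call(FunctionalGroup.KETONE, None, Confidence.INCONCLUSIVE,
                   "COOH/ketone distinction requires the DMF-DMA step")
    elif dmf.kind is ObservationKind.SHIFT:
        ddm = dmf.observed_delta_m
        if _near(ddm, 14, dmf.tolerance) or _near(ddm, 18, dmf.tolerance):
            conf = (
                Confidence.CONFIRMED
                if _retention_consistent(dmf, RetentionDirection.LATER)
                else Confidence.SUPPORTED
            )
            b.step("4", ReagentId.DMF_DMA, "shift +14/+18",
                   f"Δm {ddm:+.0f}: acid-selective methylation")
            b.call(FunctionalGroup.COOH, 1, conf,
                   "DMF-DMA methylates carboxylic acids only")
        else:
            k = _multiple_of(ddm, 46, dmf.tolerance, kmax=4)
            if k is not None:
                b.step("4", ReagentId.DMF_DMA, "shift +46k",
                       f"Δm {ddm:+.0f} ≈ 46×{k}: aldehyde methylation pathway")
                b.call(FunctionalGroup.CHO, k, Confidence.CONFIRMED,
                       "DMF-DMA +46/site response identifies CHO")
                if residual is not None:
                    residual -= 46 * k
            else:
                b.step("4", ReagentId.DMF_DMA, "shift",
                       f"Δm {ddm:+.0f} matches neither +14/+18 nor +46k")
                b.call(FunctionalGroup.COOH, None, Confidence.INCONCLUSIVE,
                       "unassignable DMF-DMA shift")
    else:
        b.step("4", ReagentId.DMF_DMA, "no change", "no acid methylation")
        if residual is not None:
            k_ket = None
            for unit in (14, 18):
                k_ket = _multiple_of(residual, unit, tol)
                if k_ket is not None:
                    break
            if k_ket is not None:
                b.call(FunctionalGroup.KETONE, k_ket, Confidence.CONFIRMED,
                       "TMSH shift beyond hydroxyl methylation with DMF-DMA "
                       "silent indicates keto group(s)")
            elif not _near(residual, 0, tol):
                b.call(FunctionalGroup.KETONE, None, Confidence.INCONCLUSIVE,
                       f"unexplained residual TMSH shift {residual:+.0f}")
        else:
            b.call(FunctionalGroup.KETONE, None, Confidence.INCONCLUSIVE,
                   "residual methylation shift unknown without the TFAA step")

    _apply_supportive(b, obs)
    return _finish(b, obs)


# ---------------------------------------------------------------------------
# consistent_group_multisets — brute-force generalization for multifunctional
# unknowns
# ---------------------------------------------------------------------------


def _multiset_matches(
    multiset: Sequence[FunctionalGroup],
    obs: ObservationSet,
    table: Mapping[ReagentId, Mapping[FunctionalGroup, tuple[tuple[int, ...], bool, OutcomeKind]]],
) -> bool:
    for o in obs.observations:
        row = table[o.reagent_id]
        reliable_choices: list[tuple[int, ...]] = []
        optional_choices: list[tuple[int, ...]] = []
        cleaves = False
        for g in multiset:
            choices, reliable, outcome = row[g]
            if outcome is OutcomeKind.NONE:
                continue
            if outcome is OutcomeKind.CLEAVAGE:
                cleaves = True
                continue
            if reliable:
                reliable_choices.append(choices)
            else:
                # unreliable chemistry may or may not respond
                optional_choices.append(choices + (0,))
        if o.kind is ObservationKind.NO_CHANGE:
            if reliable_choices or cleaves:
                return False
        elif o.kind is ObservationKind.NEW_SMALLER_PEAK:
            # fragment masses are unknowable without a structure; presence of
            # a cleavable group is the testable statement
            if not cleaves:
                return False
        else:  # SHIFT
            if cleaves and not reliable_choices and not optional_choices:
                return False
            ok = False
            n = len(reliable_choices)
            for k in range(0, n + 1):
                for combo in itertools.combinations(reliable_choices, k):
                    for picks in itertools.product(*combo, *optional_choices):
                        total = sum(picks)
                        if total > 0 and _near(o.observed_delta_m, total, o.tolerance):
                            ok = True
                            break
                    if ok:
                        break
                if ok:
                    break
            if not ok:
                return False
    return True


def consistent_group_multisets(
    obs: ObservationSet, rules: RuleSet, max_groups: int = 3
) -> list[tuple[FunctionalGroup, ...]]:
    """Every functional-group multiset (size ≤ ``max_groups``) consistent with
    the observations under the rule matrix; sorted by size then
    lexicographically. An empty list means no hypothesis survives."""
    if max_groups < 1:
        raise ValueError("max_groups must be at least 1")
    table = _group_choice_sets(rules)
    out: list[tuple[FunctionalGroup, ...]] = []
    groups = sorted(FunctionalGroup, key=lambda g: g.value)
    for size in range(1, max_groups + 1):
        for multiset in itertools.combinations_with_replacement(groups, size):
            if _multiset_matches(multiset, obs, table):
                out.append(multiset)
    return out
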