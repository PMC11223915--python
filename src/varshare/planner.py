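"""Three-phase discrepancy-resolution planner and revision accounting.

A case is a variant whose two-tier groups (actionable {LP,P} versus
non-actionable {VUS,LB,B}) disagree between classifying laboratories.

Phase 1 assigns, per case:
  * exactly two labs            -> the lab with the oldest classification;
  * one lab against >= 2        -> that outlier lab;
  * two labs against >= 2       -> one of the two, drawn at random
                                   (the "first group"; when both groups have
                                   exactly two labs, the group whose oldest
                                   classification is older);
  * otherwise                   -> every classifying lab.

Phase 2 assigns the labs not yet involved (or, after an all-labs Phase 1,
the single remaining dissenter). Phase 3 moves to discussion: an email
group for cases with up to three labs, a meeting for four or more.

Revisions are counted over Phase 1-2 records only; Phase 3 discussions are
not revisions. The brute-force comparator re-reviews every classifying lab
of every initially discordant case once.
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .concordance import ACTIONABLE, round_pct, tier_group
from .errors import ManualReviewRequiredError, VarShareError

PHASE3_EMAIL_MAX_LABS = 3


def two_tier_group(label: str) -> str:
    return "actionable" if label in ACTIONABLE else "non-actionable"


@dataclass(frozen=True)
class DiscrepancyCase:
    """A two-tier-discordant variant with per-lab labels and dates."""

    variant_key: str
    labels: Mapping[str, str]  # lab -> five-tier label
    dates: Mapping[str, date]  # lab -> classification date

    def __post_init__(self) -> None:
        if set(self.labels) != set(self.dates):
            raise VarShareError(f"{self.variant_key}: labels/dates lab sets differ")

    @property
    def labs(self) -> tuple[str, ...]:
        return tuple(sorted(self.labels))

    @property
    def n_labs(self) -> int:
        return len(self.labels)

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {"actionable": [], "non-actionable": []}
        for lab in self.labs:
            out[two_tier_group(self.labels[lab])].append(lab)
        return out

    @property
    def is_discordant(self) -> bool:
        groups = self.groups()
        return bool(groups["actionable"]) and bool(groups["non-actionable"])

    def with_labels(self, new_labels: Mapping[str, str]) -> "DiscrepancyCase":
        merged = dict(self.labels)
        merged.update(new_labels)
        return replace(self, labels=merged)


@dataclass(frozen=True)
class Assignment:
    variant_key: str
    phase: int
    labs: tuple[str, ...]
    rule: str  # oldest | outlier | random-of-two | all | remaining |
    #            further-review | email-group | meeting

    def __post_init__(self) -> None:
        if not self.labs:
            raise VarShareError(f"{self.variant_key}: empty assignment")


def _oldest_lab(case: DiscrepancyCase, labs: Iterable[str]) -> str:
    return min(labs, key=lambda lab: (case.dates[lab], lab))


def plan_phase1(case: DiscrepancyCase, rng: random.Random) -> Assignment:
    if not case.is_discordant:
        raise VarShareError(f"{case.variant_key}: not two-tier discordant")
    groups = case.groups()
    sizes = {g: len(members) for g, members in groups.items()}

    if case.n_labs == 2:
        return Assignment(case.variant_key, 1, (_oldest_lab(case, case.labs),), "oldest")

    singleton = [g for g, n in sizes.items() if n == 1]
    if singleton and sizes[_other(singleton[0])] >= 2:
        outlier = groups[singleton[0]][0]
        return Assignment(case.variant_key, 1, (outlier,), "outlier")

    pairs = [g for g, n in sizes.items() if n == 2]
    if pairs and sizes[_other(pairs[0])] >= 2:
        if len(pairs) == 2:
            # both groups have exactly two labs: the "first group" is the
            # one holding the older oldest classification
            first = min(pairs, key=lambda g: min(case.dates[lab] for lab in groups[g]))
        else:
            first = pairs[0]
        pick = rng.choice(sorted(groups[first]))
        return Assignment(case.variant_key, 1, (pick,), "random-of-two")

    return Assignment(case.variant_key, 1, case.labs, "all")


def _other(group: str) -> str:
    return "non-actionable" if group == "actionable" else "actionable"


def plan_phase2(case: DiscrepancyCase, phase1: Assignment) -> Assignment:
    """Plan Phase 2 for a case still discordant after Phase-1 resubmission.

    ``case`` must carry the post-Phase-1 labels.
    """
    if not case.is_discordant:
        raise VarShareError(f"{case.variant_key}: not discordant entering Phase 2")
    if phase1.rule in ("oldest", "outlier", "random-of-two"):
        remaining = tuple(lab for lab in case.labs if lab not in phase1.labs)
        return Assignment(case.variant_key, 2, remaining, "remaining")
    if phase1.rule == "all":
        groups = case.groups()
        dissenters = [
            members for members in groups.values() if len(members) == 1
        ]
        if len(dissenters) != 1 or min(len(m) for m in groups.values()) != 1:
            raise ManualReviewRequiredError(
                f"{case.variant_key}: more than one dissenting lab after an "
                "all-labs Phase 1; no automated rule applies"
            )
        return Assignment(case.variant_key, 2, tuple(dissenters[0]), "further-review")
    raise VarShareError(f"unexpected Phase-1 rule {phase1.rule!r}")


def plan_phase3(case: DiscrepancyCase) -> Assignment:
    if not case.is_discordant:
        raise VarShareError(f"{case.variant_key}: not discordant entering Phase 3")
    rule = "email-group" if case.n_labs <= PHASE3_EMAIL_MAX_LABS else "meeting"
    return Assignment(case.variant_key, 3, case.labs, rule)


# ---------------------------------------------------------------------------
# Execution against scripted review outcomes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RevisionRecord:
    phase: int
    lab: str
    variant_key: str
    outcome: str  # five-tier label after the review


@dataclass
class ResolutionReport:
    initial_cases: list[DiscrepancyCase]
    assignments: list[Assignment] = field(default_factory=list)
    log: list[RevisionRecord] = field(default_factory=list)
    resolved_by_phase: dict[int, set[str]] = field(default_factory=dict)
    final_cases: dict[str, DiscrepancyCase] = field(default_factory=dict)
    flagged_manual: list[str] = field(default_factory=list)

    def entered(self, phase: int) -> set[str]:
        keys = {c.variant_key for c in self.initial_cases}
        for p in range(1, phase):
            keys -= self.resolved_by_phase.get(p, set())
        return keys


#: scripted post-review labels: (variant_key, phase, lab) -> new label.
ReviewScript = Mapping[tuple[str, int, str], str]


def run_resolution(
    cases: Sequence[DiscrepancyCase],
    script: ReviewScript,
    rng: random.Random,
) -> ResolutionReport:
    """Drive the three phases with scripted review outcomes.

    The planner decides who reviews; the script supplies what each assigned
    lab resubmits (defaulting to its current label, i.e. no change). Every
    executed Phase 1-2 assignment of one lab to one variant is one revision.
    Phase-3 discussions update labels but are not logged as revisions.
    """
    report = ResolutionReport(initial_cases=list(cases))
    state: dict[str, DiscrepancyCase] = {c.variant_key: c for c in cases}
    phase1_by_key: dict[str, Assignment] = {}
    active = [c.variant_key for c in cases]

    for phase in (1, 2, 3):
        resolved: set[str] = set()
        still_active: list[str] = []
        for key in active:
            case = state[key]
            if phase == 1:
                assignment = plan_phase1(case, rng)
                phase1_by_key[key] = assignment
            elif phase == 2:
                try:
                    assignment = plan_phase2(case, phase1_by_key[key])
                except ManualReviewRequiredError:
                    report.flagged_manual.append(key)
                    still_active.append(key)
                    continue
            else:
                assignment = plan_phase3(case)
            report.assignments.append(assignment)

            new_labels: dict[str, str] = {}
            for lab in assignment.labs:
                outcome = script.get((key, phase, lab), case.labels[lab])
                new_labels[lab] = outcome
                if phase < 3:
                    report.log.append(RevisionRecord(phase, lab, key, outcome))
            case = case.with_labels(new_labels)
            state[key] = case
            if not case.is_discordant:
                resolved.add(key)
            else:
                still_active.append(key)
        report.resolved_by_phase[phase] = resolved
        active = still_active
    report.final_cases = state
    return report


# ---------------------------------------------------------------------------
# Accounting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResolutionTotals:
    revisions_by_phase: Mapping[int, int]  # phases 1-2 only
    total_revisions: int
    entered_by_phase: Mapping[int, int]
    resolved_by_phase: Mapping[int, int]
    pct_resolved_by_phase: Mapping[int, float]
    overall_resolved: int
    pct_overall: float
    brute_force_revisions: int

    def to_dict(self) -> dict:
        return {
            "revisions_by_phase": dict(self.revisions_by_phase),
            "total_revisions": self.total_revisions,
            "entered_by_phase": dict(self.entered_by_phase),
            "resolved_by_phase": dict(self.resolved_by_phase),
            "pct_resolved_by_phase": dict(self.pct_resolved_by_phase),
            "overall_resolved": self.overall_resolved,
            "pct_overall": self.pct_overall,
            "brute_force_revisions": self.brute_force_revisions,
        }


def account(report: ResolutionReport) -> ResolutionTotals:
    """Totals, per-phase resolution percentages and brute-force comparison."""
    revisions = {1: 0, 2: 0}
    for record in report.log:
        if record.phase in revisions:
            revisions[record.phase] += 1
    entered = {phase: len(report.entered(phase)) for phase in (1, 2, 3)}
    resolved = {
        phase: len(report.resolved_by_phase.get(phase, set())) for phase in (1, 2, 3)
    }
    pct = {
        phase: round_pct(resolved[phase], entered[phase])
        for phase in (1, 2, 3)
        if entered[phase]
    }
    overall = sum(resolved.values())
    n_initial = len(report.initial_cases)
    return ResolutionTotals(
        revisions_by_phase=revisions,
        total_revisions=sum(revisions.values()),
        entered_by_phase=entered,
        resolved_by_phase=resolved,
        pct_resolved_by_phase=pct,
        overall_resolved=overall,
        pct_overall=round_pct(overall, n_initial) if n_initial else 0.0,
        brute_force_revisions=sum(c.n_labs for c in report.initial_cases),
    )


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def write_assignments(assignments: Sequence[Assignment], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["variant", "phase", "rule", "labs"])
        for a in assignments:
            writer.writerow([a.variant_key, a.phase, a.rule, ",".join(a.labs)])


def write_log(log: Sequence[RevisionRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["phase", "lab", "variant", "outcome"])
        for record in log:
            writer.writerow([record.phase, record.lab, record.variant_key, record.outcome])


def cases_from_ledger(ledger, min_labs: int = 2) -> list[DiscrepancyCase]:
    """Extract the two-tier-discordant cases from a classification ledger."""
    cases: list[DiscrepancyCase] = []
    for key in ledger.multi_classified():
        entries = {
            lab: sub for (k, lab), sub in ledger.entries.items() if k == key
        }
        labels = {lab: sub.classification for lab, sub in entries.items()}
        groups = {tier_group("two-tier", label) for label in labels.values()}
        if len(groups) < 2:
            continue
        cases.append(
            DiscrepancyCase(
                variant_key=key,
                labels=labels,
                dates={lab: sub.date for lab, sub in entries.items()},
            )
        )
    return sorted(cases, key=lambda c: c.variant_key)
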