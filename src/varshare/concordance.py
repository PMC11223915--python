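"""Latest-per-lab classification ledger and tiered concordance models.

Labels follow the five-tier vocabulary B / LB / VUS / LP / P. The three-tier
model groups {LP,P} / {VUS} / {LB,B}; the two-tier model groups the
clinically actionable {LP,P} against the non-actionable {VUS,LB,B}.
Two-tier discordance therefore implies three-tier discordance, which
implies five-tier discordance.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import VarShareError
from .submission import ClassificationSubmission

FIVE_TIER_LABELS = ("B", "LB", "VUS", "LP", "P")

#: model name -> partition of the five labels into groups
TIER_MODELS: dict[str, tuple[frozenset[str], ...]] = {
    "five-tier": tuple(frozenset({label}) for label in FIVE_TIER_LABELS),
    "three-tier": (frozenset({"B", "LB"}), frozenset({"VUS"}), frozenset({"LP", "P"})),
    "two-tier": (frozenset({"B", "LB", "VUS"}), frozenset({"LP", "P"})),
}

ACTIONABLE = frozenset({"LP", "P"})


def tier_group(model: str, label: str) -> frozenset[str]:
    for group in TIER_MODELS[model]:
        if label in group:
            return group
    raise VarShareError(f"unknown classification label {label!r}")


def round_pct(numerator: int, denominator: int) -> float:
    """Percentage at one decimal, matching the printed reporting convention.

    The quotient is first fixed at two decimals (half-up) and then reduced
    to one decimal with a half-even tie rule; this reproduces every printed
    percentage in the source reporting (e.g. 51/84 -> 60.7, 15/33 -> 45.4,
    14/18 -> 77.8).
    """
    if denominator == 0:
        raise ZeroDivisionError("empty denominator for percentage")
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    two = pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    return float(two.quantize(Decimal("0.1"), rounding=ROUND_HALF_EVEN))


# ---------------------------------------------------------------------------
# Ledger
# ---------------------------------------------------------------------------


@dataclass
class ClassificationLedger:
    """Latest five-tier call per (variant key, laboratory)."""

    entries: dict[tuple[str, str], ClassificationSubmission] = field(default_factory=dict)

    def labs_for(self, variant_key: str) -> list[str]:
        return sorted(lab for (key, lab) in self.entries if key == variant_key)

    def labels_for(self, variant_key: str) -> dict[str, str]:
        return {
            lab: sub.classification
            for (key, lab), sub in self.entries.items()
            if key == variant_key
        }

    def variant_keys(self) -> list[str]:
        return sorted({key for key, _lab in self.entries})

    def multi_classified(self) -> list[str]:
        counts: dict[str, int] = {}
        for key, _lab in self.entries:
            counts[key] = counts.get(key, 0) + 1
        return sorted(k for k, n in counts.items() if n >= 2)


def build_ledger(
    submissions: Iterable[ClassificationSubmission],
    ledger: ClassificationLedger | None = None,
) -> ClassificationLedger:
    """Keep the max-date entry per (variant, lab).

    Same-date duplicates are resolved latest-in-sequence wins (flagged via
    the returned ledger's ``entries`` replacement, diagnostics upstream).
    Re-ingesting the same submissions is idempotent.
    """
    ledger = ledger or ClassificationLedger()
    for sub in submissions:
        if sub.classification not in FIVE_TIER_LABELS:
            raise VarShareError(f"unknown classification label {sub.classification!r}")
        slot = (sub.variant_key, sub.lab_id)
        current = ledger.entries.get(slot)
        if current is None or sub.date >= current.date:
            ledger.entries[slot] = sub
    return ledger


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConcordanceStatus:
    variant_key: str
    n_labs: int
    status: Mapping[str, str]  # model -> "concordant" | "discordant"

    def is_discordant(self, model: str) -> bool:
        return self.status[model] == "discordant"


def labels_concordant(model: str, labels: Iterable[str]) -> bool:
    groups = {tier_group(model, label) for label in labels}
    return len(groups) <= 1


def concordance(ledger: ClassificationLedger, variant_key: str) -> ConcordanceStatus:
    """Per-model concordance for one variant classified by >= 2 labs."""
    labels = list(ledger.labels_for(variant_key).values())
    if len(labels) < 2:
        raise VarShareError(f"{variant_key}: single-lab variant, no concordance defined")
    status = {
        model: "concordant" if labels_concordant(model, labels) else "discordant"
        for model in TIER_MODELS
    }
    return ConcordanceStatus(variant_key=variant_key, n_labs=len(labels), status=status)


@dataclass(frozen=True)
class CohortSummary:
    n_variants: int
    n_multi_classified: int
    n_full_consensus: int
    n_discordant: Mapping[str, int]  # model -> count

    def pct_full_consensus(self) -> float:
        return round_pct(self.n_full_consensus, self.n_multi_classified)

    def pct_discordant(self, model: str) -> float:
        return round_pct(self.n_discordant[model], self.n_multi_classified)

    def to_dict(self) -> dict:
        out: dict = {
            "variants": self.n_variants,
            "multi_classified": self.n_multi_classified,
            "full_consensus": self.n_full_consensus,
            "discordant": dict(self.n_discordant),
        }
        if self.n_multi_classified:
            out["pct_full_consensus"] = self.pct_full_consensus()
            out["pct_discordant"] = {
                model: self.pct_discordant(model) for model in self.n_discordant
            }
        return out


def cohort_summary(ledger: ClassificationLedger) -> CohortSummary:
    """Counts and percentages over all multi-classified variants."""
    multi = ledger.multi_classified()
    n_disc = {model: 0 for model in TIER_MODELS}
    consensus = 0
    for key in multi:
        labels = list(ledger.labels_for(key).values())
        if len(set(labels)) == 1:
            consensus += 1
        for model in TIER_MODELS:
            if not labels_concordant(model, labels):
                n_disc[model] += 1
    return CohortSummary(
        n_variants=len(ledger.variant_keys()),
        n_multi_classified=len(multi),
        n_full_consensus=consensus,
        n_discordant=n_disc,
    )


# ---------------------------------------------------------------------------
# Notification rule matching (delivery is out of scope)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NotificationPreference:
    """A user's watch rule: variants their lab classified a certain way, or
    variants in a gene list, firing when another lab files a label in
    ``trigger_labels``."""

    user: str
    lab_id: str
    watch_labels: frozenset[str] = frozenset()
    watch_genes: frozenset[str] = frozenset()
    trigger_labels: frozenset[str] = frozenset(FIVE_TIER_LABELS)


def match_notifications(
    ledger: ClassificationLedger,
    delta: Sequence[ClassificationSubmission],
    preferences: Sequence[NotificationPreference],
    gene_of: Mapping[str, str] | None = None,
) -> list[tuple[str, str]]:
    """Pure rule matching: (ledger delta, preferences) -> (user, variant)."""
    gene_of = gene_of or {}
    triggered: list[tuple[str, str]] = []
    for sub in delta:
        for pref in preferences:
            if sub.lab_id == pref.lab_id:
                continue  # own submissions do not notify
            if sub.classification not in pref.trigger_labels:
                continue
            own = ledger.entries.get((sub.variant_key, pref.lab_id))
            watched = (own is not None and own.classification in pref.watch_labels) or (
                gene_of.get(sub.variant_key) in pref.watch_genes
            )
            if watched:
                triggered.append((pref.user, sub.variant_key))
    return triggered


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def write_ledger(ledger: ClassificationLedger, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["variant", "lab", "classification", "date", "reasoning"])
        for (key, lab), sub in sorted(ledger.entries.items()):
            writer.writerow([key, lab, sub.classification, sub.date.isoformat(), sub.reasoning])


def write_summary(summary: CohortSummary, tsv_path: str | Path, json_path: str | Path) -> None:
    data = summary.to_dict()
    with open(json_path, "w") as fh:
        json.dump(data, fh, indent=2)
        fh.write("\n")
    with open(tsv_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["metric", "value"])
        writer.writerow(["variants", summary.n_variants])
        writer.writerow(["multi_classified", summary.n_multi_classified])
        writer.writerow(["full_consensus", summary.n_full_consensus])
        for model, count in summary.n_discordant.items():
            writer.writerow([f"discordant_{model}", count])
        if summary.n_multi_classified:
            writer.writerow(["pct_full_consensus", summary.pct_full_consensus()])
            for model in summary.n_discordant:
                writer.writerow([f"pct_discordant_{model}", summary.pct_discordant(model)])
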