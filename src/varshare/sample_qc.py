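"""Cohort-level sample tests: noisy, empty, duplicated and kinship.

Noisy/empty detection uses Tukey's fences on the per-sample variant-count
distribution with asymmetric multipliers (upper k=5, lower k=4). Duplicate
detection scores the mean of the reciprocal variant-overlap fractions
(cutoff: score strictly greater than 0.9). Kinship uses the robust pairwise
relatedness estimator

    phi = (N_het,het - 2 * N_opposite_hom) / (N_het(a) + N_het(b))

with relatedness declared at phi >= 0.25. All pairwise tests are restricted
to the intersection of the two samples' panel regions, since panels differ
between laboratories.

Noisy, empty and duplicated samples are excluded from insertion; kin-related
samples are inserted but deduplicated in the allele-frequency calculation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import CohortTooSmallError
from .regions import PanelRegions

DUPLICATE_CUTOFF = 0.9
KINSHIP_CUTOFF = 0.25
TUKEY_K_UPPER = 5.0
TUKEY_K_LOWER = 4.0


@dataclass(frozen=True)
class SampleProfile:
    """Post-record-QC view of one individual's callset.

    ``genotypes`` maps a site key ``(chrom, pos)`` to the alternate-allele
    dosage (1 het, 2 hom-alt) of the variant called there; covered sites
    absent from the map are taken as homozygous reference.
    """

    sample_id: str
    variant_keys: frozenset[str]
    panel: PanelRegions
    genotypes: Mapping[tuple[str, int], int] = field(default_factory=dict)
    positions: Mapping[str, tuple[str, int]] = field(default_factory=dict)  # key -> site
    family_id: str | None = None
    submission_index: int = 0

    @property
    def variant_count(self) -> int:
        return len(self.variant_keys)


# ---------------------------------------------------------------------------
# Noisy / empty
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TukeyFences:
    lower: float
    upper: float
    k_lower: float = TUKEY_K_LOWER
    k_upper: float = TUKEY_K_UPPER


def tukey_bounds(
    counts: Sequence[int], k_lower: float = TUKEY_K_LOWER, k_upper: float = TUKEY_K_UPPER
) -> TukeyFences:
    """Fences ``(Q1 - k_lower*IQR, Q3 + k_upper*IQR)``.

    Quartiles use linear interpolation between order statistics; at least
    four samples are required for the quartiles to be meaningful.
    """
    if len(counts) < 4:
        raise CohortTooSmallError(f"need >= 4 samples for fences, got {len(counts)}")
    q1, q3 = np.quantile(np.asarray(counts, dtype=float), [0.25, 0.75], method="linear")
    iqr = q3 - q1
    return TukeyFences(lower=q1 - k_lower * iqr, upper=q3 + k_upper * iqr,
                       k_lower=k_lower, k_upper=k_upper)


def detect_noisy_empty(profiles: Sequence[SampleProfile]) -> dict[str, str]:
    """Per-sample verdicts: 'noisy', 'empty' or 'ok' (strict inequalities)."""
    fences = tukey_bounds([p.variant_count for p in profiles])
    verdicts: dict[str, str] = {}
    for p in profiles:
        if p.variant_count > fences.upper:
            verdicts[p.sample_id] = "noisy"
        elif p.variant_count < fences.lower:
            verdicts[p.sample_id] = "empty"
        else:
            verdicts[p.sample_id] = "ok"
    return verdicts


# ---------------------------------------------------------------------------
# Duplicates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DuplicateScore:
    sample_a: str
    sample_b: str
    p1: float
    p2: float

    @property
    def score(self) -> float:
        return (self.p1 + self.p2) / 2.0

    @property
    def is_duplicate(self) -> bool:
        return self.score > DUPLICATE_CUTOFF


def _keys_in_region(profile: SampleProfile, region: PanelRegions) -> frozenset[str]:
    if not profile.positions:
        return profile.variant_keys
    return frozenset(
        k for k in profile.variant_keys
        if k in profile.positions and region.contains(*profile.positions[k])
    )


def duplicate_score(a: SampleProfile, b: SampleProfile) -> DuplicateScore | None:
    """Presence-based overlap score over the panel intersection.

    Returns None (pair skipped) when the panel intersection is empty or
    neither sample has a variant inside it.
    """
    shared = a.panel.intersect(b.panel)
    if shared.is_empty:
        return None
    ka, kb = _keys_in_region(a, shared), _keys_in_region(b, shared)
    if not ka and not kb:
        return None
    p1 = len(ka & kb) / len(ka) if ka else 0.0
    p2 = len(ka & kb) / len(kb) if kb else 0.0
    return DuplicateScore(a.sample_id, b.sample_id, p1, p2)


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KinshipEstimate:
    sample_a: str
    sample_b: str
    phi: float
    n_shared_sites: int

    @property
    def is_related(self) -> bool:
        return self.phi >= KINSHIP_CUTOFF


def kinship(a: SampleProfile, b: SampleProfile) -> KinshipEstimate | None:
    """Robust pairwise relatedness over shared biallelic sites.

    Sites are the union of both samples' called sites restricted to the
    panel intersection; a sample with no call at a covered site counts as
    homozygous reference there. Returns None when neither sample is
    heterozygous anywhere (estimator undefined).
    """
    shared = a.panel.intersect(b.panel)
    if shared.is_empty:
        return None
    sites = {
        s for s in set(a.genotypes) | set(b.genotypes) if shared.contains(*s)
    }
    n_hethet = n_opp = n_het_a = n_het_b = 0
    for site in sites:
        ga = a.genotypes.get(site, 0)
        gb = b.genotypes.get(site, 0)
        if ga == 1:
            n_het_a += 1
        if gb == 1:
            n_het_b += 1
        if ga == 1 and gb == 1:
            n_hethet += 1
        if {ga, gb} == {0, 2}:
            n_opp += 1
    denom = n_het_a + n_het_b
    if denom == 0:
        return None
    phi = (n_hethet - 2.0 * n_opp) / denom
    return KinshipEstimate(a.sample_id, b.sample_id, phi, len(sites))


# ---------------------------------------------------------------------------
# Clustering and the cohort driver
# ---------------------------------------------------------------------------


def relatedness_clusters(
    sample_ids: Sequence[str],
    kin_pairs: Iterable[tuple[str, str]],
    family_ids: Mapping[str, str | None] | None = None,
) -> list[frozenset[str]]:
    """Connected components of the kinship-or-same-family graph."""
    parent = {s: s for s in sample_ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    for x, y in kin_pairs:
        if x in parent and y in parent:
            union(x, y)
    if family_ids:
        by_family: dict[str, list[str]] = {}
        for sid in sample_ids:
            fam = family_ids.get(sid)
            if fam:
                by_family.setdefault(fam, []).append(sid)
        for members in by_family.values():
            for other in members[1:]:
                union(members[0], other)
    clusters: dict[str, set[str]] = {}
    for sid in sample_ids:
        clusters.setdefault(find(sid), set()).add(sid)
    return [frozenset(members) for members in clusters.values()]


@dataclass
class CohortQCResult:
    verdicts: dict[str, str]              # sample -> noisy/empty/duplicate/ok
    duplicate_pairs: list[DuplicateScore]
    kinship_pairs: list[KinshipEstimate]
    clusters: list[frozenset[str]]
    insertable: list[str]
    warnings: list[str]


def run_cohort_qc(profiles: Sequence[SampleProfile]) -> CohortQCResult:
    """Run all four tests and derive insertability plus AF clusters.

    Of a duplicate pair, the later-submitted sample is the one rejected.
    """
    warnings: list[str] = []
    try:
        verdicts = detect_noisy_empty(profiles)
    except CohortTooSmallError as exc:
        warnings.append(f"noisy/empty tests skipped: {exc}")
        verdicts = {p.sample_id: "ok" for p in profiles}

    dup_scores: list[DuplicateScore] = []
    kin_estimates: list[KinshipEstimate] = []
    by_id = {p.sample_id: p for p in profiles}
    for a, b in combinations(profiles, 2):
        if verdicts[a.sample_id] != "ok" or verdicts[b.sample_id] != "ok":
            continue
        dup = duplicate_score(a, b)
        if dup is None:
            warnings.append(f"duplicate test skipped for {a.sample_id}/{b.sample_id}")
        else:
            dup_scores.append(dup)
            if dup.is_duplicate:
                later = max(a, b, key=lambda p: p.submission_index)
                verdicts[later.sample_id] = "duplicate"
        kin = kinship(a, b)
        if kin is None:
            warnings.append(f"kinship test skipped for {a.sample_id}/{b.sample_id}")
        else:
            kin_estimates.append(kin)

    insertable = [p.sample_id for p in profiles if verdicts[p.sample_id] == "ok"]
    kin_edges = [
        (k.sample_a, k.sample_b)
        for k in kin_estimates
        if k.is_related and k.sample_a in insertable and k.sample_b in insertable
    ]
    clusters = relatedness_clusters(
        insertable, kin_edges, {sid: by_id[sid].family_id for sid in insertable}
    )
    return CohortQCResult(
        verdicts=verdicts,
        duplicate_pairs=dup_scores,
        kinship_pairs=kin_estimates,
        clusters=clusters,
        insertable=insertable,
        warnings=warnings,
    )


def profile_from_vcf(
    path: str | Path,
    sample_id: str,
    panel: PanelRegions,
    min_depth: int,
    reference=None,
    caller: str = "generic",
    family_id: str | None = None,
    submission_index: int = 0,
) -> SampleProfile:
    """Read a single-sample VCF through record QC into a SampleProfile.

    When a reference is supplied, variant keys use the left-normalized
    canonical identity; otherwise the as-submitted coordinates.
    """
    from .core import shift_left
    from .record_qc import filter_records, read_sample_vcf

    records = read_sample_vcf(path, caller=caller)
    kept, _dropped = filter_records(records, panel, min_depth)
    keys: set[str] = set()
    genotypes: dict[tuple[str, int], int] = {}
    positions: dict[str, tuple[str, int]] = {}
    for rec in kept:
        v = rec.variant
        if reference is not None and v.chrom in reference:
            v = shift_left(v, reference[v.chrom])
        keys.add(v.key)
        positions[v.key] = (v.chrom, v.pos)
        dosage = sum(1 for a in (rec.genotype or ()) if a != 0)
        genotypes[(v.chrom, v.pos)] = dosage
    return SampleProfile(
        sample_id=sample_id,
        variant_keys=frozenset(keys),
        panel=panel,
        genotypes=genotypes,
        positions=positions,
        family_id=family_id,
        submission_index=submission_index,
    )


def write_cohort_report(result: CohortQCResult, path: str | Path) -> None:
    """TSV report: one row per sample verdict and per pairwise statistic."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["subject", "test", "statistic", "verdict"])
        for sid, verdict in sorted(result.verdicts.items()):
            writer.writerow([sid, "noisy-empty-duplicate", "", verdict])
        for dup in result.duplicate_pairs:
            writer.writerow(
                [f"{dup.sample_a}|{dup.sample_b}", "duplicate", f"{dup.score:.4f}",
                 "duplicate" if dup.is_duplicate else "ok"]
            )
        for kin in result.kinship_pairs:
            writer.writerow(
                [f"{kin.sample_a}|{kin.sample_b}", "kinship", f"{kin.phi:.4f}",
                 "related" if kin.is_related else "unrelated"]
            )
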