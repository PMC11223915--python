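"""Deterministic synthetic-data generation for every pipeline input.

Everything here is seeded and byte-reproducible: reference FASTA, panel BED,
per-individual VCFs with injected pathologies (duplicates, noisy/empty
samples, parent-offspring pairs), and per-lab classification tables
realizing a requested concordance/resolution profile.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

from .concordance import ACTIONABLE
from .errors import InfeasibleProfileError
from .planner import DiscrepancyCase, two_tier_group
from .regions import PanelRegions
from .sample_qc import SampleProfile
from .submission import ClassificationSubmission

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# Reference sequences
# ---------------------------------------------------------------------------


def make_reference(
    seed: int,
    length: int,
    repeat_tracts: Sequence[tuple[int, str, int]] = (),
) -> str:
    """Random sequence with requested repeat tracts spliced in.

    ``repeat_tracts`` entries are (1-based position, motif, copy count);
    the tract overwrites the random background at that locus.
    """
    rng = random.Random(seed)
    seq = [rng.choice(_BASES) for _ in range(length)]
    for pos, motif, count in repeat_tracts:
        tract = motif * count
        if pos < 1 or pos - 1 + len(tract) > length:
            raise ValueError(f"repeat tract at {pos} exceeds sequence length {length}")
        seq[pos - 1 : pos - 1 + len(tract)] = list(tract)
    return "".join(seq)


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortRecipe:
    """Requested structure of a simulated cohort."""

    seed: int
    n_unrelated: int = 20
    n_parent_offspring: int = 0  # pairs, each sharing a family identifier
    n_duplicates: int = 0        # near-copies of existing unrelated samples
    n_noisy: int = 0
    n_empty: int = 0
    n_sites: int = 2000
    maf: float = 0.2
    chrom: str = "1"
    site_spacing: int = 10
    depth: int = 50

    def __post_init__(self) -> None:
        if self.n_duplicates > self.n_unrelated:
            raise InfeasibleProfileError("more duplicates requested than source samples")
        if self.n_sites < 1 or not (0 < self.maf < 1):
            raise InfeasibleProfileError("need n_sites >= 1 and 0 < maf < 1")


@dataclass
class SimulatedSample:
    sample_id: str
    genotypes: dict[int, int]  # site index -> dosage (1/2); absent = hom-ref
    family_id: str | None = None
    role: str = "unrelated"    # unrelated | parent | offspring | duplicate | noisy | empty
    sex: str = "F"


@dataclass
class SimulatedCohort:
    recipe: CohortRecipe
    reference: str
    sites: list[int]           # 1-based positions
    alts: list[str]            # per-site alt base
    samples: list[SimulatedSample]
    panel: PanelRegions

    def site_key(self, index: int) -> str:
        pos = self.sites[index]
        return f"{self.recipe.chrom}:{pos}:{self.reference[pos - 1]}:{self.alts[index]}"

    def profiles(self) -> list[SampleProfile]:
        chrom = self.recipe.chrom
        out = []
        for order, sample in enumerate(self.samples):
            keys = frozenset(self.site_key(i) for i in sample.genotypes)
            out.append(
                SampleProfile(
                    sample_id=sample.sample_id,
                    variant_keys=keys,
                    panel=self.panel,
                    genotypes={
                        (chrom, self.sites[i]): dosage
                        for i, dosage in sample.genotypes.items()
                    },
                    positions={
                        self.site_key(i): (chrom, self.sites[i]) for i in sample.genotypes
                    },
                    family_id=sample.family_id,
                    submission_index=order,
                )
            )
        return out

    def metadata(self) -> dict[str, dict[str, str]]:
        return {
            s.sample_id: {
                "sex": s.sex,
                "suspicion": "hereditary cancer syndrome",
                "lab": "LAB01",
                "caller": "VarDict",
            }
            for s in self.samples
        }

    # -- file emission ------------------------------------------------------

    def write(self, outdir: str | Path) -> dict:
        """Emit FASTA, BED, one VCF per sample, individuals TSV and manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        chrom = self.recipe.chrom
        write_fasta({chrom: self.reference}, outdir / "reference.fa")
        self.panel.to_bed(outdir / "panel.bed")
        vcf_paths = {}
        for sample in self.samples:
            path = outdir / f"{sample.sample_id}.vcf"
            self._write_vcf(sample, path)
            vcf_paths[sample.sample_id] = path.name
        with open(outdir / "individuals.tsv", "w") as fh:
            fh.write("individual_id\tsex\tsuspicion\tfamily_id\n")
            for sample in self.samples:
                fh.write(
                    f"{sample.sample_id}\t{sample.sex}\thereditary cancer syndrome\t"
                    f"{sample.family_id or ''}\n"
                )
        manifest = {
            "seed": self.recipe.seed,
            "chrom": chrom,
            "reference": "reference.fa",
            "panel": "panel.bed",
            "individuals": "individuals.tsv",
            "vcfs": vcf_paths,
            "depth_threshold": 10,
            "caller": "VarDict",
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return manifest

    def _write_vcf(self, sample: SimulatedSample, path: Path) -> None:
        chrom = self.recipe.chrom
        depth = self.recipe.depth
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID={chrom},length={len(self.reference)}>\n")
            fh.write('##FILTER=<ID=PASS,Description="All filters passed">\n')
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                f"{sample.sample_id}\n"
            )
            for i in sorted(sample.genotypes):
                pos = self.sites[i]
                ref = self.reference[pos - 1]
                alt = self.alts[i]
                dosage = sample.genotypes[i]
                gt = "0/1" if dosage == 1 else "1/1"
                alt_reads = depth // 2 if dosage == 1 else depth
                ad = f"{depth - alt_reads},{alt_reads}"
                fh.write(
                    f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t100\tPASS\t.\t"
                    f"GT:AD:DP\t{gt}:{ad}:{depth}\n"
                )


def _draw_genotype(rng: random.Random, maf: float) -> int:
    return (rng.random() < maf) + (rng.random() < maf)


def simulate_cohort(recipe: CohortRecipe) -> SimulatedCohort:
    """Draw genotypes from the allele-frequency spectrum and inject
    duplicates, parent-offspring pairs and noisy/empty samples."""
    rng = random.Random(recipe.seed)
    span = recipe.n_sites * recipe.site_spacing + 10
    reference = make_reference(rng.randrange(2**31), span)
    sites = [i * recipe.site_spacing + 5 for i in range(recipe.n_sites)]
    alts = []
    for pos in sites:
        ref_base = reference[pos - 1]
        alts.append(rng.choice([b for b in _BASES if b != ref_base]))
    panel = PanelRegions.from_intervals([(recipe.chrom, 0, span)])

    samples: list[SimulatedSample] = []
    counter = 0

    def next_id(prefix: str = "S") -> str:
        nonlocal counter
        counter += 1
        return f"{prefix}{counter:04d}"

    for _ in range(recipe.n_unrelated):
        genotypes = {}
        for i in range(recipe.n_sites):
            dosage = _draw_genotype(rng, recipe.maf)
            if dosage:
                genotypes[i] = dosage
        samples.append(SimulatedSample(next_id(), genotypes))

    for pair in range(recipe.n_parent_offspring):
        family = f"FAM{pair + 1:03d}"
        parent_gt: dict[int, int] = {}
        child_gt: dict[int, int] = {}
        for i in range(recipe.n_sites):
            p = _draw_genotype(rng, recipe.maf)
            transmitted = (
                1 if p == 2 else (0 if p == 0 else (1 if rng.random() < 0.5 else 0))
            )
            other = 1 if rng.random() < recipe.maf else 0
            c = transmitted + other
            if p:
                parent_gt[i] = p
            if c:
                child_gt[i] = c
        samples.append(
            SimulatedSample(next_id(), parent_gt, family_id=family, role="parent")
        )
        samples.append(
            SimulatedSample(next_id(), child_gt, family_id=family, role="offspring")
        )

    for d in range(recipe.n_duplicates):
        source = samples[d]
        genotypes = dict(source.genotypes)
        # drop ~2% of calls so the copy is byte-distinct but > 90% shared
        for i in sorted(genotypes):
            if rng.random() < 0.02:
                del genotypes[i]
        samples.append(
            SimulatedSample(next_id("D"), genotypes, role="duplicate")
        )

    for _ in range(recipe.n_noisy):
        # a call at every site: far above any plausible upper fence
        genotypes = {i: 1 + (rng.random() < 0.1) for i in range(recipe.n_sites)}
        samples.append(SimulatedSample(next_id("N"), genotypes, role="noisy"))

    for _ in range(recipe.n_empty):
        samples.append(SimulatedSample(next_id("E"), {}, role="empty"))

    return SimulatedCohort(
        recipe=recipe,
        reference=reference,
        sites=sites,
        alts=alts,
        samples=samples,
        panel=panel,
    )


# ---------------------------------------------------------------------------
# Classification / resolution fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CaseSpec:
    """Structure of one two-tier-discordant case.

    ``n_first`` labs sit in the actionable group, ``n_other`` in the
    non-actionable group; ``resolve_phase`` is 1, 2, 3 or 0 (never).
    """

    n_first: int
    n_other: int
    resolve_phase: int

    @property
    def n_labs(self) -> int:
        return self.n_first + self.n_other


@dataclass(frozen=True)
class ConcordanceProfile:
    """Requested ledger composition for the concordance fixture."""

    n_consensus: int
    n_five_only: int     # e.g. {P, LP}: five-tier discordant only
    n_three_only: int    # e.g. {VUS, LB}: three-tier discordant, two-tier not
    cases: tuple[CaseSpec, ...]  # the two-tier-discordant cases
    n_single_lab: int = 0

    @property
    def n_two_tier(self) -> int:
        return len(self.cases)

    @property
    def n_multi_classified(self) -> int:
        return self.n_consensus + self.n_five_only + self.n_three_only + self.n_two_tier


def published_profile() -> ConcordanceProfile:
    """The worked-example composition: 2469 multi-classified variants,
    1697 in full consensus, 405 three-tier and 84 two-tier discordant;
    the 84 cases span 285 lab classifications and resolve 51/15/14 across
    the three phases (4 never resolve)."""
    cases: list[CaseSpec] = []
    cases += [CaseSpec(1, 1, 1)] * 10        # oldest rule, resolved in Phase 1
    cases += [CaseSpec(1, 2, 1)] * 9         # outlier
    cases += [CaseSpec(1, 3, 1)] * 15        # outlier
    cases += [CaseSpec(1, 4, 1)] * 17        # outlier
    cases += [CaseSpec(1, 1, 2)] * 8         # oldest, resolved in Phase 2
    cases += [CaseSpec(1, 1, 3)] * 5
    cases += [CaseSpec(1, 1, 0)] * 1
    cases += [CaseSpec(1, 2, 2)] * 6         # outlier, resolved later
    cases += [CaseSpec(1, 2, 3)] * 8
    cases += [CaseSpec(1, 2, 0)] * 3
    cases += [CaseSpec(2, 2, 2)] * 1         # random-of-two branch
    cases += [CaseSpec(3, 7, 3)] * 1         # all-labs branch, meeting in Phase 3
    return ConcordanceProfile(
        n_consensus=1697,
        n_five_only=367,
        n_three_only=321,
        cases=tuple(cases),
    )


@dataclass
class ClassificationFixture:
    submissions: list[ClassificationSubmission]
    cases: list[DiscrepancyCase]
    script: dict[tuple[str, int, str], str]
    profile: ConcordanceProfile

    def lab_tables(self) -> dict[str, list[dict]]:
        """Rows per lab, in the canonical column layout."""
        tables: dict[str, list[dict]] = {}
        for sub in self.submissions:
            chrom, pos, ref, alt = sub.variant_key.split(":")
            tables.setdefault(sub.lab_id, []).append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "classification": sub.classification,
                    "date": sub.date.isoformat(),
                    "reasoning": sub.reasoning,
                }
            )
        return tables

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        columns = ["chrom", "pos", "ref", "alt", "classification", "date", "reasoning"]
        for lab, rows in sorted(self.lab_tables().items()):
            with open(outdir / f"{lab}_classifications.tsv", "w") as fh:
                fh.write("\t".join(columns) + "\n")
                for row in rows:
                    fh.write("\t".join(str(row[c]) for c in columns) + "\n")
            spec = {
                "lab_id": lab,
                "column_map": {c: c for c in columns},
                "value_maps": {},
                "date_format": "%Y-%m-%d",
            }
            with open(outdir / f"{lab}_spec.json", "w") as fh:
                json.dump(spec, fh, indent=2, sort_keys=True)
                fh.write("\n")
        with open(outdir / "resolution_script.json", "w") as fh:
            json.dump(
                [
                    {"variant": k, "phase": p, "lab": lab, "outcome": outcome}
                    for (k, p, lab), outcome in sorted(self.script.items())
                ],
                fh,
                indent=2,
            )
            fh.write("\n")


_ACTIONABLE_LABEL = "P"
_NON_ACTIONABLE_LABEL = "VUS"
_LAB_POOL = 18


def _case_labs(rng: random.Random, n: int) -> list[str]:
    pool = [f"LAB{j:02d}" for j in range(1, _LAB_POOL + 1)]
    return sorted(rng.sample(pool, n))


def make_classification_fixture(
    profile: ConcordanceProfile, seed: int
) -> ClassificationFixture:
    """Emit per-lab submissions realizing ``profile`` exactly, plus the
    scripted post-review labels that drive the three resolution phases.

    The script is written so that resolution does not depend on which lab a
    random-of-two draw picks: scripted Phase-2 outcomes converge every
    remaining lab onto the designated group.
    """
    if any(spec.n_first < 1 or spec.n_other < 1 for spec in profile.cases):
        raise InfeasibleProfileError("every case needs labs in both two-tier groups")

    rng = random.Random(seed)
    submissions: list[ClassificationSubmission] = []
    cases: list[DiscrepancyCase] = []
    script: dict[tuple[str, int, str], str] = {}
    pos = 1000
    base_date = date(2019, 6, 1)

    def add(key: str, lab: str, label: str, when: date, why: str = "routine") -> None:
        submissions.append(
            ClassificationSubmission(
                lab_id=lab, classification=label, date=when, variant_key=key,
                reasoning=why,
            )
        )

    def next_key() -> str:
        nonlocal pos
        pos += 17
        return f"1:{pos}:A:C"

    for _ in range(profile.n_single_lab):
        add(next_key(), _case_labs(rng, 1)[0], rng.choice(("B", "VUS", "P")), base_date)

    for _ in range(profile.n_consensus):
        key = next_key()
        label = rng.choice(("B", "LB", "VUS", "LP", "P"))
        for lab in _case_labs(rng, 2):
            add(key, lab, label, base_date + timedelta(days=rng.randrange(365)))

    for _ in range(profile.n_five_only):
        key = next_key()
        labs = _case_labs(rng, 2)
        pair = rng.choice((("P", "LP"), ("B", "LB")))
        add(key, labs[0], pair[0], base_date)
        add(key, labs[1], pair[1], base_date + timedelta(days=30))

    for _ in range(profile.n_three_only):
        key = next_key()
        labs = _case_labs(rng, 2)
        pair = rng.choice((("VUS", "LB"), ("VUS", "B")))
        add(key, labs[0], pair[0], base_date)
        add(key, labs[1], pair[1], base_date + timedelta(days=30))

    for spec in profile.cases:
        key = next_key()
        labs = _case_labs(rng, spec.n_labs)
        first_group, other_group = labs[: spec.n_first], labs[spec.n_first :]
        labels: dict[str, str] = {}
        dates: dict[str, date] = {}
        # first-group classifications are strictly older: for two-lab cases
        # the oldest rule then designates the (single) first-group lab, and
        # for the 2v2 random branch the first group is well-defined
        for i, lab in enumerate(first_group):
            labels[lab] = _ACTIONABLE_LABEL
            dates[lab] = base_date - timedelta(days=400 - i)
        for i, lab in enumerate(other_group):
            labels[lab] = _NON_ACTIONABLE_LABEL
            dates[lab] = base_date + timedelta(days=10 + i)
        for lab in labs:
            add(key, lab, labels[lab], dates[lab], why="pre-resolution")
        cases.append(DiscrepancyCase(variant_key=key, labels=labels, dates=dates))

        is_all_rule = spec.n_first >= 3 and spec.n_other >= 3
        if spec.resolve_phase == 1:
            # phase-1 assignee is the lone first-group lab (oldest/outlier)
            script[(key, 1, first_group[0])] = _NON_ACTIONABLE_LABEL
        elif spec.resolve_phase == 2:
            # phase-1 review changes nothing; phase-2 converges the
            # remaining labs onto the first group, whoever reviewed first
            for lab in labs:
                script[(key, 2, lab)] = _ACTIONABLE_LABEL
        elif spec.resolve_phase == 3:
            if is_all_rule:
                # all labs reviewed in phase 1: all but one dissenter join
                # the majority; the dissenter holds through phase 2 and
                # concedes at the phase-3 meeting
                dissenter = first_group[0]
                for lab in first_group[1:]:
                    script[(key, 1, lab)] = _NON_ACTIONABLE_LABEL
                script[(key, 3, dissenter)] = _NON_ACTIONABLE_LABEL
            else:
                for lab in labs:
                    script[(key, 3, lab)] = _NON_ACTIONABLE_LABEL
        # resolve_phase == 0: no scripted change anywhere

    rng.shuffle(submissions)
    return ClassificationFixture(
        submissions=submissions, cases=cases, script=script, profile=profile
    )
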