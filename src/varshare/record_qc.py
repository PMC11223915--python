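"""Record-level hard filters applied to each VCF call before ingestion.

A record is dropped iff any of: FILTER is not PASS, genotype is
homozygous-reference (or missing/malformed), allele balance is below 0.2,
depth is below the submitter threshold, or the position lies outside the
panel regions. Boundary semantics are strict: AB exactly 0.2 and depth
exactly at the threshold both pass.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .core import GenomicVariant, decompose_multiallelic
from .regions import PanelRegions

MIN_ALLELE_BALANCE = 0.2

#: FORMAT-field dialects of the supported callers. "varscan" exposes the
#: ref depth as RD and a scalar alt depth as AD; everything else follows the
#: standard AD list layout.
CALLER_DIALECTS = ("generic", "varscan")


@dataclass(frozen=True)
class CallRecord:
    """One biallelic call for one sample."""

    variant: GenomicVariant
    genotype: tuple[int, ...] | None  # allele indices, None when missing
    depth: int | None
    ref_depth: int | None
    alt_depth: int | None
    filter_status: str = "PASS"
    depth_source: str = "DP"  # "DP" or "AD-sum"

    def allele_balance(self) -> float | None:
        """alt / (ref + alt) read fraction; None when undefined."""
        if self.ref_depth is None or self.alt_depth is None:
            return None
        denom = self.ref_depth + self.alt_depth
        if denom == 0:
            return None
        return self.alt_depth / denom


def allele_balance(record: CallRecord) -> float | None:
    return record.allele_balance()


@dataclass(frozen=True)
class FilterVerdict:
    keep: bool
    reasons: tuple[str, ...] = ()

    @property
    def first_reason(self) -> str | None:
        return self.reasons[0] if self.reasons else None


def filter_record(
    record: CallRecord, panel: PanelRegions, min_depth: int
) -> FilterVerdict:
    """Apply the hard filters; all failing reasons are accumulated."""
    reasons: list[str] = []
    if record.filter_status != "PASS":
        reasons.append("non-pass")
    gt = record.genotype
    if gt is None:
        reasons.append("missing-GT")
    elif any(a < 0 for a in gt):
        reasons.append("bad-GT")
    elif all(a == 0 for a in gt):
        reasons.append("hom-ref")
    ab = record.allele_balance()
    if record.ref_depth is None or record.alt_depth is None:
        reasons.append("no-AB")
    elif ab is None:
        reasons.append("no-AB")
    elif ab < MIN_ALLELE_BALANCE:
        reasons.append("low-AB")
    depth = record.depth
    if depth is None:
        reasons.append("no-depth")
    elif depth < min_depth:
        reasons.append("low-depth")
    v = record.variant
    if not panel.contains(v.chrom, v.pos):
        reasons.append("off-panel")
    return FilterVerdict(keep=not reasons, reasons=tuple(reasons))


def filter_records(
    records: Iterable[CallRecord], panel: PanelRegions, min_depth: int
) -> tuple[list[CallRecord], list[tuple[CallRecord, FilterVerdict]]]:
    """Partition records into kept and (dropped, verdict) lists."""
    kept: list[CallRecord] = []
    dropped: list[tuple[CallRecord, FilterVerdict]] = []
    for rec in records:
        verdict = filter_record(rec, panel, min_depth)
        if verdict.keep:
            kept.append(rec)
        else:
            dropped.append((rec, verdict))
    return kept, dropped


def write_qc_report(
    dropped: Sequence[tuple[CallRecord, FilterVerdict]], sample_id: str, path: str | Path
) -> None:
    """TSV log of dropped records and their first-fail reason."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample", "variant", "first_reason", "all_reasons"])
        for rec, verdict in dropped:
            writer.writerow(
                [sample_id, rec.variant.key, verdict.first_reason, ",".join(verdict.reasons)]
            )


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------


def _sample_field(sample, key):
    try:
        value = sample[key]
    except KeyError:
        return None
    if value is None:
        return None
    return value


def read_sample_vcf(path: str | Path, caller: str = "generic") -> list[CallRecord]:
    """Read a single-sample VCF into CallRecords, decomposing multiallelics.

    Depth comes from FORMAT/DP with an AD-sum fallback (flagged in
    ``depth_source``). The ``varscan`` dialect maps RD/AD (scalar) onto
    ref/alt depths.
    """
    import pysam

    if caller not in CALLER_DIALECTS:
        raise ValueError(f"unsupported caller dialect {caller!r}")

    records: list[CallRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        if len(sample_names) != 1:
            raise ValueError(f"{path}: expected single-sample VCF, found {len(sample_names)}")
        for rec in vcf:
            filters = list(rec.filter.keys())
            filter_status = "PASS" if filters == ["PASS"] else (";".join(filters) or ".")
            sample = rec.samples[sample_names[0]]
            gt_raw = _sample_field(sample, "GT")
            dp = _sample_field(sample, "DP")

            alts = [a for a in (rec.alts or ()) if a not in (None, "*", ".", "<NON_REF>")]
            variants = decompose_multiallelic(rec.chrom, rec.pos, rec.ref, alts)
            for alt_index, variant in enumerate(variants, start=1):
                if caller == "varscan":
                    ref_depth = _sample_field(sample, "RD")
                    ad = _sample_field(sample, "AD")
                    alt_depth = ad[0] if isinstance(ad, tuple) else ad
                else:
                    ad = _sample_field(sample, "AD")
                    ref_depth = ad[0] if ad is not None else None
                    alt_depth = (
                        ad[alt_index] if ad is not None and len(ad) > alt_index else None
                    )
                if gt_raw is None or any(a is None for a in gt_raw):
                    genotype = None
                else:
                    # project onto this alt: matching alt -> 1, anything else -> 0
                    genotype = tuple(1 if a == alt_index else 0 for a in gt_raw)
                depth, depth_source = dp, "DP"
                if depth is None and ref_depth is not None and alt_depth is not None:
                    depth, depth_source = ref_depth + alt_depth, "AD-sum"
                records.append(
                    CallRecord(
                        variant=variant,
                        genotype=genotype,
                        depth=depth,
                        ref_depth=ref_depth,
                        alt_depth=alt_depth,
                        filter_status=filter_status,
                        depth_source=depth_source,
                    )
                )
    return records
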