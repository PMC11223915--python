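"""Coverage-aware, relatedness-deduplicated allele frequencies.

AF = AC / AN. The allele number counts two alleles per eligible individual
whose panel regions cover the variant position; eligibility keeps exactly
one representative per relatedness cluster. AN depends only on coverage and
eligibility, never on carrier status.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .sample_qc import SampleProfile

#: Diploid allele number is used on every chromosome; rows on the sex
#: chromosomes carry a limitation flag instead of haploid handling.
SEX_CHROMS = {"X", "Y", "chrX", "chrY"}


@dataclass(frozen=True)
class StratifiedAF:
    variant_key: str
    stratum: tuple[tuple[str, str], ...]  # ((field, value), ...), () = overall
    ac: int
    an: int
    flags: tuple[str, ...] = ()

    @property
    def af(self) -> float | None:
        if self.an == 0:
            return None
        return self.ac / self.an

    @property
    def stratum_label(self) -> str:
        if not self.stratum:
            return "all"
        return ";".join(f"{k}={v}" for k, v in self.stratum)


def select_representatives(
    clusters: Sequence[frozenset[str]], profiles: Mapping[str, SampleProfile]
) -> set[str]:
    """One AF-eligible sample per relatedness cluster.

    The representative is the member with the widest panel (total bp),
    ties broken by earliest submission, then by id — deterministic.
    """
    chosen: set[str] = set()
    for cluster in clusters:
        rep = min(
            cluster,
            key=lambda sid: (
                -profiles[sid].panel.total_bp,
                profiles[sid].submission_index,
                sid,
            ),
        )
        chosen.add(rep)
    return chosen


def _site_of(variant_key: str) -> tuple[str, int]:
    chrom, pos, _ref, _alt = variant_key.split(":")
    return chrom, int(pos)


def allele_number(
    variant_key: str,
    profiles: Mapping[str, SampleProfile],
    eligible: Iterable[str],
) -> int:
    """AN = 2 x eligible individuals whose panel covers the position."""
    chrom, pos = _site_of(variant_key)
    return 2 * sum(1 for sid in eligible if profiles[sid].panel.contains(chrom, pos))


def allele_count(
    variant_key: str,
    profiles: Mapping[str, SampleProfile],
    eligible: Iterable[str],
) -> int:
    """Sum of alternate-allele dosages over eligible carriers."""
    site = _site_of(variant_key)
    total = 0
    for sid in eligible:
        p = profiles[sid]
        if variant_key in p.variant_keys:
            total += p.genotypes.get(site, 1)
    return total


def aggregate(
    variant_keys: Sequence[str],
    profiles: Mapping[str, SampleProfile],
    clusters: Sequence[frozenset[str]],
    metadata: Mapping[str, Mapping[str, str]],
    strata_fields: Sequence[str] = (),
) -> list[StratifiedAF]:
    """One AF row per (variant, stratum); the overall stratum always emitted.

    ``metadata`` maps sample id to a flat field->value mapping (sex,
    suspicion, lab, panel, platform, aligner, caller, ...). Strata are the
    observed value combinations of ``strata_fields``.
    """
    for fieldname in strata_fields:
        for sid in profiles:
            if fieldname not in metadata.get(sid, {}):
                raise KeyError(f"unknown stratum field {fieldname!r} for sample {sid}")

    eligible = sorted(select_representatives(clusters, profiles))
    strata: dict[tuple[tuple[str, str], ...], list[str]] = {(): list(eligible)}
    if strata_fields:
        for sid in eligible:
            label = tuple((f, metadata[sid][f]) for f in strata_fields)
            strata.setdefault(label, []).append(sid)

    rows: list[StratifiedAF] = []
    for key in variant_keys:
        chrom, _pos = _site_of(key)
        flags = ("sex-chromosome-diploid-AN",) if chrom in SEX_CHROMS else ()
        for label, members in sorted(strata.items()):
            rows.append(
                StratifiedAF(
                    variant_key=key,
                    stratum=label,
                    ac=allele_count(key, profiles, members),
                    an=allele_number(key, profiles, members),
                    flags=flags,
                )
            )
    return rows


def histogram(values: Sequence[float], bin_width: float) -> dict[float, int]:
    """Simple fixed-width binned counts (depth: 10x bins, AB: 0.05 bins)."""
    counts: dict[float, int] = {}
    for value in values:
        left = int(value / bin_width) * bin_width
        left = round(left, 10)
        counts[left] = counts.get(left, 0) + 1
    return dict(sorted(counts.items()))


def write_af_table(rows: Sequence[StratifiedAF], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["variant", "stratum", "AC", "AN", "AF", "flags"])
        for row in rows:
            af = "" if row.af is None else f"{row.af:.6g}"
            writer.writerow(
                [row.variant_key, row.stratum_label, row.ac, row.an, af, ",".join(row.flags)]
            )


def write_sites_vcf(rows: Sequence[StratifiedAF], path: str | Path) -> None:
    """Sites-only VCF with gnomAD-style AC/AN/AF INFO tags per stratum."""
    by_variant: dict[str, list[StratifiedAF]] = {}
    for row in rows:
        by_variant.setdefault(row.variant_key, []).append(row)

    def tag(row: StratifiedAF) -> str:
        if not row.stratum:
            return ""
        return "_" + "_".join(v for _f, v in row.stratum)

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        seen_tags: list[str] = []
        for variant_rows in by_variant.values():
            for row in variant_rows:
                t = tag(row)
                if t not in seen_tags:
                    seen_tags.append(t)
        for t in seen_tags:
            fh.write(f'##INFO=<ID=AC{t},Number=1,Type=Integer,Description="Allele count">\n')
            fh.write(f'##INFO=<ID=AN{t},Number=1,Type=Integer,Description="Allele number">\n')
            fh.write(f'##INFO=<ID=AF{t},Number=1,Type=Float,Description="Allele frequency">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for key in sorted(by_variant, key=lambda k: (_site_of(k)[0], _site_of(k)[1])):
            chrom, pos, ref, alt = key.split(":")
            info_parts: list[str] = []
            for row in by_variant[key]:
                t = tag(row)
                info_parts.append(f"AC{t}={row.ac}")
                info_parts.append(f"AN{t}={row.an}")
                if row.af is not None:
                    info_parts.append(f"AF{t}={row.af:.6g}")
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t{';'.join(info_parts)}\n")
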