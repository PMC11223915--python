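"""Variant representation, reference-based normalization and transcript mapping.

Coordinates are 1-based inclusive (VCF convention) throughout this module.
Indels inside repeat tracts admit several equivalent placements; the genomic
canonical identity uses the most-5' (left-shifted) placement, while coding-DNA
reporting uses the most-3' (right-shifted) placement, both anchored VCF-style
with one base of shared context.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import (
    NoCandidateTranscriptError,
    NonVariantError,
    OutsideTranscriptError,
    ReferenceMismatchError,
    UnknownConsequenceError,
    VarShareError,
)

_ALLELE_RE = re.compile(r"^[ACGTNRYSWKMBDHV]+$")


@dataclass(frozen=True, order=True)
class GenomicVariant:
    """A single biallelic variant in VCF-style coordinates.

    ``pos`` is the 1-based position of the first base of ``ref``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref", self.ref.upper())
        object.__setattr__(self, "alt", self.alt.upper())
        if self.pos < 1:
            raise VarShareError(f"position must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not _ALLELE_RE.match(allele):
                raise VarShareError(f"invalid {name} allele {allele!r}")

    @property
    def end(self) -> int:
        """1-based inclusive position of the last reference base."""
        return self.pos + len(self.ref) - 1

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 == len(self.alt)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


@dataclass(frozen=True)
class NormalizedVariant:
    """Left (most-5') and right (most-3') placements of the same edit."""

    left: GenomicVariant
    right: GenomicVariant

    @property
    def key(self) -> str:
        """Canonical identity string, built from the left-shifted form."""
        return self.left.key


def trim_alleles(v: GenomicVariant) -> GenomicVariant:
    """Reduce ``v`` to its minimal VCF representation.

    Shared suffix bases are removed first, then shared prefix bases (the
    position advances by the prefix length). One anchor base of shared
    context is retained whenever an allele would otherwise become empty.
    """
    ref, alt, pos = v.ref, v.alt, v.pos
    if ref == alt:
        raise NonVariantError(f"{v.key}: ref equals alt")
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if ref == alt:
        raise NonVariantError(f"{v.key}: non-variant after trimming")
    return GenomicVariant(v.chrom, pos, ref, alt)


def _check_reference(v: GenomicVariant, seq: str) -> None:
    lo, hi = v.pos - 1, v.pos - 1 + len(v.ref)
    if lo < 0 or hi > len(seq):
        raise ReferenceMismatchError(f"{v.key}: outside reference bounds")
    observed = seq[lo:hi].upper()
    if observed != v.ref:
        raise ReferenceMismatchError(
            f"{v.key}: reference has {observed!r} at {v.pos}, variant claims {v.ref!r}"
        )


def _pure_edit(v: GenomicVariant) -> tuple[int, str, str]:
    """Strip all shared context, returning (start, deleted, inserted).

    ``start`` is the 1-based position of the first affected base (for a pure
    insertion, of the base the insertion precedes). Exactly one of the two
    returned strings is empty for a pure indel; both are non-empty for
    MNV/complex substitutions.
    """
    ref, alt = v.ref, v.alt
    npfx = 0
    while npfx < min(len(ref), len(alt)) and ref[npfx] == alt[npfx]:
        npfx += 1
    ref, alt = ref[npfx:], alt[npfx:]
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    return v.pos + npfx, ref, alt


def _anchored(chrom: str, start: int, deleted: str, inserted: str, seq: str) -> GenomicVariant:
    """Rebuild a VCF-style anchored variant from a pure edit."""
    if deleted and inserted:
        return GenomicVariant(chrom, start, deleted, inserted)
    if start > 1:
        anchor = seq[start - 2].upper()
        return GenomicVariant(chrom, start - 1, anchor + deleted, anchor + inserted)
    # Edit at the very first base: anchor on the following base instead.
    follow = seq[len(deleted)].upper()
    return GenomicVariant(chrom, 1, deleted + follow, inserted + follow)


def _shift(v: GenomicVariant, seq: str, direction: int) -> GenomicVariant:
    """Shared engine for left (-1) and right (+1) shifting."""
    v = trim_alleles(v)
    _check_reference(v, seq)
    if not v.is_indel:
        return v
    start, deleted, inserted = _pure_edit(v)
    if deleted and inserted:  # complex substitution: no repeat ambiguity
        return v
    s = seq.upper()
    if deleted:
        i = start - 1  # 0-based index of deleted block
        size = len(deleted)
        if direction < 0:
            while i > 0 and s[i - 1] == s[i + size - 1]:
                i -= 1
        else:
            while i + size < len(s) and s[i] == s[i + size]:
                i += 1
        return _anchored(v.chrom, i + 1, s[i : i + size], "", s)
    # pure insertion before 0-based index q
    q = start - 1
    ins = inserted
    if direction < 0:
        while q > 0 and ins[-1] == s[q - 1]:
            ins = s[q - 1] + ins[:-1]
            q -= 1
    else:
        while q < len(s) and ins[0] == s[q]:
            ins = ins[1:] + s[q]
            q += 1
    return _anchored(v.chrom, q + 1, "", ins, s)


def shift_left(v: GenomicVariant, reference: str) -> GenomicVariant:
    """Return the most-5' equivalent representation of ``v``.

    SNVs are returned unchanged (after trimming). Idempotent.
    """
    return _shift(v, reference, -1)


def shift_right(v: GenomicVariant, reference: str) -> GenomicVariant:
    """Return the most-3' equivalent representation of ``v``."""
    return _shift(v, reference, +1)


def normalize(v: GenomicVariant, reference: str) -> NormalizedVariant:
    """Compute both shifted placements and the canonical identity."""
    return NormalizedVariant(left=shift_left(v, reference), right=shift_right(v, reference))


def apply_variant(seq: str, v: GenomicVariant) -> str:
    """Apply ``v`` to a reference sequence, returning the edited sequence.

    Used as the ground-truth equivalence check between placements.
    """
    _check_reference(v, seq)
    lo = v.pos - 1
    return seq[:lo] + v.alt + seq[lo + len(v.ref) :]


def decompose_multiallelic(
    chrom: str, pos: int, ref: str, alts: Sequence[str]
) -> list[GenomicVariant]:
    """Split a multi-allelic VCF record into biallelic variants."""
    return [GenomicVariant(chrom, pos, ref, alt) for alt in alts if alt not in ("*", ".")]


# ---------------------------------------------------------------------------
# Transcript coordinate mapping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TranscriptModel:
    """Minimal exon/CDS model of one transcript.

    ``exons`` are 1-based inclusive genomic intervals sorted ascending
    regardless of strand; ``cds_start``/``cds_end`` are genomic bounds
    (cds_start <= cds_end).
    """

    id: str
    gene: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    is_lrg_first: bool = False
    is_canonical: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise VarShareError(f"bad strand {self.strand!r}")
        prev_end = 0
        for start, end in self.exons:
            if start > end or start <= prev_end:
                raise VarShareError(f"{self.id}: exons must be sorted, non-overlapping")
            prev_end = end
        span = (self.exons[0][0], self.exons[-1][1])
        if not (span[0] <= self.cds_start <= self.cds_end <= span[1]):
            raise VarShareError(f"{self.id}: CDS bounds outside exon span")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class CdnaPosition:
    """Coding-DNA coordinate: coding base index plus signed intronic offset.

    ``coding_pos`` counts transcript bases from the CDS start (1-based);
    positions 5' of the CDS start come out non-positive. ``offset`` is zero
    for exonic positions, positive downstream of a donor site and negative
    upstream of an acceptor site (transcript orientation).
    """

    coding_pos: int
    offset: int = 0


def _exonic_positions(t: TranscriptModel) -> list[int]:
    """Genomic positions of transcript bases in transcript order."""
    positions = [p for start, end in t.exons for p in range(start, end + 1)]
    if t.strand == "-":
        positions.reverse()
    return positions


def map_to_cdna(v: GenomicVariant, t: TranscriptModel) -> CdnaPosition:
    """Map the anchor position of ``v`` into coding-DNA coordinates.

    The caller is expected to right-normalize ``v`` with respect to the
    transcript direction beforehand; this function maps ``v.pos`` only.
    """
    g = v.pos
    lo, hi = t.span
    if not (lo <= g <= hi):
        raise OutsideTranscriptError(f"{v.key} outside transcript {t.id} span {lo}-{hi}")

    order = _exonic_positions(t)
    index_of = {p: i for i, p in enumerate(order)}  # transcript index, 0-based
    cds_anchor = t.cds_start if t.strand == "+" else t.cds_end
    cds_index = index_of[cds_anchor]

    def coding(i: int) -> int:
        c = i - cds_index
        return c + 1 if c >= 0 else c  # no coding position 0

    if g in index_of:
        return CdnaPosition(coding(index_of[g]))

    # Intronic: locate flanking exons in genomic order.
    for (s1, e1), (s2, _e2) in zip(t.exons, t.exons[1:]):
        if e1 < g < s2:
            d_prev = g - e1  # distance to the genomically-left exon edge
            d_next = s2 - g
            if t.strand == "+":
                if d_prev <= d_next:
                    return CdnaPosition(coding(index_of[e1]), +d_prev)
                return CdnaPosition(coding(index_of[s2]), -d_next)
            if d_next <= d_prev:
                return CdnaPosition(coding(index_of[s2]), +d_next)
            return CdnaPosition(coding(index_of[e1]), -d_prev)
    raise OutsideTranscriptError(f"{v.key}: position {g} not locatable in {t.id}")


# ---------------------------------------------------------------------------
# Main transcript selection
# ---------------------------------------------------------------------------

#: Default severity ordering, most severe first (subset of the usual
#: annotator ordering, sufficient for panel data; configurable).
DEFAULT_CONSEQUENCE_RANKING: tuple[str, ...] = (
    "transcript_ablation",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "stop_gained",
    "frameshift_variant",
    "stop_lost",
    "start_lost",
    "inframe_insertion",
    "inframe_deletion",
    "missense_variant",
    "protein_altering_variant",
    "splice_region_variant",
    "synonymous_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "intron_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "intergenic_variant",
)


@dataclass(frozen=True)
class ConsequenceRanking:
    """Total order over consequence terms, most severe first."""

    terms: tuple[str, ...] = field(default=DEFAULT_CONSEQUENCE_RANKING)

    def __post_init__(self) -> None:
        if len(set(self.terms)) != len(self.terms):
            raise VarShareError("duplicate terms in consequence ranking")

    def rank(self, term: str) -> int:
        try:
            return self.terms.index(term)
        except ValueError:
            raise UnknownConsequenceError(f"consequence {term!r} not in ranking") from None


@dataclass(frozen=True)
class TranscriptAnnotation:
    """One candidate (transcript, consequence) pair for a variant."""

    transcript: TranscriptModel
    consequence: str


def _gene_candidate(candidates: Sequence[TranscriptAnnotation]) -> TranscriptAnnotation:
    lrg = [c for c in candidates if c.transcript.is_lrg_first]
    if lrg:
        return min(lrg, key=lambda c: c.transcript.id)
    canonical = [c for c in candidates if c.transcript.is_canonical]
    if canonical:
        return min(canonical, key=lambda c: c.transcript.id)
    raise NoCandidateTranscriptError(
        f"gene {candidates[0].transcript.gene!r}: no LRG-first or canonical transcript"
    )


def select_main_transcript(
    annotations: Iterable[TranscriptAnnotation],
    ranking: ConsequenceRanking | None = None,
) -> str:
    """Pick the single transcript used for default display.

    Per gene: the first-LRG transcript if flagged, else the canonical one.
    Across genes: the per-gene candidate whose consequence is most severe,
    ties broken by transcript id (first lexicographically).
    """
    ranking = ranking or ConsequenceRanking()
    by_gene: dict[str, list[TranscriptAnnotation]] = {}
    for ann in annotations:
        by_gene.setdefault(ann.transcript.gene, []).append(ann)
    if not by_gene:
        raise NoCandidateTranscriptError("no candidate transcripts")
    chosen = [_gene_candidate(cands) for cands in by_gene.values()]
    return min(chosen, key=lambda c: (ranking.rank(c.consequence), c.transcript.id)).transcript.id


# ---------------------------------------------------------------------------
# Reference and transcript I/O
# ---------------------------------------------------------------------------


class ReferenceGenome:
    """Chromosome-name-keyed access to reference sequences."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {name: str(seq).upper() for name, seq in sequences.items()}

    @classmethod
    def from_fasta(cls, path: str) -> "ReferenceGenome":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def keys(self):
        return self._seqs.keys()


def read_transcripts(path: str) -> list[TranscriptModel]:
    """Load transcript models from a tab-delimited file.

    Columns: id, gene, strand, exons (comma-separated start-end pairs),
    cds_start, cds_end, lrg_first (0/1), canonical (0/1).
    """
    out: list[TranscriptModel] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tid, gene, strand, exons_s, cs, ce, lrg, canon = line.split("\t")
            exons = tuple(
                (int(a), int(b)) for a, b in (pair.split("-") for pair in exons_s.split(","))
            )
            out.append(
                TranscriptModel(
                    id=tid,
                    gene=gene,
                    strand=strand,
                    exons=exons,
                    cds_start=int(cs),
                    cds_end=int(ce),
                    is_lrg_first=lrg == "1",
                    is_canonical=canon == "1",
                )
            )
    return out
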