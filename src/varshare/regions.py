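"""Panel region sets (BED convention: 0-based half-open intervals on disk).

Internally intervals stay 0-based half-open; membership queries take 1-based
positions so the rest of the package never converts coordinates itself.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Iterator


def _merge(intervals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if start >= end:
            continue
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return tuple(merged)


@dataclass(frozen=True)
class PanelRegions:
    """Merged, sorted genomic interval set for one panel."""

    intervals: dict[str, tuple[tuple[int, int], ...]] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, raw: Iterable[tuple[str, int, int]]) -> "PanelRegions":
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in raw:
            per_chrom.setdefault(chrom, []).append((int(start), int(end)))
        return cls({c: _merge(iv) for c, iv in per_chrom.items() if _merge(iv)})

    @classmethod
    def from_bed(cls, path: str) -> "PanelRegions":
        rows: list[tuple[str, int, int]] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                rows.append((fields[0], int(fields[1]), int(fields[2])))
        return cls.from_intervals(rows)

    def to_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.intervals):
                for start, end in self.intervals[chrom]:
                    fh.write(f"{chrom}\t{start}\t{end}\n")

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position."""
        ivs = self.intervals.get(chrom)
        if not ivs:
            return False
        zero = pos - 1
        idx = bisect_right(ivs, (zero, float("inf"))) - 1
        return idx >= 0 and ivs[idx][0] <= zero < ivs[idx][1]

    def intersect(self, other: "PanelRegions") -> "PanelRegions":
        out: dict[str, tuple[tuple[int, int], ...]] = {}
        for chrom in self.intervals.keys() & other.intervals.keys():
            a, b = self.intervals[chrom], other.intervals[chrom]
            i = j = 0
            acc: list[tuple[int, int]] = []
            while i < len(a) and j < len(b):
                lo = max(a[i][0], b[j][0])
                hi = min(a[i][1], b[j][1])
                if lo < hi:
                    acc.append((lo, hi))
                if a[i][1] < b[j][1]:
                    i += 1
                else:
                    j += 1
            if acc:
                out[chrom] = tuple(acc)
        return PanelRegions(out)

    @property
    def total_bp(self) -> int:
        return sum(end - start for ivs in self.intervals.values() for start, end in ivs)

    @property
    def is_empty(self) -> bool:
        return self.total_bp == 0

    def iter_positions(self) -> Iterator[tuple[str, int]]:
        """Yield every covered (chrom, 1-based position). Small panels only."""
        for chrom in sorted(self.intervals):
            for start, end in self.intervals[chrom]:
                for zero in range(start, end):
                    yield chrom, zero + 1
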