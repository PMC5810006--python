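"""Core domain types shared by every pipeline stage.

Coordinate conventions: SNP/variant positions are 1-based (``chr7:91708964``
style); :class:`RegionSet` intervals are 0-based half-open, matching BED.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

CONSEQUENCES = ("synonymous", "nonsynonymous", "nonsense", "other")
COMPARTMENTS = ("primary", "metastasis", "axillary", "germline")

#: Lesion labels in temporal order, as used by mutation tables and trajectories.
LESION_ORDER = ("primary", "axillary", "metastasis_1", "metastasis_2")


class FormatError(ValueError):
    """A tabular input violated its dialect (missing column, bad value...)."""


@dataclass(frozen=True)
class SnpObservation:
    """Ref/alt read counts for one sample at one genomic position."""

    chrom: str
    pos: int
    ref_count: int
    alt_count: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError(
                f"negative read count at {self.chrom}:{self.pos} "
                f"({self.ref_count}/{self.alt_count})"
            )
        if self.pos < 1:
            raise ValueError(f"position must be 1-based positive, got {self.pos}")

    @property
    def coverage(self) -> int:
        return self.ref_count + self.alt_count


@dataclass(frozen=True)
class VariantRecord:
    """A candidate somatic variant with paired germline/tumor read support."""

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    germline_ref: int
    germline_alt: int
    tumor_ref: int
    tumor_alt: int
    tumor_alt_fwd: Optional[int] = None
    tumor_alt_rev: Optional[int] = None
    gene: str = ""
    consequence: str = "other"
    sample_id: str = ""
    compartment: str = "primary"

    def __post_init__(self) -> None:
        for name in ("germline_ref", "germline_alt", "tumor_ref", "tumor_alt"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative {name} at {self.chrom}:{self.pos}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.strand_evaluable and self.tumor_alt_fwd + self.tumor_alt_rev != self.tumor_alt:
            raise ValueError(
                f"strand counts {self.tumor_alt_fwd}+{self.tumor_alt_rev} "
                f"!= tumor_alt {self.tumor_alt} at {self.chrom}:{self.pos}"
            )

    @property
    def strand_evaluable(self) -> bool:
        return self.tumor_alt_fwd is not None and self.tumor_alt_rev is not None

    @property
    def tumor_coverage(self) -> int:
        return self.tumor_ref + self.tumor_alt

    @property
    def germline_coverage(self) -> int:
        return self.germline_ref + self.germline_alt

    @property
    def tumor_vaf(self) -> Optional[float]:
        cov = self.tumor_coverage
        return self.tumor_alt / cov if cov > 0 else None

    @property
    def germline_vaf(self) -> Optional[float]:
        cov = self.germline_coverage
        return self.germline_alt / cov if cov > 0 else None

    @property
    def key(self) -> tuple:
        """Substitution identity used to match positions across lesions."""
        return (self.chrom, self.pos, self.ref_base, self.alt_base)


@dataclass(frozen=True)
class MutationTableRow:
    """One printed-mutation-table row: a mutation with per-lesion VAFs.

    ``vafs`` maps a lesion label from :data:`LESION_ORDER` to the list of
    VAF fractions reported for that lesion (several tissue blocks of one
    sample may each carry a VAF). A lesion absent from the mapping was not
    assayed / not reported; a present lesion with VAF 0.0 was assayed and
    negative.
    """

    gene: str
    patient_id: str
    vafs: tuple  # tuple of (lesion_label, tuple_of_fractions)
    substitution: str = ""
    consequence: str = "nonsynonymous"
    chrom: str = ""
    pos: int = 0

    def __post_init__(self) -> None:
        for lesion, values in self.vafs:
            if lesion not in LESION_ORDER:
                raise ValueError(f"unknown lesion label {lesion!r}")
            for v in values:
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"VAF {v} outside [0, 1] for {self.gene}")

    def vaf(self, lesion: str) -> Optional[float]:
        """Representative VAF for a lesion: max over blocks, None if missing."""
        for label, values in self.vafs:
            if label == lesion:
                return max(values) if values else None
        return None

    def vaf_list(self, lesion: str) -> Optional[tuple]:
        for label, values in self.vafs:
            if label == lesion:
                return values
        return None


class RegionSet:
    """Sorted 0-based half-open genomic intervals with optional labels."""

    def __init__(self, intervals: Iterable[tuple]) -> None:
        rows = []
        for iv in intervals:
            if len(iv) == 3:
                chrom, start, end = iv
                label = ""
            else:
                chrom, start, end, label = iv
            start, end = int(start), int(end)
            if start >= end:
                raise ValueError(f"empty/inverted interval {chrom}:{start}-{end}")
            rows.append((str(chrom), start, end, str(label)))
        rows.sort(key=lambda r: (r[0], r[1], r[2]))
        self._rows = rows
        self._starts = {}
        for chrom in {r[0] for r in rows}:
            self._starts[chrom] = [r[1] for r in rows if r[0] == chrom]

    def __iter__(self) -> Iterator[tuple]:
        return iter(self._rows)

    def __len__(self) -> int:
        return len(self._rows)

    def __eq__(self, other) -> bool:
        return isinstance(other, RegionSet) and self._rows == other._rows

    def __repr__(self) -> str:
        return f"RegionSet({len(self._rows)} intervals)"

    def contains(self, chrom: str, pos: int) -> bool:
        """True if 1-based position ``pos`` falls in any interval."""
        point = pos - 1
        for c, start, end, _ in self._rows:
            if c == chrom and start <= point < end:
                return True
        return False

    def label_at(self, chrom: str, pos: int) -> Optional[str]:
        point = pos - 1
        for c, start, end, label in self._rows:
            if c == chrom and start <= point < end:
                return label
        return None

    def overlapping(self, chrom: str, start: int, end: int) -> list:
        """Intervals overlapping [start, end) on ``chrom`` (0-based)."""
        return [
            r for r in self._rows
            if r[0] == chrom and r[1] < end and start < r[2]
        ]

    def has_self_overlap(self) -> bool:
        by_chrom: dict = {}
        for c, s, e, _ in self._rows:
            by_chrom.setdefault(c, []).append((s, e))
        for ivs in by_chrom.values():
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    return True
        return False

    @classmethod
    def from_bed(cls, path) -> "RegionSet":
        rows = []
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise FormatError(f"{path}:{i}: BED line needs >= 3 columns")
                label = parts[3] if len(parts) > 3 else ""
                rows.append((parts[0], int(parts[1]), int(parts[2]), label))
        return cls(rows)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end, label in self._rows:
                cols = [chrom, str(start), str(end)]
                if label:
                    cols.append(label)
                fh.write("\t".join(cols) + "\n")
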