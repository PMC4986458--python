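"""Readers, writers and shared genomic primitives.

All internal coordinates are 1-based and closed, matching the convention used
for physical positions in linkage-map tables.  BED input (0-based, half-open)
is converted at the boundary and converted back on write.

Pileup decoding follows the samtools mpileup text dialect: ``.``/``,`` are the
reference base, ``ACGTacgt`` are explicit calls, ``^X`` (read start + mapping
quality), ``$`` (read end), ``*``/``#`` (deletion placeholders), ``>``/``<``
(reference skips) and ``+n``/``-n`` indel events are consumed without
contributing to base counts.  Depth is defined as the sum of the four decoded
A/C/G/T counts; ambiguity codes (N) are dropped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Sequence

import numpy as np

BASES = ("A", "C", "G", "T")
MISSING_CHAR = "?"

_INDEL_RE = re.compile(r"[+-](\d+)")
_CARET_RE = re.compile(r"\^.")


@dataclass(frozen=True, order=True)
class GenomeCoordinate:
    """A 1-based reference position."""

    chromosome: str
    position: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")


@dataclass
class PileupColumn:
    """Per-site, per-sample A/C/G/T counts at one reference coordinate."""

    coordinate: GenomeCoordinate
    reference_base: str
    per_sample_counts: dict[str, dict[str, int]]

    def depth(self, sample: str) -> int:
        return sum(self.per_sample_counts[sample].values())


@dataclass
class TargetRegion:
    """A capture-probe target interval with its central targeted site."""

    chromosome: str
    start: int          # 1-based closed
    end: int
    central_site: GenomeCoordinate = None  # type: ignore[assignment]
    is_targeted: bool = True

    def __post_init__(self) -> None:
        if self.central_site is None:
            mid = (self.start + self.end) // 2
            self.central_site = GenomeCoordinate(self.chromosome, mid)
        if not (self.start <= self.central_site.position <= self.end):
            raise ValueError(
                f"central site {self.central_site.position} outside "
                f"[{self.start}, {self.end}]"
            )


class PileupParseError(ValueError):
    pass


def decode_base_column(bases: str, reference_base: str) -> dict[str, int]:
    """Decode one mpileup base-call string into A/C/G/T counts.

    Read-start (``^X``), read-end (``$``), deletion/skip placeholders and
    indel events are consumed; indel sequences do not contribute counts, but
    the anchoring base call of an indel-containing read is kept.
    """
    s = bases
    if "^" in s:
        s = _CARET_RE.sub("", s)
    if "+" in s or "-" in s:
        out: list[str] = []
        i, n = 0, len(s)
        while i < n:
            c = s[i]
            if c in "+-":
                m = _INDEL_RE.match(s, i)
                if not m:
                    raise PileupParseError(f"malformed indel in column {bases!r}")
                i = m.end() + int(m.group(1))
            else:
                out.append(c)
                i += 1
        s = "".join(out)
    ref = reference_base.upper()
    counts = dict.fromkeys(BASES, 0)
    n_ref = s.count(".") + s.count(",")
    if ref in counts:
        counts[ref] += n_ref
    for b in BASES:
        counts[b] += s.count(b) + s.count(b.lower())
    return counts


def read_pileup(
    stream: IO[str] | Iterable[str], sample_names: Sequence[str]
) -> Iterator[PileupColumn]:
    """Parse multi-sample mpileup text into :class:`PileupColumn` records.

    Expects one ``depth  bases  quals`` column block per sample.  Raises
    :class:`PileupParseError` naming the offending line on malformed input.
    """
    n = len(sample_names)
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 3 + 3 * n:
            raise PileupParseError(
                f"line {lineno}: expected {3 + 3 * n} columns for "
                f"{n} samples, got {len(fields)}"
            )
        chrom, pos_s, ref = fields[0], fields[1], fields[2]
        try:
            pos = int(pos_s)
        except ValueError as exc:
            raise PileupParseError(f"line {lineno}: bad position {pos_s!r}") from exc
        per_sample: dict[str, dict[str, int]] = {}
        for k, sample in enumerate(sample_names):
            bases = fields[4 + 3 * k]
            per_sample[sample] = decode_base_column(bases, ref)
        yield PileupColumn(GenomeCoordinate(chrom, pos), ref.upper(), per_sample)


def read_target_bed(stream: IO[str] | Iterable[str]) -> list[TargetRegion]:
    """Read BED3/BED4 target intervals (0-based half-open) into 1-based
    closed :class:`TargetRegion` records.  An optional 4th column gives the
    0-based central targeted site; otherwise the interval midpoint is used."""
    regions: list[TargetRegion] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise ValueError(f"line {lineno}: BED record needs >= 3 fields")
        chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
        if end0 <= start0:
            raise ValueError(f"line {lineno}: empty/negative interval {start0}-{end0}")
        start1, end1 = start0 + 1, end0
        if len(fields) >= 4 and fields[3].isdigit():
            central = GenomeCoordinate(chrom, int(fields[3]) + 1)
        else:
            central = GenomeCoordinate(chrom, (start1 + end1) // 2)
        regions.append(TargetRegion(chrom, start1, end1, central))
    return regions


def write_target_bed(regions: Iterable[TargetRegion], stream: IO[str]) -> None:
    for r in regions:
        stream.write(
            f"{r.chromosome}\t{r.start - 1}\t{r.end}\t{r.central_site.position - 1}\n"
        )


@dataclass
class TaxonMatrix:
    """An aligned site × taxon character matrix with missing data.

    Rows are taxa (linkage groups, diploid reference taxa, outgroups); columns
    are reference coordinates.  Cells hold a single nucleotide or ``?``.
    """

    taxa: list[str]
    sites: list[GenomeCoordinate]
    cells: np.ndarray = field(repr=False)  # dtype '<U1', shape (n_taxa, n_sites)

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype="<U1")
        if self.cells.shape != (len(self.taxa), len(self.sites)):
            raise ValueError("cells shape does not match taxa x sites")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cells.shape

    def row(self, taxon: str) -> np.ndarray:
        return self.cells[self.taxa.index(taxon)]

    def drop_empty_sites(self) -> "TaxonMatrix":
        keep = (self.cells != MISSING_CHAR).any(axis=0)
        return TaxonMatrix(
            list(self.taxa),
            [s for s, k in zip(self.sites, keep) if k],
            self.cells[:, keep],
        )

    def missing_fraction(self) -> float:
        if self.cells.size == 0:
            return 0.0
        return float((self.cells == MISSING_CHAR).mean())


def write_phylip_matrix(matrix: TaxonMatrix, path) -> None:
    """Write a relaxed-PHYLIP alignment; missing cells become ``?``."""
    if len(matrix.taxa) == 0 or len(matrix.sites) == 0:
        raise ValueError("cannot write an empty matrix")
    if len(set(matrix.taxa)) != len(matrix.taxa):
        raise ValueError("duplicate taxon names")
    width = max(len(t) for t in matrix.taxa) + 2
    with open(path, "w") as fh:
        fh.write(f"{len(matrix.taxa)} {len(matrix.sites)}\n")
        for taxon, row in zip(matrix.taxa, matrix.cells):
            fh.write(taxon.ljust(width) + "".join(row) + "\n")


def read_phylip_matrix(path, sites: Sequence[GenomeCoordinate] | None = None) -> TaxonMatrix:
    """Read a relaxed-PHYLIP alignment written by :func:`write_phylip_matrix`.

    Site coordinates are not stored in PHYLIP; callers may supply them, else
    placeholder 1..n coordinates on chromosome ``.`` are used.
    """
    with open(path) as fh:
        header = fh.readline().split()
        n_taxa, n_sites = int(header[0]), int(header[1])
        taxa, rows = [], []
        for _ in range(n_taxa):
            name, seq = fh.readline().split(None, 1)
            taxa.append(name)
            rows.append(list(seq.strip()))
    if sites is None:
        sites = [GenomeCoordinate(".", i + 1) for i in range(n_sites)]
    return TaxonMatrix(taxa, list(sites), np.array(rows, dtype="<U1"))


def format_pileup_column(
    coordinate: GenomeCoordinate,
    reference_base: str,
    counts_per_sample: Sequence[dict[str, int]],
) -> str:
    """Render one mpileup text line from per-sample A/C/G/T counts
    (inverse of :func:`read_pileup` up to the order of base characters)."""
    ref = reference_base.upper()
    cols = [coordinate.chromosome, str(coordinate.position), ref]
    for counts in counts_per_sample:
        depth = sum(counts.values())
        parts = []
        for b in BASES:
            c = counts.get(b, 0)
            parts.append(("." if b == ref else b) * c)
        bases = "".join(parts) or "*"
        cols.extend([str(depth), bases, "~" * max(depth, 1)])
    return "\t".join(cols)
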