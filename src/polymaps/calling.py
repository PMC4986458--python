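"""Genotype calling for the octoploid F1 cross and the diploid cross.

The octoploid caller is threshold-based.  A variant heterozygous at a single
homeolog occurs at roughly one-eighth read frequency, so a sample is coded

* HET      -- rare variant seen at least twice and at >= 2.5% frequency,
* HOM      -- no rare variant, or a single copy at < 1.25% frequency
              (treated as a potential sequencing error),
* MISSING  -- depth below 32x, or any pattern between the two rules.

Frequency comparisons use exact integer cross-multiplication so the 2.5% and
1.25% boundaries behave identically at every depth.

Sites retained as linkage-map markers (LG SNPs) must be heterozygous in
exactly one parent, show both genotype classes in at least eight progeny
each (the Mendelian 1:1 screen), and be missing in at most one progeny.
Sites heterozygous in both parents are routed to a separate biparental set,
used only to pair corresponding maternal/paternal linkage groups.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .formats_io import BASES, GenomeCoordinate

MIN_DEPTH = 32
HET_MIN_COUNT = 2
HET_MIN_FREQ_NUM, HET_MIN_FREQ_DEN = 25, 1000      # 2.5%
HOM_MAX_FREQ_NUM, HOM_MAX_FREQ_DEN = 125, 10000    # 1.25%


class GenotypeState(enum.Enum):
    HOM = "hom"
    HET = "het"
    MISSING = "missing"


@dataclass(frozen=True)
class GenotypeCall:
    state: GenotypeState
    minor_allele: str | None = None
    minor_count: int = 0
    depth: int = 0

    def __post_init__(self) -> None:
        if self.state is GenotypeState.HET and self.minor_count < HET_MIN_COUNT:
            raise ValueError("HET call requires minor_count >= 2")


MISSING_CALL = GenotypeCall(GenotypeState.MISSING)


def call_octoploid_genotype(
    counts: Mapping[str, int], min_depth: int = MIN_DEPTH
) -> GenotypeCall:
    """Apply the octoploid HET/HOM/MISSING thresholds to A/C/G/T counts.

    A tie between two non-major bases (no unique rare variant) is coded
    MISSING: the rules assume a biallelic rare variant.
    """
    acgt = [(counts.get(b, 0), b) for b in BASES]
    depth = sum(c for c, _ in acgt)
    if depth < min_depth:
        return MISSING_CALL
    acgt.sort(key=lambda cb: (-cb[0], cb[1]))
    major_count, major = acgt[0]
    minor_count, minor = acgt[1]
    if minor_count == 0:
        return GenotypeCall(GenotypeState.HOM, major, 0, depth)
    if acgt[2][0] == minor_count:
        return MISSING_CALL  # ambiguous minor allele
    # HET: count >= 2 and freq >= 2.5%
    if minor_count >= HET_MIN_COUNT and (
        minor_count * HET_MIN_FREQ_DEN >= depth * HET_MIN_FREQ_NUM
    ):
        return GenotypeCall(GenotypeState.HET, minor, minor_count, depth)
    # HOM: single copy at < 1.25%
    if minor_count == 1 and (minor_count * HOM_MAX_FREQ_DEN < depth * HOM_MAX_FREQ_NUM):
        return GenotypeCall(GenotypeState.HOM, major, minor_count, depth)
    return MISSING_CALL


class ParentOfOrigin(enum.Enum):
    MATERNAL = "maternal"
    PATERNAL = "paternal"
    BOTH = "both"


@dataclass
class LGSNP:
    """A single-subgenome heterozygous marker with its progeny segregation."""

    coordinate: GenomeCoordinate
    parent_of_origin: ParentOfOrigin
    minor_allele: str
    progeny_calls: list[GenotypeCall]
    region_id: int | None = None

    def segregation(self) -> tuple[list[int], list[bool]]:
        """Binary HET(1)/HOM(0) states plus a missing mask over progeny."""
        states, missing = [], []
        for c in self.progeny_calls:
            missing.append(c.state is GenotypeState.MISSING)
            states.append(1 if c.state is GenotypeState.HET else 0)
        return states, missing


@dataclass
class SiteSelection:
    lg_snps: list[LGSNP]
    biparental: list[LGSNP]


def select_lg_snps(
    sites: Sequence[
        tuple[GenomeCoordinate, GenotypeCall, GenotypeCall, Sequence[GenotypeCall]]
    ],
    min_per_class: int = 8,
    max_missing: int = 1,
) -> SiteSelection:
    """Filter called sites down to retained LG SNPs.

    ``sites`` holds (coordinate, maternal call, paternal call, progeny calls).
    Retention requires exactly one HET parent, >= ``min_per_class`` progeny in
    each of the HET and HOM classes, and <= ``max_missing`` missing progeny.
    Sites HET in both parents pass the same progeny screens but are returned
    in the separate biparental set.
    """
    if sites and len(sites[0][3]) < 2 * min_per_class:
        raise ValueError(
            f"{len(sites[0][3])} progeny cannot satisfy >= {min_per_class} "
            "per genotype class"
        )
    retained: list[LGSNP] = []
    biparental: list[LGSNP] = []
    for coord, mat, pat, progeny in sites:
        mat_het = mat.state is GenotypeState.HET
        pat_het = pat.state is GenotypeState.HET
        if not (mat_het or pat_het):
            continue
        if mat.state is GenotypeState.MISSING or pat.state is GenotypeState.MISSING:
            continue
        n_het = sum(1 for c in progeny if c.state is GenotypeState.HET)
        n_hom = sum(1 for c in progeny if c.state is GenotypeState.HOM)
        n_missing = sum(1 for c in progeny if c.state is GenotypeState.MISSING)
        if n_het < min_per_class or n_hom < min_per_class or n_missing > max_missing:
            continue
        if mat_het and pat_het:
            origin = ParentOfOrigin.BOTH
            minor = mat.minor_allele or pat.minor_allele
        elif mat_het:
            origin, minor = ParentOfOrigin.MATERNAL, mat.minor_allele
        else:
            origin, minor = ParentOfOrigin.PATERNAL, pat.minor_allele
        snp = LGSNP(coord, origin, minor or "N", list(progeny))
        (biparental if origin is ParentOfOrigin.BOTH else retained).append(snp)
    return SiteSelection(retained, biparental)


# ---------------------------------------------------------------------------
# Diploid likelihood-based site filter


def valid_diploid_genotype(
    depth: int,
    phred_likelihoods: Sequence[float],
    min_depth: int = 20,
    min_other_pl: float = 40.0,
) -> int | None:
    """Return the index of the called genotype, or None if invalid/missing.

    Valid requires depth >= 20, best Phred-scaled likelihood exactly 0, and
    every other genotype's PL >= 40 (likelihood ratio <= 1e-4).
    """
    if depth < min_depth or len(phred_likelihoods) == 0:
        return None
    pls = list(phred_likelihoods)
    best = min(pls)
    if best != 0:
        return None
    idx = pls.index(best)
    others = [p for i, p in enumerate(pls) if i != idx]
    if others and min(others) < min_other_pl:
        return None
    return idx


_MENDEL = {
    # parental genotype pair (unordered, 0=hom-ref,1=het,2=hom-alt)
    # -> producible offspring genotypes
    (0, 0): {0},
    (0, 1): {0, 1},
    (0, 2): {1},
    (1, 1): {0, 1, 2},
    (1, 2): {1, 2},
    (2, 2): {2},
}


def filter_diploid_site(
    parent_genotypes: tuple[int | None, int | None],
    offspring_genotypes: Sequence[int | None],
    max_missing: int = 8,
    max_same_fraction: float = 0.85,
) -> bool:
    """Site-level retention for the diploid cross.

    Requires < ``max_missing`` missing offspring, no genotype class exceeding
    ``max_same_fraction`` of non-missing offspring, informative (non-missing)
    parents, and offspring genotypes producible from the parental pair under
    Mendelian inheritance.
    """
    called = [g for g in offspring_genotypes if g is not None]
    n_missing = len(offspring_genotypes) - len(called)
    if n_missing >= max_missing or not called:
        return False
    for g in set(called):
        if called.count(g) / len(called) > max_same_fraction:
            return False
    pm, pp = parent_genotypes
    if pm is None or pp is None:
        return False
    if pm == pp and pm != 1:
        return False  # uninformative: no segregation expected
    allowed = _MENDEL[tuple(sorted((pm, pp)))]
    return set(called) <= allowed


# ---------------------------------------------------------------------------
# 1-kb region grouping


@dataclass
class MarkerRegion:
    region_id: int
    chromosome: str
    positions: list[int]
    is_targeted: bool = False

    @property
    def span(self) -> tuple[int, int]:
        return self.positions[0], self.positions[-1]


def group_regions(
    positions: Sequence[int], chromosome: str = ".", gap: int = 1000,
    start_id: int = 0,
) -> list[MarkerRegion]:
    """Chain sorted positions into regions: consecutive SNPs < ``gap`` bp
    apart share a region; a difference of >= ``gap`` starts a new one."""
    if any(b < a for a, b in zip(positions, positions[1:])):
        raise ValueError("positions must be sorted ascending")
    regions: list[MarkerRegion] = []
    current: list[int] = []
    rid = start_id
    for pos in positions:
        if current and pos - current[-1] >= gap:
            regions.append(MarkerRegion(rid, chromosome, current))
            rid += 1
            current = []
        current.append(pos)
    if current:
        regions.append(MarkerRegion(rid, chromosome, current))
    return regions
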