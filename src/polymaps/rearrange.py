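"""Interchromosomal-rearrangement detection, permutation null, depth proxies
and in-silico PCR placement of SSR primer pairs.

A rearrangement is an LG SNP whose linkage group pertains to a different
reference pseudochromosome than the SNP's own mapping position.  Clustering
of such events across targeted regions is judged against a null in which the
same number of events is dropped independently and uniformly over all
targeted regions that carry LG SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .calling import LGSNP
from .formats_io import TargetRegion


@dataclass
class RearrangementEvent:
    snp_chromosome: str
    snp_position: int
    linkage_group_id: str
    group_primary_chromosome: str
    nearest_target: TargetRegion | None
    distance_to_target: int

    def __post_init__(self) -> None:
        if self.snp_chromosome == self.group_primary_chromosome:
            raise ValueError("not a rearrangement: chromosomes match")


def detect_rearrangements(
    snps_with_groups: Iterable[tuple[LGSNP, str, str]],
    target_regions: Sequence[TargetRegion],
    max_distance: int = 1000,
) -> tuple[list[RearrangementEvent], list[RearrangementEvent]]:
    """Find LG SNPs whose reference chromosome differs from their group's
    primary chromosome.

    ``snps_with_groups`` yields (snp, group_id, group_primary_chromosome);
    events may pool several parental maps.  Returns (all events, the
    restricted set within ``max_distance`` bp of a targeted region).
    """
    by_chrom: dict[str, list[TargetRegion]] = {}
    for t in target_regions:
        by_chrom.setdefault(t.chromosome, []).append(t)
    for ts in by_chrom.values():
        ts.sort(key=lambda t: t.central_site.position)
    events: list[RearrangementEvent] = []
    for snp, group_id, primary in snps_with_groups:
        if snp.coordinate.chromosome == primary:
            continue
        nearest, dist = _nearest_region(
            by_chrom.get(snp.coordinate.chromosome, []), snp.coordinate.position
        )
        events.append(
            RearrangementEvent(
                snp.coordinate.chromosome,
                snp.coordinate.position,
                group_id,
                primary,
                nearest,
                dist,
            )
        )
    restricted = [e for e in events if e.nearest_target and e.distance_to_target <= max_distance]
    return events, restricted


def _nearest_region(
    regions: Sequence[TargetRegion], position: int
) -> tuple[TargetRegion | None, int]:
    if not regions:
        return None, -1
    best, best_d = None, None
    for t in regions:
        if t.start <= position <= t.end:
            return t, 0
        d = min(abs(position - t.start), abs(position - t.end))
        if best_d is None or d < best_d:
            best, best_d = t, d
    return best, int(best_d)


@dataclass
class PermutationResult:
    replicates: int
    seed: int
    mean_regions_multi: float
    ci_regions_multi: tuple[float, float]
    mean_co_occupancy: float
    ci_co_occupancy: tuple[float, float]


def permutation_clustering_test(
    n_events: int,
    n_regions: int,
    reps: int = 10_000,
    seed: int = 0,
    with_replacement: bool = True,
) -> PermutationResult:
    """Random-distribution null for rearrangement clustering.

    Each replicate assigns ``n_events`` events independently and uniformly to
    ``n_regions`` regions and records (a) the number of regions holding >= 2
    events and (b) the mean, over events, of co-occupants in the event's
    region.  Intervals are empirical 2.5/97.5 percentiles over replicates.
    ``with_replacement=False`` gives a without-replacement sensitivity
    variant (each replicate a distinct region per event).
    """
    if n_events < 1 or n_regions < 1:
        raise ValueError("need n_events >= 1 and n_regions >= 1")
    rng = np.random.default_rng(seed)
    multi = np.empty(reps, dtype=np.int64)
    coocc = np.empty(reps, dtype=np.float64)
    for rep in range(reps):
        if with_replacement:
            draws = rng.integers(0, n_regions, size=n_events)
        else:
            draws = rng.choice(n_regions, size=n_events, replace=False)
        occ = np.bincount(draws, minlength=n_regions)
        multi[rep] = int((occ >= 2).sum())
        coocc[rep] = float((occ[draws] - 1).mean())
    return PermutationResult(
        replicates=reps,
        seed=seed,
        mean_regions_multi=float(multi.mean()),
        ci_regions_multi=tuple(np.percentile(multi, [2.5, 97.5])),
        mean_co_occupancy=float(coocc.mean()),
        ci_co_occupancy=tuple(np.percentile(coocc, [2.5, 97.5])),
    )


def normalize_depth(
    central_depths: Mapping[str, Sequence[float]],
    octoploid_samples: Sequence[str],
    diploid_sample: str,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Normalise per-sample central-site depths and form the
    octoploid:diploid ratio per targeted region.

    Each sample's depths are divided by their sum (so they sum to 1); the
    octoploid value per region is the mean of normalised depths across the
    octoploid parents.  Regions where the diploid normalised depth is zero
    get a NaN ratio (excluded from downstream comparisons).
    """
    normed: dict[str, np.ndarray] = {}
    for sample, depths in central_depths.items():
        arr = np.asarray(depths, dtype=float)
        total = arr.sum()
        if total <= 0:
            raise ValueError(f"sample {sample!r} has no depth")
        normed[sample] = arr / total
    octo = np.mean([normed[s] for s in octoploid_samples], axis=0)
    dip = normed[diploid_sample]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(dip > 0, octo / dip, np.nan)
    return normed, ratio


def compare_ratio_distributions(
    ratios_in_set: Sequence[float], ratios_out_of_set: Sequence[float]
) -> dict:
    """Welch two-sample t comparison of depth-ratio distributions."""
    a = np.asarray(ratios_in_set, dtype=float)
    b = np.asarray(ratios_out_of_set, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each set needs n >= 2")
    out = {
        "mean_in": float(a.mean()), "sd_in": float(a.std(ddof=1)),
        "mean_out": float(b.mean()), "sd_out": float(b.std(ddof=1)),
        "n_in": len(a), "n_out": len(b),
    }
    if out["sd_in"] == 0 and out["sd_out"] == 0:
        out["t"], out["p"] = float("nan"), float("nan")
        out["degenerate"] = True
        return out
    t, p = stats.ttest_ind(a, b, equal_var=False)
    out["t"], out["p"] = float(t), float(p)
    return out


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PrimerPlacement:
    marker_id: str
    chromosome: str
    forward_start: int       # 1-based position of forward primer 5' end
    reverse_start: int       # 1-based position of reverse primer 3'-most base
    amplicon_length: int


def insilico_pcr(
    primer_pairs: Iterable[tuple[str, str, str]],
    genome: Mapping[str, str],
    max_separation: int = 2000,
) -> list[PrimerPlacement]:
    """Place SSR primer pairs by exact matching.

    A placement requires the forward primer on the plus strand and the
    reverse primer's reverse complement downstream on the plus strand
    (primers on opposite strands facing inward), with 3' ends separated by
    <= ``max_separation`` bp.  Markers with no such placement are dropped.
    """
    placements: list[PrimerPlacement] = []
    for marker_id, fwd, rev in primer_pairs:
        fwd_u, rev_rc = fwd.upper(), reverse_complement(rev.upper())
        for chrom, seq in genome.items():
            seq_u = seq.upper()
            for f_start in _find_all(seq_u, fwd_u):
                f3 = f_start + len(fwd_u) - 1  # forward 3' end (0-based)
                window_end = min(len(seq_u), f3 + 1 + max_separation)
                r_start = seq_u.find(rev_rc, f3 + 1, window_end)
                while r_start != -1:
                    r3 = r_start  # reverse primer 3' end on plus strand
                    if r3 - f3 <= max_separation:
                        placements.append(
                            PrimerPlacement(
                                marker_id,
                                chrom,
                                f_start + 1,
                                r3 + 1,
                                r_start + len(rev_rc) - f_start,
                            )
                        )
                    r_start = seq_u.find(rev_rc, r_start + 1, window_end)
    return placements


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)
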