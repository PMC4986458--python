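"""Site/region homoplasy classification and introgression-cluster detection.

For a site with known bases for a subgenome (S), the F. vesca-like ingroup
taxon (V), the F. iinumae-like ingroup taxon (I) and an outgroup (O), only
2:2 base patterns are informative:

* SUPPORTIVE           -- S shares a base with its sister ingroup taxon while
                          the other two taxa share a different base;
* INTROGRESSION_LIKE   -- S shares a base with the *wrong* ingroup taxon
                          while its sister shares a different base with O;
* OUTGROUP_HOMOPLASY   -- S shares a base with O while V and I share a
                          different base.

Any other pattern (invariant, 3:1, >2 states) is uninformative.  Without
introgression, introgression-like and outgroup homoplasy arise from the same
processes (independent mutation, incomplete lineage sorting, error) and
should be equally frequent; the excess test is the resulting ABBA/BABA-style
comparison.

Region calls aggregate sites within a ~1-kb marker region; regions with both
supportive and introgression-like sites for the same parental sample are
"support/homoplasy" and count against introgression.  A cluster is a maximal
run of regions starting and ending at introgression-like regions, containing
at least two of them, with (introgression-like : supportive-side) ratio >= 4;
outgroup-homoplasy regions are neutral.  Overlapping qualifying windows merge.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from statistics import mean, median
from typing import Iterable, Sequence

import numpy as np
from scipy import stats


class SiteClass(enum.Enum):
    SUPPORTIVE = "supportive"
    INTROGRESSION_LIKE = "introgression_like"
    OUTGROUP_HOMOPLASY = "outgroup_homoplasy"
    UNINFORMATIVE = "uninformative"


class RegionClass(enum.Enum):
    SUPPORTIVE = "supportive"
    INTROGRESSION_LIKE = "introgression_like"
    OUTGROUP = "outgroup"
    SUPPORT_HOMOPLASY = "support_homoplasy"


def classify_site(
    subgenome_base: str,
    vesca_base: str,
    iinumae_base: str,
    outgroup_base: str,
    sister: str,
) -> SiteClass:
    """Classify one informative site; ``sister`` is ``"vesca"`` or
    ``"iinumae"`` (the subgenome's true sister ingroup taxon)."""
    s, v, i, o = (b.upper() for b in (subgenome_base, vesca_base,
                                      iinumae_base, outgroup_base))
    if sister not in ("vesca", "iinumae"):
        raise ValueError("sister must be 'vesca' or 'iinumae'")
    bases = (s, v, i, o)
    if len(set(bases)) != 2 or any(bases.count(b) != 2 for b in set(bases)):
        return SiteClass.UNINFORMATIVE
    sis, other = (v, i) if sister == "vesca" else (i, v)
    if s == sis and other == o:
        return SiteClass.SUPPORTIVE
    if s == other and sis == o:
        return SiteClass.INTROGRESSION_LIKE
    if s == o and v == i:
        return SiteClass.OUTGROUP_HOMOPLASY
    return SiteClass.UNINFORMATIVE


@dataclass
class RegionCall:
    region_id: int
    chromosome: str
    subgenome: str
    klass: RegionClass
    maps: frozenset[str]          # parental samples contributing
    first_site: int = 0           # span over member marker sites
    last_site: int = 0
    n_sites: int = 0


def classify_region(
    site_classes_by_map: dict[str, Sequence[SiteClass]]
) -> RegionClass | None:
    """Region-level call from per-parental-sample site classes.

    The support/homoplasy demotion applies when the *same* parental sample
    shows both supportive and introgression-like sites in the region.
    Returns None when the region has no informative site.
    """
    informative = [
        c
        for classes in site_classes_by_map.values()
        for c in classes
        if c is not SiteClass.UNINFORMATIVE
    ]
    if not informative:
        return None
    for classes in site_classes_by_map.values():
        if SiteClass.SUPPORTIVE in classes and SiteClass.INTROGRESSION_LIKE in classes:
            return RegionClass.SUPPORT_HOMOPLASY
    has_s = SiteClass.SUPPORTIVE in informative
    has_i = SiteClass.INTROGRESSION_LIKE in informative
    if has_s and has_i:
        return RegionClass.SUPPORT_HOMOPLASY
    if has_i:
        return RegionClass.INTROGRESSION_LIKE
    if has_s:
        return RegionClass.SUPPORTIVE
    return RegionClass.OUTGROUP


@dataclass
class IntrogressionCluster:
    subgenome: str
    chromosome: str
    first_site: int
    last_site: int
    region_count: int             # introgression-like member regions
    maps: frozenset[str]

    @property
    def span(self) -> int:
        return self.last_site - self.first_site


_SIDE = {
    RegionClass.INTROGRESSION_LIKE: "I",
    RegionClass.SUPPORTIVE: "S",
    RegionClass.SUPPORT_HOMOPLASY: "S",  # counts against introgression
    RegionClass.OUTGROUP: "O",           # neutral
}


def detect_clusters(
    region_calls: Sequence[RegionCall],
    min_regions: int = 2,
    min_ratio: float = 4.0,
) -> list[IntrogressionCluster]:
    """Find introgression clusters along one subgenome of one chromosome.

    ``region_calls`` must be position-sorted regions of a single subgenome.
    All maximal windows starting/ending at INTROGRESSION_LIKE regions with
    >= ``min_regions`` of them and introgression:supportive-side ratio
    >= ``min_ratio`` (zero supportive-side regions always qualifies) are
    reported; overlapping qualifying windows are merged.
    """
    track = [_SIDE[rc.klass] for rc in region_calls]
    n = len(track)
    i_idx = [k for k, t in enumerate(track) if t == "I"]
    if len(i_idx) < min_regions:
        return []
    # prefix counts for O(1) window evaluation
    ci = list(itertools.accumulate((1 if t == "I" else 0 for t in track), initial=0))
    cs = list(itertools.accumulate((1 if t == "S" else 0 for t in track), initial=0))
    qualifying: list[tuple[int, int]] = []
    for ai, a in enumerate(i_idx):
        for b in i_idx[ai + min_regions - 1 :]:
            ni = ci[b + 1] - ci[a]
            ns = cs[b + 1] - cs[a]
            if ni >= min_regions and (ns == 0 or ni >= min_ratio * ns):
                qualifying.append((a, b))
    if not qualifying:
        return []
    merged = merge_intervals(qualifying)
    clusters = []
    for a, b in merged:
        members = region_calls[a : b + 1]
        intro = [rc for rc in members if rc.klass is RegionClass.INTROGRESSION_LIKE]
        clusters.append(
            IntrogressionCluster(
                subgenome=members[0].subgenome,
                chromosome=members[0].chromosome,
                first_site=min(rc.first_site for rc in intro),
                last_site=max(rc.last_site for rc in intro),
                region_count=len(intro),
                maps=frozenset().union(*(rc.maps for rc in intro)),
            )
        )
    return clusters


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent closed intervals."""
    out: list[list[int]] = []
    for a, b in sorted(intervals):
        if out and a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [(a, b) for a, b in out]


def excess_homoplasy_test(
    n_introgression_like: int, n_outgroup: int
) -> tuple[float, float, float]:
    """(ratio, exact binomial p, Fisher p) for the homoplasy excess test.

    Under no introgression the two homoplasy classes are equally frequent;
    the primary test is an exact two-sided binomial against 0.5, with a
    Fisher variant against an exactly 50:50 expected row reported alongside.
    """
    a, b = n_introgression_like, n_outgroup
    if a < 0 or b < 0 or (a == 0 and b == 0):
        raise ValueError("counts must be nonnegative and not both zero")
    ratio = math_inf_ratio(a, b)
    p_binom = stats.binomtest(a, a + b, 0.5).pvalue
    half = (a + b) / 2
    expected = [int(np.floor(half)), int(np.ceil(half))]
    p_fisher = stats.fisher_exact([[a, b], expected]).pvalue
    return ratio, float(p_binom), float(p_fisher)


def math_inf_ratio(a: int, b: int) -> float:
    return a / b if b else float("inf")


def directionality_test(
    clusters_toward_vesca: int, clusters_toward_iinumae: int
) -> tuple[tuple[int, int], float]:
    """Fisher's exact test of observed cluster directions against a 3:1
    expectation (three F. iinumae-like subgenomes vs one Av).

    Returns ((expected_toward_vesca, expected_toward_iinumae), p).
    """
    total = clusters_toward_vesca + clusters_toward_iinumae
    if total < 1:
        raise ValueError("need at least one cluster")
    exp_v = round(total * 3 / 4)
    exp_i = total - exp_v
    table = [[clusters_toward_vesca, clusters_toward_iinumae], [exp_v, exp_i]]
    return (exp_v, exp_i), float(stats.fisher_exact(table).pvalue)


@dataclass
class ClusterGeometry:
    count: int
    span_min: int
    span_max: int
    span_median: float
    span_mean: float
    genomic_union: int
    overlap_instances: int
    overlap_extent: int


def cluster_geometry(clusters: Sequence[IntrogressionCluster]) -> ClusterGeometry:
    """Summary geometry over reference intervals of a cluster set.

    Span is last minus first member marker site.  The genomic union merges
    all intervals regardless of subgenome; overlap statistics count pairwise
    intersections between clusters on *different* subgenomes (extent is the
    union length of those intersections).
    """
    if not clusters:
        return ClusterGeometry(0, 0, 0, 0.0, 0.0, 0, 0, 0)
    spans = [c.span for c in clusters]
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c in clusters:
        by_chrom.setdefault(c.chromosome, []).append((c.first_site, c.last_site))
    union = sum(
        b - a for ivs in by_chrom.values() for a, b in merge_intervals(ivs)
    )
    inter: dict[str, list[tuple[int, int]]] = {}
    instances = 0
    for c1, c2 in itertools.combinations(clusters, 2):
        if c1.chromosome != c2.chromosome or c1.subgenome == c2.subgenome:
            continue
        a = max(c1.first_site, c2.first_site)
        b = min(c1.last_site, c2.last_site)
        if a <= b:
            instances += 1
            inter.setdefault(c1.chromosome, []).append((a, b))
    extent = sum(
        b - a for ivs in inter.values() for a, b in merge_intervals(ivs)
    )
    return ClusterGeometry(
        count=len(clusters),
        span_min=min(spans),
        span_max=max(spans),
        span_median=float(median(spans)),
        span_mean=float(mean(spans)),
        genomic_union=int(union),
        overlap_instances=instances,
        overlap_extent=int(extent),
    )


def allele_depth_ratio(
    positions: np.ndarray,
    vesca_like_depth: np.ndarray,
    iinumae_like_depth: np.ndarray,
    cluster_intervals: Sequence[tuple[int, int]],
    bin_size: int = 1_000_000,
    min_combined: int = 45,
    max_combined: int = 200,
    max_ratio: float = 8.0,
) -> dict:
    """Per-bin mean vesca:iinumae allele-depth ratios plus the in/out-of-
    cluster Welch comparison.

    Sites are retained when ``min_combined <= v + i <= max_combined`` and
    ``1/max_ratio <= v/i <= max_ratio`` (zero-denominator sites dropped).
    """
    positions = np.asarray(positions)
    v = np.asarray(vesca_like_depth, dtype=float)
    i = np.asarray(iinumae_like_depth, dtype=float)
    combined = v + i
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(i > 0, v / i, np.inf)
    keep = (
        (combined >= min_combined)
        & (combined <= max_combined)
        & (i > 0)
        & (ratio <= max_ratio)
        & (ratio >= 1.0 / max_ratio)
    )
    positions, ratio = positions[keep], ratio[keep]
    in_cluster = np.zeros(len(positions), dtype=bool)
    for a, b in cluster_intervals:
        in_cluster |= (positions >= a) & (positions <= b)
    bins = positions // bin_size
    bin_means = {
        int(b): float(ratio[bins == b].mean()) for b in np.unique(bins)
    }
    result = {
        "bin_means": bin_means,
        "n_sites": int(keep.sum()),
        "mean_in": float(ratio[in_cluster].mean()) if in_cluster.any() else np.nan,
        "mean_out": float(ratio[~in_cluster].mean()) if (~in_cluster).any() else np.nan,
    }
    if in_cluster.sum() >= 2 and (~in_cluster).sum() >= 2:
        t, p = stats.ttest_ind(ratio[in_cluster], ratio[~in_cluster], equal_var=False)
        result["welch_t"], result["welch_p"] = float(t), float(p)
    return result


def source_informative_sites(
    rows: Iterable[tuple[str, str, str, str]]
) -> tuple[int, int]:
    """Count sites polarising the source of introgressed sequence.

    Each row holds (B-subgenome base, vesca base, Av base, outgroup base).
    A site counts when the B subgenome carries a derived allele (relative to
    the outgroup) shared with exactly one of {vesca, Av}.  Returns
    (shared-with-vesca-only, shared-with-Av-only).
    """
    vesca_only = av_only = 0
    for b, v, av, og in rows:
        b, v, av, og = (x.upper() for x in (b, v, av, og))
        if b == og:
            continue  # not derived
        if b == v and b != av:
            vesca_only += 1
        elif b == av and b != v:
            av_only += 1
    return vesca_only, av_only
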