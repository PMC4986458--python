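"""Two-point linkage grouping of LG SNPs for a disomic testcross.

Each LG SNP segregates 1:1 (HET x HOM testcross configuration), so its
progeny vector is binary.  For a marker pair with n pairwise-complete progeny
and k matches under the better of the two linkage phases, the recombination
fraction estimate is r = (n - k) / n (clamped away from 0 and 0.5) and the
two-point LOD at r is

    LOD = k*log10(2*(1 - r)) + (n - k)*log10(2*r).

Markers are grouped by single-linkage transitive closure over pairs with
LOD >= 5, ordered within a group by greedy nearest-neighbour seriation on r,
converted to centimorgans with the Kosambi map function
d = 25*ln((1 + 2r)/(1 - 2r)), and split wherever adjacent markers are more
than 33 cM apart.  Groups that the splitting step separated but that share a
reference chromosome (and compatible subgenome label, when known) are joined
back automatically, with every join logged -- a deterministic stand-in for
the visual-inspection joins used when curating real maps.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .calling import LGSNP

logger = logging.getLogger(__name__)

LOD_THRESHOLD = 5.0
GAP_CM = 33.0
MIN_MAJOR_SIZE = 5
R_FLOOR = 1e-6

ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII")
SUBGENOMES = ("Av", "B1", "B2", "Bi")


@dataclass
class SegregationVector:
    """Binary HET/HOM progeny states with a missing mask."""

    states: np.ndarray   # int8, 0/1
    missing: np.ndarray  # bool

    @classmethod
    def from_lg_snp(cls, snp: LGSNP) -> "SegregationVector":
        states, missing = snp.segregation()
        return cls(np.asarray(states, dtype=np.int8), np.asarray(missing, dtype=bool))


def two_point_rf_lod(
    v1: SegregationVector, v2: SegregationVector
) -> tuple[float, float]:
    """Recombination fraction and LOD for one marker pair (pairwise deletion).

    The linkage phase is unknown, so the phase minimising r is used.  Returns
    (nan, nan) when no pairwise-complete progeny exist.
    """
    ok = ~(v1.missing | v2.missing)
    n = int(ok.sum())
    if n == 0:
        return math.nan, math.nan
    agree = int((v1.states[ok] == v2.states[ok]).sum())
    k = max(agree, n - agree)  # phase minimising r
    r = (n - k) / n
    r = min(max(r, R_FLOOR), 0.5)
    lod = k * math.log10(2.0 * (1.0 - r)) + (n - k) * math.log10(2.0 * r)
    return r, lod


def pairwise_rf_lod(vectors: Sequence[SegregationVector]) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised all-pairs (r, LOD) matrices for one parent's markers."""
    m = len(vectors)
    S = np.stack([v.states for v in vectors]).astype(np.float64)
    P = np.stack([~v.missing for v in vectors]).astype(np.float64)
    S = S * P
    n = P @ P.T
    # agreements = both-1 matches + both-0 matches over complete pairs
    both1 = S @ S.T
    both0 = (P - S) @ (P - S).T
    agree = both1 + both0
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.maximum(agree, n - agree)
        r = (n - k) / np.maximum(n, 1)
        r = np.clip(r, R_FLOOR, 0.5)
        lod = k * np.log10(2.0 * (1.0 - r)) + (n - k) * np.log10(2.0 * r)
    lod[n == 0] = np.nan
    r[n == 0] = np.nan
    np.fill_diagonal(lod, 0.0)
    np.fill_diagonal(r, 0.0)
    return r, lod


def cluster_at_lod(lod: np.ndarray, threshold: float = LOD_THRESHOLD) -> list[list[int]]:
    """Single-linkage transitive closure over marker pairs with LOD >= 5."""
    adj = csr_matrix(np.nan_to_num(lod, nan=-np.inf) >= threshold)
    n_comp, labels = connected_components(adj, directed=False)
    groups: list[list[int]] = [[] for _ in range(n_comp)]
    for i, lab in enumerate(labels):
        groups[lab].append(i)
    groups.sort(key=lambda g: g[0])
    return groups


def cluster_vectors_at_lod(
    vectors: Sequence[SegregationVector],
    threshold: float = LOD_THRESHOLD,
    block: int = 512,
) -> list[list[int]]:
    """Memory-bounded LOD clustering: the full pairwise LOD matrix is never
    materialised; linked pairs are found block-by-block and clustered by
    transitive closure.  Identical to :func:`cluster_at_lod` on the dense
    matrix."""
    m = len(vectors)
    if m == 0:
        return []
    S = np.stack([v.states for v in vectors]).astype(np.float32)
    P = np.stack([~v.missing for v in vectors]).astype(np.float32)
    S = S * P
    rows_idx: list[np.ndarray] = []
    cols_idx: list[np.ndarray] = []
    for lo in range(0, m, block):
        hi = min(lo + block, m)
        n = P[lo:hi] @ P.T
        agree = S[lo:hi] @ S.T + (P[lo:hi] - S[lo:hi]) @ (P - S).T
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.maximum(agree, n - agree)
            r = np.clip((n - k) / np.maximum(n, 1), R_FLOOR, 0.5)
            lod = k * np.log10(2.0 * (1.0 - r)) + (n - k) * np.log10(2.0 * r)
        lod[n == 0] = -np.inf
        rr, cc = np.nonzero(lod >= threshold)
        rows_idx.append(rr + lo)
        cols_idx.append(cc)
    rows = np.concatenate(rows_idx)
    cols = np.concatenate(cols_idx)
    adj = csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(m, m)
    )
    n_comp, labels = connected_components(adj, directed=False)
    groups: list[list[int]] = [[] for _ in range(n_comp)]
    for i, lab in enumerate(labels):
        groups[lab].append(i)
    groups.sort(key=lambda g: g[0])
    return groups


def kosambi(r: float) -> float:
    """Kosambi map distance in cM; monotone in r, unbounded as r -> 0.5."""
    r = min(max(r, 0.0), 0.5 - 1e-12)
    return 25.0 * math.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def haldane(r: float) -> float:
    r = min(max(r, 0.0), 0.5 - 1e-12)
    return -50.0 * math.log(1.0 - 2.0 * r)


def seriate(
    members: Sequence[int], r: np.ndarray, tie_key: Sequence[tuple] | None = None
) -> list[int]:
    """Greedy nearest-neighbour ordering on recombination fractions.

    Starts from the pair with the largest r inside the group (the putative
    ends) and extends the path end with the closest unplaced marker.  Ties
    are broken by ``tie_key`` (reference position) then index.
    """
    if len(members) <= 2:
        return list(members)
    key = {i: (tie_key[j] if tie_key is not None else ()) for j, i in enumerate(members)}
    sub = [(r[i, j], i, j) for a, i in enumerate(members) for j in members[a + 1 :]]
    _, start, _ = max(sub, key=lambda t: (t[0], key[t[1]], key[t[2]]))
    path = [start]
    unplaced = set(members) - {start}
    while unplaced:
        head, tail = path[0], path[-1]
        cand_tail = min(unplaced, key=lambda i: (r[tail, i], key[i], i))
        cand_head = min(unplaced, key=lambda i: (r[head, i], key[i], i))
        if r[tail, cand_tail] <= r[head, cand_head]:
            path.append(cand_tail)
            unplaced.discard(cand_tail)
        else:
            path.insert(0, cand_head)
            unplaced.discard(cand_head)
    return path


@dataclass
class LinkageGroup:
    """An ordered set of LG SNPs with centimorgan positions."""

    group_id: str
    snps: list[LGSNP]
    cm_positions: list[float]
    parent: str = "?"                     # 'm' or 'p'
    primary_chromosome: str | None = None
    subgenome_label: str | None = None
    name: str | None = None

    @property
    def is_major(self) -> bool:
        return len(self.snps) >= MIN_MAJOR_SIZE

    def chromosomes(self) -> list[str]:
        return [s.coordinate.chromosome for s in self.snps]


def order_and_split(
    members: Sequence[int],
    snps: Sequence[LGSNP],
    r: np.ndarray,
    gap_cm: float = GAP_CM,
    map_function=kosambi,
) -> list[list[int]]:
    """Order a group by seriation and split at adjacent gaps > ``gap_cm``."""
    tie = [(snps[i].coordinate.chromosome, snps[i].coordinate.position) for i in members]
    path = seriate(list(members), r, tie_key=tie)
    pieces: list[list[int]] = [[path[0]]]
    for a, b in zip(path, path[1:]):
        if map_function(r[a, b]) > gap_cm:
            pieces.append([])
        pieces[-1].append(b)
    return pieces


def assign_primary_chromosome(chromosomes: Sequence[str]) -> tuple[str, bool]:
    """Modal reference chromosome of a group's markers.

    Ties go to the smaller chromosome identifier; the second return value
    flags that a tie occurred.
    """
    if not chromosomes:
        raise ValueError("empty group has no primary chromosome")
    counts: dict[str, int] = {}
    for c in chromosomes:
        counts[c] = counts.get(c, 0) + 1
    best = max(counts.values())
    modal = sorted(c for c, n in counts.items() if n == best)
    tie = len(modal) > 1
    if tie:
        logger.warning("primary-chromosome tie among %s; using %s", modal, modal[0])
    return modal[0], tie


def cm_from_path(members: Sequence[int], r: np.ndarray, map_function=kosambi) -> list[float]:
    cm = [0.0]
    for a, b in zip(members, members[1:]):
        cm.append(cm[-1] + map_function(r[a, b]))
    return cm


def build_linkage_groups(
    snps: Sequence[LGSNP],
    parent: str,
    lod_threshold: float = LOD_THRESHOLD,
    gap_cm: float = GAP_CM,
    map_function=kosambi,
    auto_join: bool = True,
) -> list[LinkageGroup]:
    """Full grouping pipeline for one parent's LG SNPs.

    Cluster at LOD >= 5, seriate, split at > 33 cM gaps, then automatically
    re-join split pieces that share a primary reference chromosome (logged).
    """
    if not snps:
        return []
    vectors = [SegregationVector.from_lg_snp(s) for s in snps]
    raw_groups = cluster_vectors_at_lod(vectors, lod_threshold)
    pieces: list[list[int]] = []
    r_cache: dict[int, tuple[dict[int, int], np.ndarray]] = {}
    for gid, g in enumerate(raw_groups):
        if len(g) == 1:
            cluster_pieces = [list(g)]
        else:
            # recombination fractions only within the cluster
            sub_r, _ = pairwise_rf_lod([vectors[i] for i in g])
            local = {i: j for j, i in enumerate(g)}
            r_cache[gid] = (local, sub_r)
            r_view = _SubmatrixView(local, sub_r)
            cluster_pieces = order_and_split(g, snps, r_view, gap_cm, map_function)
        if auto_join and len(cluster_pieces) > 1:
            cluster_pieces = _auto_join(cluster_pieces, snps)
        for piece in cluster_pieces:
            pieces.append((gid, piece))
    groups = []
    for gi, (gid, members) in enumerate(pieces):
        chrom, _ = assign_primary_chromosome([snps[i].coordinate.chromosome for i in members])
        if gid in r_cache:
            local, sub_r = r_cache[gid]
            cm = cm_from_path(
                [local[i] for i in members], sub_r, map_function
            )
        else:
            cm = [0.0] * len(members)
        groups.append(
            LinkageGroup(
                group_id=f"{parent}{gi:02d}",
                snps=[snps[i] for i in members],
                cm_positions=cm,
                parent=parent,
                primary_chromosome=chrom,
            )
        )
    return groups


class _SubmatrixView:
    """Index a within-cluster rf matrix by global marker indices."""

    def __init__(self, local: dict[int, int], sub: np.ndarray):
        self._local = local
        self._sub = sub

    def __getitem__(self, key):
        i, j = key
        return self._sub[self._local[i], self._local[j]]


def _auto_join(pieces: list[list[int]], snps: Sequence[LGSNP]) -> list[list[int]]:
    """Re-join pieces split from one LOD cluster that share a primary
    reference chromosome, largest first.  Only called within a cluster:
    homeologous groups from different clusters share reference chromosomes
    by construction and must never be merged on that evidence alone."""
    by_chrom: dict[str, list[list[int]]] = {}
    for piece in pieces:
        chrom, _ = assign_primary_chromosome([snps[i].coordinate.chromosome for i in piece])
        by_chrom.setdefault(chrom, []).append(piece)
    joined: list[list[int]] = []
    for chrom in sorted(by_chrom):
        parts = sorted(by_chrom[chrom], key=len, reverse=True)
        if len(parts) > 1:
            logger.info(
                "auto-join: merged %d linkage-group pieces on %s (sizes %s)",
                len(parts), chrom, [len(p) for p in parts],
            )
        merged: list[int] = []
        for p in parts:
            merged.extend(p)
        joined.append(merged)
    return joined


def join_groups_by_label(groups: list[LinkageGroup]) -> list[LinkageGroup]:
    """Join groups of one parent sharing both primary chromosome and a
    resolved subgenome label (the post-labelling analogue of manual joins).
    Unlabelled or singleton combinations pass through unchanged; every join
    is logged."""
    by_key: dict[tuple, list[LinkageGroup]] = {}
    passthrough: list[LinkageGroup] = []
    for g in groups:
        if g.subgenome_label in (None, "unresolved"):
            passthrough.append(g)
        else:
            by_key.setdefault(
                (g.parent, g.primary_chromosome, g.subgenome_label), []
            ).append(g)
    out: list[LinkageGroup] = list(passthrough)
    for key in sorted(by_key):
        parts = sorted(by_key[key], key=lambda g: len(g.snps), reverse=True)
        if len(parts) == 1:
            out.append(parts[0])
            continue
        logger.info(
            "label-join: merged %d groups with key %s (sizes %s)",
            len(parts), key, [len(p.snps) for p in parts],
        )
        snps, cms, offset = [], [], 0.0
        for p in parts:
            snps.extend(p.snps)
            cms.extend(c + offset for c in p.cm_positions)
            offset = cms[-1] + GAP_CM
        merged = LinkageGroup(
            group_id=parts[0].group_id,
            snps=snps,
            cm_positions=cms,
            parent=parts[0].parent,
            primary_chromosome=parts[0].primary_chromosome,
            subgenome_label=parts[0].subgenome_label,
        )
        out.append(merged)
    return out


def pair_parental_groups(
    shared_region_counts: dict[tuple[str, str], int]
) -> list[tuple[str, str]]:
    """Maximum-weight bipartite matching of maternal to paternal groups.

    ``shared_region_counts`` maps (maternal_id, paternal_id) to the number of
    biparental-SNP regions shared by the two groups.  Unmatched groups are
    simply absent from the result.
    """
    if not shared_region_counts:
        return []
    mats = sorted({m for m, _ in shared_region_counts})
    pats = sorted({p for _, p in shared_region_counts})
    W = np.zeros((len(mats), len(pats)))
    for (m, p), w in shared_region_counts.items():
        W[mats.index(m), pats.index(p)] = w
    rows, cols = linear_sum_assignment(-W)
    return [(mats[i], pats[j]) for i, j in zip(rows, cols) if W[i, j] > 0]


def name_group(
    species_code: str, chromosome_numeral: str, subgenome: str, parent: str
) -> str:
    """Hyphen-joined map name, e.g. ``Fvirg-IV-Av-p``."""
    if chromosome_numeral not in ROMAN:
        raise ValueError(f"chromosome numeral must be one of {ROMAN}")
    if subgenome not in SUBGENOMES:
        raise ValueError(f"subgenome must be one of {SUBGENOMES}")
    if parent not in ("m", "p"):
        raise ValueError("parent must be 'm' or 'p'")
    if not species_code or "-" in species_code:
        raise ValueError("invalid species code")
    return f"{species_code}-{chromosome_numeral}-{subgenome}-{parent}"
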