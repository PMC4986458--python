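"""Read-anchored phylogenetic markers and subgenome labelling.

An LG SNP's minor allele occurs on a single homeolog, so the subset of reads
carrying that allele samples one subgenome's haplotype.  Any variant site on
those reads within a read length of the anchor can therefore be assigned to
the anchor's linkage group and used as a phylogenetic marker, even though the
site itself is not segregating in the cross.  LG SNP positions themselves are
never used as markers.

Markers for the linkage groups of one haploid chromosome, together with
diploid reference-taxon calls and an outgroup, form a site x taxon matrix
with (often extensive) missing data.  An internal neighbour-joining tree on
p-distances with pairwise deletion supports automatic subgenome labelling:

* Av -- the group(s) inside the minimal clade containing the F. vesca-like
  taxon but not the F. iinumae-like taxon;
* Bi -- among the rest, the group(s) sister to the F. iinumae-like taxon;
* B1/B2 -- of a parent's final two groups, B1 is the one with the greater
  mean p-distance to the F. iinumae-like taxon.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from .formats_io import MISSING_CHAR, GenomeCoordinate, TaxonMatrix

logger = logging.getLogger(__name__)

READ_LENGTH = 100
BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3}
CODE_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class AlignedRead:
    """A gap-free aligned read: reference start (1-based) plus its sequence."""

    start: int
    sequence: str
    sample: str = ""

    @property
    def end(self) -> int:
        return self.start + len(self.sequence) - 1

    def base_at(self, position: int) -> str | None:
        if self.start <= position <= self.end:
            return self.sequence[position - self.start].upper()
        return None


@dataclass(frozen=True)
class AnchoredMarker:
    coordinate: GenomeCoordinate
    linkage_group_id: str
    base: str
    supporting_read_count: int
    distance_to_anchor_bp: int


@dataclass
class ReadBlock:
    """Reads of one capture target, materialised only at variant sites.

    ``bases`` holds base codes (0..3) for every read at every site; whether a
    read actually covers a site is derived from ``starts`` and
    ``read_length``.
    """

    chromosome: str
    sites: np.ndarray        # int64 positions, sorted ascending
    starts: np.ndarray       # int64, one per read
    bases: np.ndarray        # uint8 (n_reads, n_sites)
    read_length: int = READ_LENGTH

    def coverage(self) -> np.ndarray:
        """Boolean (n_reads, n_sites): read covers site."""
        s = self.starts[:, None]
        p = self.sites[None, :]
        return (s <= p) & (p < s + self.read_length)


def anchor_block(
    block: ReadBlock,
    anchors: Sequence[tuple[int, str, str]],
    excluded_positions: frozenset[int] | set[int],
    min_support: int = 1,
) -> list[AnchoredMarker]:
    """Extract markers from one read block.

    ``anchors`` holds (position, minor_allele, linkage_group_id) for the LG
    SNPs falling in this block.  For each linkage group, reads carrying a
    minor allele at any of its anchors are pooled; at every variant site
    covered by >= ``min_support`` such reads a strict-majority consensus is
    emitted (exact tie or no majority -> no marker).  Sites in
    ``excluded_positions`` (all LG SNP positions) are skipped.
    """
    if len(block.sites) == 0 or len(block.starts) == 0:
        return []
    cov = block.coverage()
    site_index = {int(p): i for i, p in enumerate(block.sites)}
    # pool qualifying reads per linkage group
    group_reads: dict[str, np.ndarray] = {}
    group_anchor_pos: dict[str, list[int]] = {}
    for pos, minor, group_id in anchors:
        i = site_index.get(int(pos))
        if i is None:
            continue
        code = BASE_CODES[minor]
        qual = cov[:, i] & (block.bases[:, i] == code)
        if group_id in group_reads:
            group_reads[group_id] |= qual
        else:
            group_reads[group_id] = qual
        group_anchor_pos.setdefault(group_id, []).append(int(pos))
    markers: list[AnchoredMarker] = []
    for group_id in sorted(group_reads):
        mask = group_reads[group_id]
        if not mask.any():
            continue
        sub_cov = cov[mask]
        sub_bases = block.bases[mask]
        apos = group_anchor_pos[group_id]
        for j, pos in enumerate(block.sites):
            pos = int(pos)
            if pos in excluded_positions:
                continue
            covering = sub_cov[:, j]
            n = int(covering.sum())
            if n < max(min_support, 1):
                continue
            counts = np.bincount(sub_bases[covering, j], minlength=4)
            best = int(counts.argmax())
            if counts[best] * 2 <= n:  # no strict majority
                continue
            dist = min(abs(pos - a) for a in apos)
            markers.append(
                AnchoredMarker(
                    GenomeCoordinate(block.chromosome, pos),
                    group_id,
                    str(CODE_BASES[best]),
                    int(counts[best]),
                    dist,
                )
            )
    return markers


def reads_to_block(
    reads: Sequence[AlignedRead], chromosome: str, sites: Sequence[int],
    read_length: int = READ_LENGTH,
) -> ReadBlock:
    """Materialise aligned reads into a :class:`ReadBlock` at given sites."""
    sites_arr = np.asarray(sorted(sites), dtype=np.int64)
    starts = np.array([r.start for r in reads], dtype=np.int64)
    bases = np.zeros((len(reads), len(sites_arr)), dtype=np.uint8)
    for i, r in enumerate(reads):
        for j, p in enumerate(sites_arr):
            b = r.base_at(int(p))
            if b in BASE_CODES:
                bases[i, j] = BASE_CODES[b]
    return ReadBlock(chromosome, sites_arr, starts, bases, read_length)


def extract_anchored_markers(
    reads: Sequence[AlignedRead],
    lg_snps: Sequence[tuple[int, str, str]],
    variant_sites: Sequence[int],
    chromosome: str = ".",
    read_length: int = READ_LENGTH,
    min_support: int = 1,
) -> list[AnchoredMarker]:
    """Record-level entry point: anchors are (position, minor_allele,
    linkage_group_id) triples; ``variant_sites`` are the candidate marker
    positions (sites segregating among groups and/or diploid taxa)."""
    anchor_positions = {int(p) for p, _, _ in lg_snps}
    all_sites = sorted(set(int(p) for p in variant_sites) | anchor_positions)
    block = reads_to_block(reads, chromosome, all_sites, read_length)
    return anchor_block(block, lg_snps, frozenset(anchor_positions), min_support)


def build_taxon_matrix(
    markers: Iterable[AnchoredMarker],
    diploid_calls: Mapping[str, Mapping[int, str]],
    chromosome: str,
    group_ids: Sequence[str] | None = None,
) -> TaxonMatrix:
    """Assemble the per-chromosome site x taxon matrix.

    Rows are linkage groups followed by diploid taxa; cells with no
    qualifying read (or no diploid call) are missing; sites with zero
    non-missing rows are dropped.  Markers from other chromosomes are
    ignored.
    """
    markers = [m for m in markers if m.coordinate.chromosome == chromosome]
    groups = sorted({m.linkage_group_id for m in markers})
    if group_ids is not None:
        groups = list(group_ids)
    taxa = groups + sorted(diploid_calls)
    positions = sorted(
        {m.coordinate.position for m in markers}
        | {p for calls in diploid_calls.values() for p in calls}
    )
    idx = {p: j for j, p in enumerate(positions)}
    cells = np.full((len(taxa), len(positions)), MISSING_CHAR, dtype="<U1")
    for m in markers:
        if m.linkage_group_id in groups:
            cells[groups.index(m.linkage_group_id), idx[m.coordinate.position]] = m.base
    for i, taxon in enumerate(sorted(diploid_calls), start=len(groups)):
        for p, b in diploid_calls[taxon].items():
            cells[i, idx[p]] = b.upper()
    matrix = TaxonMatrix(
        taxa, [GenomeCoordinate(chromosome, p) for p in positions], cells
    )
    return matrix.drop_empty_sites()


def p_distance_matrix(matrix: TaxonMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise p-distances with pairwise deletion.

    Returns (distances, shared-site counts).  Pairs with zero shared sites
    get the maximum observed distance (logged).
    """
    cells = matrix.cells
    present = cells != MISSING_CHAR
    n = len(matrix.taxa)
    d = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            both = present[i] & present[j]
            m = int(both.sum())
            shared[i, j] = shared[j, i] = m
            if m:
                d[i, j] = d[j, i] = float((cells[i, both] != cells[j, both]).mean())
    if (shared + np.eye(n, dtype=int) == 0).any():
        dmax = d.max() if d.max() > 0 else 1.0
        holes = shared + np.eye(n, dtype=int) == 0
        d[holes] = dmax
        logger.warning(
            "%d taxon pairs share no sites; distance set to max observed (%.3f)",
            int(holes.sum()) // 2, dmax,
        )
    return d, shared


def nj_tree(matrix: TaxonMatrix) -> TreeNode:
    """Neighbour-joining tree on p-distances (pairwise deletion)."""
    if len(matrix.taxa) < 3:
        raise ValueError("neighbour joining requires at least 3 taxa")
    d, _ = p_distance_matrix(matrix)
    dm = DistanceMatrix(d, ids=matrix.taxa)
    return _skbio_nj(dm)


def _clades(tree: TreeNode, outgroup_taxa: set[str]) -> list[set[str]]:
    """All unrooted splits, expressed as the side not containing any
    outgroup taxon (i.e. clades of the outgroup-rooted tree)."""
    clades = []
    for node in tree.traverse(include_self=False):
        tips = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        if tips & outgroup_taxa:
            tips = {t.name for t in tree.tips()} - tips
        if tips and not (tips & outgroup_taxa):
            clades.append(tips)
    return clades


def assign_subgenome_labels(
    tree: TreeNode,
    matrix: TaxonMatrix,
    group_parents: Mapping[str, str],
    vesca_taxon: str,
    iinumae_taxon: str,
    outgroup_taxa: Sequence[str],
) -> dict[str, str]:
    """Label each linkage group Av / Bi / B1 / B2 from tree position.

    ``group_parents`` maps linkage-group taxon names to a parent key (any
    hashable tag).  Tree clades drive the assignment: Av from the minimal
    clade containing the vesca-like taxon, Bi from the minimal clade
    containing the iinumae-like taxon among the rest, B1/B2 by divergence
    from the iinumae-like taxon within each parent.  When a parent has all
    four groups but the clade-based assignment is inconsistent (sparse
    shared sites can distort NJ), that parent falls back to a deterministic
    divergence ranking: Av = closest to vesca, then Bi = closest / B1 =
    farthest from iinumae.  Anything still inconsistent is labelled
    ``unresolved`` rather than guessed.
    """
    og = set(outgroup_taxa)
    groups = set(group_parents)
    clades = _clades(tree, og)

    def minimal_clade(include: str, exclude: str, candidates: set[str]) -> set[str] | None:
        best = None
        for c in clades:
            if include in c and exclude not in c and c & candidates:
                if best is None or len(c) < len(best):
                    best = c
        return best

    tentative: dict[str, str] = {}
    av_clade = minimal_clade(vesca_taxon, iinumae_taxon, groups)
    if av_clade:
        for g in av_clade & groups:
            tentative[g] = "Av"
    remaining = groups - set(tentative)
    bi_clade = minimal_clade(iinumae_taxon, vesca_taxon, remaining)
    if bi_clade:
        for g in bi_clade & remaining:
            tentative[g] = "Bi"

    d, _ = p_distance_matrix(matrix)
    tidx = {t: i for i, t in enumerate(matrix.taxa)}
    ii = tidx.get(iinumae_taxon)
    vv = tidx.get(vesca_taxon)

    def dist(g: str, ref: int | None) -> float:
        if ref is None or g not in tidx:
            return math.nan
        return float(d[tidx[g], ref])

    labels: dict[str, str] = {}
    by_parent: dict[str, list[str]] = {}
    for g in sorted(groups):
        by_parent.setdefault(group_parents[g], []).append(g)
    for parent, gs in sorted(by_parent.items()):
        got = [tentative.get(g) for g in gs]
        n_av, n_bi = got.count("Av"), got.count("Bi")
        consistent = (
            n_av <= 1 and n_bi <= 1 and len(gs) - n_av - n_bi in (0, 2)
        )
        if consistent:
            labels.update({g: tentative[g] for g in gs if g in tentative})
            rest = [g for g in gs if g not in tentative]
            _rank_b1_b2(rest, labels, dist, ii, parent)
            continue
        if len(gs) == 4 and ii is not None and vv is not None and all(
            g in tidx for g in gs
        ):
            logger.info(
                "clade labelling inconsistent for parent %r; using divergence "
                "ranking", parent,
            )
            av = min(gs, key=lambda g: (dist(g, vv), g))
            labels[av] = "Av"
            rest = sorted(set(gs) - {av})
            bi = min(rest, key=lambda g: (dist(g, ii), g))
            labels[bi] = "Bi"
            _rank_b1_b2(sorted(set(rest) - {bi}), labels, dist, ii, parent)
        else:
            logger.warning(
                "labels unresolved for parent %r (clades inconsistent)", parent
            )
            for g in gs:
                labels[g] = "unresolved"
    return labels


def _rank_b1_b2(rest: list[str], labels: dict[str, str], dist, ii, parent) -> None:
    if not rest:
        return
    if len(rest) != 2 or ii is None:
        for g in rest:
            labels[g] = "unresolved"
        return
    d0, d1 = dist(rest[0], ii), dist(rest[1], ii)
    if math.isnan(d0) or math.isnan(d1):
        for g in rest:
            labels[g] = "unresolved"
    elif d0 == d1:
        logger.warning("B1/B2 tie for parent %r (%s); using group-id order", parent, rest)
        labels[rest[0]], labels[rest[1]] = "B1", "B2"
    elif d0 > d1:
        labels[rest[0]], labels[rest[1]] = "B1", "B2"
    else:
        labels[rest[0]], labels[rest[1]] = "B2", "B1"
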