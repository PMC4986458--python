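"""Read-anchored marker extraction, taxon matrices, NJ and labelling."""

import itertools

import numpy as np
import pytest

from polymaps.anchoring import (
    AlignedRead,
    anchor_block,
    assign_subgenome_labels,
    build_taxon_matrix,
    extract_anchored_markers,
    nj_tree,
    p_distance_matrix,
    reads_to_block,
)
from polymaps.formats_io import GenomeCoordinate, TaxonMatrix


def read_at(start, seq):
    return AlignedRead(start, seq)


class TestExtractAnchoredMarkers:
    def _reads(self):
        # anchor site at 100 (minor T, major A), marker site at 140
        ref = "A" * 200
        reads = []
        for _ in range(3):  # minor-allele reads show G at 140
            seq = list("A" * 100)
            seq[100 - 60] = "T"   # read start 60: position 100 at index 40
            seq[140 - 60] = "G"
            reads.append(read_at(60, "".join(seq)))
        for _ in range(5):  # major-allele reads carry A at both sites
            reads.append(read_at(60, "A" * 100))
        return reads

    def test_unanimous_consensus(self):
        markers = extract_anchored_markers(
            self._reads(), [(100, "T", "g1")], [140], chromosome="chr1"
        )
        assert len(markers) == 1
        m = markers[0]
        assert (m.coordinate.position, m.base) == (140, "G")
        assert m.supporting_read_count == 3
        assert m.distance_to_anchor_bp == 40

    def test_major_allele_reads_ignored(self):
        # without the minor-allele reads there is no marker at all
        reads = [read_at(60, "A" * 100) for _ in range(5)]
        markers = extract_anchored_markers(
            reads, [(100, "T", "g1")], [140], chromosome="chr1"
        )
        assert markers == []

    def test_tie_gives_no_marker(self):
        reads = []
        for base in "GGCC":
            seq = list("A" * 100)
            seq[40] = "T"
            seq[80] = base
            reads.append(read_at(60, "".join(seq)))
        markers = extract_anchored_markers(
            reads, [(100, "T", "g1")], [140], chromosome="chr1"
        )
        assert markers == []

    def test_markers_never_at_anchor_positions(self):
        # two LG SNPs of different groups share reads; neither position may
        # yield a marker even though it differentiates the groups
        reads = []
        for _ in range(3):
            seq = list("A" * 100)
            seq[40] = "T"
            reads.append(read_at(60, "".join(seq)))
        markers = extract_anchored_markers(
            reads, [(100, "T", "g1"), (120, "C", "g2")], [100, 120, 140],
            chromosome="chr1",
        )
        assert all(m.coordinate.position not in (100, 120) for m in markers)

    def test_min_support_threshold(self):
        markers = extract_anchored_markers(
            self._reads(), [(100, "T", "g1")], [140], chromosome="chr1",
            min_support=4,
        )
        assert markers == []

    def test_block_and_record_paths_agree(self):
        reads = self._reads()
        sites = [100, 140]
        block = reads_to_block(reads, "chr1", sites)
        got = anchor_block(block, [(100, "T", "g1")], frozenset({100}))
        via_records = extract_anchored_markers(
            reads, [(100, "T", "g1")], [140], chromosome="chr1"
        )
        assert [(m.coordinate.position, m.base) for m in got] == [
            (m.coordinate.position, m.base) for m in via_records
        ]


class TestTaxonMatrix:
    def test_missing_cells_for_unanchored_groups(self):
        from polymaps.anchoring import AnchoredMarker

        markers = [
            AnchoredMarker(GenomeCoordinate("chr1", 10), "g1", "A", 3, 5),
            AnchoredMarker(GenomeCoordinate("chr1", 10), "g2", "C", 2, 5),
        ]
        m = build_taxon_matrix(
            markers, {"vesca": {10: "A"}}, "chr1",
            group_ids=[f"g{i}" for i in range(1, 9)],
        )
        col = m.cells[:, 0]
        assert (col == "?").sum() == 6  # six groups without qualifying reads

    def test_diploid_call_overrides_nothing_else(self):
        m = build_taxon_matrix([], {"vesca": {10: "G"}}, "chr1", group_ids=["g1"])
        assert m.row("vesca")[0] == "G"
        assert m.row("g1")[0] == "?"

    def test_chromosome_partition(self):
        from polymaps.anchoring import AnchoredMarker

        markers = [AnchoredMarker(GenomeCoordinate("chr3", 10), "g1", "A", 1, 2)]
        m = build_taxon_matrix(markers, {"vesca": {}}, "chr5", group_ids=["g1"])
        assert m.shape[1] == 0


# ---------------------------------------------------------------------------
# Neighbour joining against exhaustive topology scoring


def enumerate_topologies(taxa):
    """All unrooted binary topologies as nested tuples."""
    if len(taxa) == 3:
        return [tuple(taxa)]

    def insert(tree, leaf):
        # yield every tree obtainable by attaching leaf on an edge of tree
        if isinstance(tree, tuple):
            for i, sub in enumerate(tree):
                for new_sub in insert(sub, leaf):
                    yield tuple(new_sub if j == i else s for j, s in enumerate(tree))
        yield (tree, leaf)

    trees = [tuple(taxa[:3])]
    for leaf in taxa[3:]:
        nxt = []
        for t in trees:
            if isinstance(t, tuple) and len(t) == 3:
                # unrooted core: attach on each of the three edges or split
                for i in range(3):
                    for new_sub in insert(t[i], leaf):
                        nxt.append(tuple(new_sub if j == i else s for j, s in enumerate(t)))
            else:
                nxt.extend(insert(t, leaf))
        trees = nxt
    return trees


def splits_of(tree, all_taxa):
    """Non-trivial bipartitions of a nested-tuple unrooted tree."""
    out = set()

    def tips(t):
        if isinstance(t, tuple):
            s = frozenset()
            for sub in t:
                s |= tips(sub)
            return s
        return frozenset([t])

    def walk(t):
        if not isinstance(t, tuple):
            return
        for sub in t:
            s = tips(sub)
            if 1 < len(s) < len(all_taxa) - 1:
                out.add(min(s, frozenset(all_taxa) - s, key=sorted))
            walk(sub)

    walk(tree)
    return out


def ls_score(tree, taxa, d):
    """OLS branch-length fit of a topology to a distance matrix; returns SSE."""
    splits = list(splits_of(tree, taxa)) + [frozenset([t]) for t in taxa]
    pairs = list(itertools.combinations(range(len(taxa)), 2))
    X = np.zeros((len(pairs), len(splits)))
    y = np.array([d[i, j] for i, j in pairs])
    for r, (i, j) in enumerate(pairs):
        for c, s in enumerate(splits):
            if (taxa[i] in s) != (taxa[j] in s):
                X[r, c] = 1.0
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def additive_matrix_from_random_tree(taxa, rng):
    """Evolve binary characters with a distinct block per branch so p-distances
    are exactly additive; returns (TaxonMatrix, true splits)."""
    topos = enumerate_topologies(taxa)
    tree = topos[rng.integers(0, len(topos))]
    splits = list(splits_of(tree, taxa)) + [frozenset([t]) for t in taxa]
    lengths = rng.integers(2, 8, len(splits))
    total = int(lengths.sum())
    cells = np.full((len(taxa), total), "A", dtype="<U1")
    col = 0
    for s, ln in zip(splits, lengths):
        for _ in range(int(ln)):
            for ti, t in enumerate(taxa):
                if t in s:
                    cells[ti, col] = "C"
            col += 1
    sites = [GenomeCoordinate("c", i + 1) for i in range(total)]
    return TaxonMatrix(list(taxa), sites, cells), splits_of(tree, taxa), topos


@pytest.mark.parametrize("n_taxa", [4, 5, 6])
def test_nj_recovers_topology_vs_exhaustive_scoring(n_taxa):
    """On additive distances the NJ tree matches the least-squares-best
    topology found by exhaustive enumeration."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    rng = np.random.default_rng(40 + n_taxa)
    for _ in range(5):
        matrix, true_splits, topos = additive_matrix_from_random_tree(taxa, rng)
        d, _ = p_distance_matrix(matrix)
        scored = sorted(topos, key=lambda t: ls_score(t, taxa, d))
        assert splits_of(scored[0], taxa) == true_splits  # oracle sanity
        tree = nj_tree(matrix)
        nj_splits = set()
        for node in tree.traverse(include_self=False):
            tips = frozenset(t.name for t in node.tips()) or frozenset([node.name])
            if 1 < len(tips) < n_taxa - 1:
                nj_splits.add(min(tips, frozenset(taxa) - tips, key=sorted))
        assert nj_splits == true_splits


class TestNJDegenerate:
    def test_identical_rows_zero_branch(self):
        cells = np.array(
            [list("AAAA"), list("AAAA"), list("CCAA"), list("CCCC")], dtype="<U1"
        )
        m = TaxonMatrix(
            ["a", "b", "c", "d"],
            [GenomeCoordinate("c", i + 1) for i in range(4)],
            cells,
        )
        tree = nj_tree(m)
        ta, tb = tree.find("a"), tree.find("b")
        assert ta.parent is tb.parent
        assert (abs(ta.length or 0) + abs(tb.length or 0)) == pytest.approx(0, abs=1e-9)

    def test_fewer_than_three_taxa_rejected(self):
        m = TaxonMatrix(
            ["a", "b"], [GenomeCoordinate("c", 1)], np.array([["A"], ["C"]])
        )
        with pytest.raises(ValueError):
            nj_tree(m)

    def test_zero_shared_sites_flagged_with_max_distance(self):
        cells = np.array(
            [["A", "?", "A"], ["?", "C", "?"], ["A", "C", "C"]], dtype="<U1"
        )
        m = TaxonMatrix(
            ["a", "b", "c"], [GenomeCoordinate("c", i + 1) for i in range(3)], cells
        )
        d, shared = p_distance_matrix(m)
        assert shared[0, 1] == 0
        assert d[0, 1] == d.max()


class TestSubgenomeLabels:
    def _matrix_and_tree(self, tract_on=None):
        """Synthetic clean history: Av sister to vesca, Bi sister to iinumae,
        B1 most divergent from iinumae."""
        rng = np.random.default_rng(9)
        n = 20_000
        root = rng.integers(0, 4, n)

        def mutate(seq, rate):
            out = seq.copy()
            mask = rng.random(n) < rate
            out[mask] = (out[mask] + rng.integers(1, 4, mask.sum())) % 4
            return out

        vesca_anc = mutate(root, 0.02)
        b_anc = mutate(root, 0.015)
        ii_bi = mutate(b_anc, 0.004)
        seqs = {
            "outgroup": mutate(root, 0.06),
            "vesca": mutate(vesca_anc, 0.006),
            "Av-m": mutate(vesca_anc, 0.006),
            "iinumae": mutate(ii_bi, 0.004),
            "Bi-m": mutate(ii_bi, 0.004),
            "B1-m": mutate(b_anc, 0.014),
            "B2-m": mutate(b_anc, 0.005),
        }
        cells = np.array(
            [np.array(list("ACGT"))[seqs[t]] for t in sorted(seqs)], dtype="<U1"
        )
        taxa = sorted(seqs)
        m = TaxonMatrix(
            taxa, [GenomeCoordinate("c", i + 1) for i in range(n)], cells
        )
        return m

    def test_clean_labels(self):
        m = self._matrix_and_tree()
        tree = nj_tree(m)
        groups = {"Av-m": "m", "B1-m": "m", "B2-m": "m", "Bi-m": "m"}
        labels = assign_subgenome_labels(
            tree, m, groups, "vesca", "iinumae", ["outgroup"]
        )
        assert labels == {"Av-m": "Av", "B1-m": "B1", "B2-m": "B2", "Bi-m": "Bi"}

    def test_missing_av_still_resolves_b_side(self):
        m = self._matrix_and_tree()
        keep = [t for t in m.taxa if t != "Av-m"]
        idx = [m.taxa.index(t) for t in keep]
        m2 = TaxonMatrix(keep, m.sites, m.cells[idx])
        tree = nj_tree(m2)
        labels = assign_subgenome_labels(
            tree, m2, {"B1-m": "m", "B2-m": "m", "Bi-m": "m"},
            "vesca", "iinumae", ["outgroup"],
        )
        assert labels == {"B1-m": "B1", "B2-m": "B2", "Bi-m": "Bi"}
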