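"""End-to-end orchestration: calling -> maps -> anchoring -> scans -> report.

The staged functions operate on in-memory objects (blocks of reads, calls,
groups) so they can be driven either by the simulator or by parsed external
files; ``run_simulated_pipeline`` wires the whole chain for a synthetic
cross and is what the command-line ``run`` subcommand and the test bed use.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import anchoring, calling, introgression, linkage, rearrange
from .anchoring import AnchoredMarker
from .calling import (
    GenotypeState,
    LGSNP,
    ParentOfOrigin,
    SiteSelection,
    call_octoploid_genotype,
    group_regions,
    select_lg_snps,
)
from .formats_io import GenomeCoordinate, TargetRegion, TaxonMatrix, write_phylip_matrix
from .introgression import (
    IntrogressionCluster,
    RegionCall,
    RegionClass,
    SiteClass,
    classify_region,
    classify_site,
    cluster_geometry,
    detect_clusters,
    directionality_test,
    excess_homoplasy_test,
)
from .linkage import LinkageGroup, ROMAN, SUBGENOMES, build_linkage_groups, name_group
from .simulate import CaptureSimulator, SimulationConfig, simulate_cross, simulate_lineages

logger = logging.getLogger(__name__)

DIPLOID_TAXA = ("vesca", "iinumae", "outgroup")


# ---------------------------------------------------------------------------
# Stage 1: genotype calling from pileup evidence


def call_sites_from_counts(
    site_records: Iterable[tuple[GenomeCoordinate, np.ndarray]],
    n_progeny: int,
    min_depth: int = calling.MIN_DEPTH,
) -> SiteSelection:
    """Call parents and progeny at each site and apply the LG SNP filters.

    ``site_records`` yields (coordinate, counts) with counts shaped
    (2 + n_progeny [+ extras], 4) ordered mother, father, progeny...; extra
    trailing samples (e.g. a diploid reference) are ignored.
    """
    sites = []
    for coord, counts in site_records:
        mat = call_octoploid_genotype(dict(zip("ACGT", counts[0])), min_depth)
        pat = call_octoploid_genotype(dict(zip("ACGT", counts[1])), min_depth)
        if (
            mat.state is not GenotypeState.HET
            and pat.state is not GenotypeState.HET
        ):
            continue
        progeny = [
            call_octoploid_genotype(dict(zip("ACGT", counts[2 + i])), min_depth)
            for i in range(n_progeny)
        ]
        sites.append((coord, mat, pat, progeny))
    return select_lg_snps(sites)


def assign_regions(selection: SiteSelection, gap: int = 1000) -> None:
    """Assign shared 1-kb region ids (per chromosome) to retained LG SNPs."""
    by_chrom: dict[str, list[LGSNP]] = {}
    for snp in selection.lg_snps:
        by_chrom.setdefault(snp.coordinate.chromosome, []).append(snp)
    next_id = 0
    for chrom in sorted(by_chrom):
        snps = sorted(by_chrom[chrom], key=lambda s: s.coordinate.position)
        regions = group_regions(
            [s.coordinate.position for s in snps], chrom, gap, start_id=next_id
        )
        next_id += len(regions)
        k = 0
        for region in regions:
            for _ in region.positions:
                snps[k].region_id = region.region_id
                k += 1


# ---------------------------------------------------------------------------
# Stage 3/4: anchored markers, matrices, labels


@dataclass
class ChromosomeAnalysis:
    chromosome: str
    groups: list[LinkageGroup]
    markers: list[AnchoredMarker]
    matrix: TaxonMatrix | None = None
    tree: object | None = None
    labels: dict[str, str] = field(default_factory=dict)


def label_chromosome(
    chromosome: str,
    groups: Sequence[LinkageGroup],
    markers: Sequence[AnchoredMarker],
    diploid_calls: Mapping[str, Mapping[int, str]],
) -> ChromosomeAnalysis:
    """Build the taxon matrix for one chromosome, estimate the NJ tree and
    assign subgenome labels to its linkage groups."""
    analysis = ChromosomeAnalysis(chromosome, list(groups), list(markers))
    group_ids = [g.group_id for g in groups]
    matrix = anchoring.build_taxon_matrix(
        markers, diploid_calls, chromosome, group_ids=group_ids
    )
    analysis.matrix = matrix
    have_data = [
        gid for gid in group_ids if (matrix.row(gid) != "?").sum() > 0
    ]
    if len(have_data) + len(DIPLOID_TAXA) < 4:
        for g in groups:
            g.subgenome_label = "unresolved"
        return analysis
    tree = anchoring.nj_tree(matrix)
    analysis.tree = tree
    labels = anchoring.assign_subgenome_labels(
        tree,
        matrix,
        {g.group_id: g.parent for g in groups},
        vesca_taxon="vesca",
        iinumae_taxon="iinumae",
        outgroup_taxa=["outgroup"],
    )
    analysis.labels = labels
    for g in groups:
        g.subgenome_label = labels.get(g.group_id, "unresolved")
    return analysis


# ---------------------------------------------------------------------------
# Stage 5: introgression scan


@dataclass
class IntrogressionScan:
    region_calls: list[RegionCall]
    clusters: list[IntrogressionCluster]
    geometry: object
    n_introgression_like_regions: int
    n_outgroup_regions: int
    excess: tuple | None
    directionality: tuple | None


def scan_introgression(
    markers_by_chromosome: Mapping[str, Sequence[AnchoredMarker]],
    labels_by_group: Mapping[str, str],
    parents_by_group: Mapping[str, str],
    diploid_calls_by_chromosome: Mapping[str, Mapping[str, Mapping[int, str]]],
    gap: int = 1000,
) -> IntrogressionScan:
    """Classify informative sites and 1-kb regions per subgenome, then call
    clusters and run the excess/directionality tests."""
    region_calls: list[RegionCall] = []
    clusters: list[IntrogressionCluster] = []
    next_region = 0
    for chrom in sorted(markers_by_chromosome):
        calls = diploid_calls_by_chromosome[chrom]
        per_sub: dict[str, list[tuple[int, str, SiteClass]]] = {}
        for m in markers_by_chromosome[chrom]:
            label = labels_by_group.get(m.linkage_group_id)
            if label not in SUBGENOMES:
                continue
            pos = m.coordinate.position
            v = calls["vesca"].get(pos)
            i = calls["iinumae"].get(pos)
            o = calls["outgroup"].get(pos)
            if None in (v, i, o):
                continue
            sister = "vesca" if label == "Av" else "iinumae"
            sc = classify_site(m.base, v, i, o, sister)
            if sc is SiteClass.UNINFORMATIVE:
                continue
            per_sub.setdefault(label, []).append(
                (pos, parents_by_group[m.linkage_group_id], sc)
            )
        for label in sorted(per_sub):
            rows = sorted(per_sub[label])
            regions = group_regions([p for p, _, _ in rows], chrom, gap, next_region)
            next_region += len(regions)
            k = 0
            sub_calls: list[RegionCall] = []
            for region in regions:
                chunk = rows[k : k + len(region.positions)]
                k += len(region.positions)
                by_map: dict[str, list[SiteClass]] = {}
                for pos, pmap, sc in chunk:
                    by_map.setdefault(pmap, []).append(sc)
                klass = classify_region(by_map)
                if klass is None:
                    continue
                sub_calls.append(
                    RegionCall(
                        region.region_id,
                        chrom,
                        label,
                        klass,
                        frozenset(by_map),
                        first_site=chunk[0][0],
                        last_site=chunk[-1][0],
                        n_sites=len(chunk),
                    )
                )
            region_calls.extend(sub_calls)
            clusters.extend(detect_clusters(sub_calls))
    n_intro = sum(
        1 for rc in region_calls if rc.klass is RegionClass.INTROGRESSION_LIKE
    )
    n_out = sum(1 for rc in region_calls if rc.klass is RegionClass.OUTGROUP)
    excess = (
        excess_homoplasy_test(n_intro, n_out) if (n_intro or n_out) else None
    )
    toward_vesca = sum(1 for c in clusters if c.subgenome != "Av")
    toward_iinumae = sum(1 for c in clusters if c.subgenome == "Av")
    directionality = (
        directionality_test(toward_vesca, toward_iinumae)
        if toward_vesca + toward_iinumae
        else None
    )
    return IntrogressionScan(
        region_calls,
        clusters,
        cluster_geometry(clusters),
        n_intro,
        n_out,
        excess,
        directionality,
    )


# ---------------------------------------------------------------------------
# Table-1-style report


def make_table1(
    region_calls: Sequence[RegionCall],
    clusters: Sequence[IntrogressionCluster],
    chromosomes: Sequence[str] | None = None,
    informative_regions_per_chromosome: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-subgenome x per-chromosome region-classification table.

    Rows: supportive, clustered/isolated introgression-like (with cluster
    counts), outgroup homoplasy, support/homoplasy, plus an all-subgenome
    informative-region row.  Row and column totals are included.
    """
    if chromosomes is None:
        chromosomes = sorted({rc.chromosome for rc in region_calls})
    clustered_ids: set[tuple[str, str, int]] = set()
    for c in clusters:
        for rc in region_calls:
            if (
                rc.subgenome == c.subgenome
                and rc.chromosome == c.chromosome
                and rc.klass is RegionClass.INTROGRESSION_LIKE
                and c.first_site <= rc.first_site
                and rc.last_site <= c.last_site
            ):
                clustered_ids.add((rc.chromosome, rc.subgenome, rc.region_id))
    rows = []
    signals = [
        ("supportive", RegionClass.SUPPORTIVE),
        ("clustered_introgression_like", None),
        ("clusters", None),
        ("isolated_introgression_like", None),
        ("outgroup_homoplasy", RegionClass.OUTGROUP),
        ("support_homoplasy", RegionClass.SUPPORT_HOMOPLASY),
    ]
    for signal, klass in signals:
        for sub in SUBGENOMES:
            row: dict[str, object] = {"signal": signal, "subgenome": sub}
            total = 0
            for chrom in chromosomes:
                if signal == "clusters":
                    n = sum(
                        1
                        for c in clusters
                        if c.subgenome == sub and c.chromosome == chrom
                    )
                elif signal == "clustered_introgression_like":
                    n = sum(
                        1
                        for rc in region_calls
                        if rc.subgenome == sub
                        and rc.chromosome == chrom
                        and (rc.chromosome, rc.subgenome, rc.region_id) in clustered_ids
                    )
                elif signal == "isolated_introgression_like":
                    n = sum(
                        1
                        for rc in region_calls
                        if rc.subgenome == sub
                        and rc.chromosome == chrom
                        and rc.klass is RegionClass.INTROGRESSION_LIKE
                        and (rc.chromosome, rc.subgenome, rc.region_id)
                        not in clustered_ids
                    )
                else:
                    n = sum(
                        1
                        for rc in region_calls
                        if rc.subgenome == sub
                        and rc.chromosome == chrom
                        and rc.klass is klass
                    )
                row[chrom] = n
                total += n
            row["Total"] = total
            rows.append(row)
    if informative_regions_per_chromosome is not None:
        row = {"signal": "informative_regions", "subgenome": "All"}
        row.update(informative_regions_per_chromosome)
        row["Total"] = sum(informative_regions_per_chromosome.values())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full simulated run


@dataclass
class PipelineResult:
    config: SimulationConfig
    selection: SiteSelection
    groups: list[LinkageGroup]
    major_groups: list[LinkageGroup]
    analyses: dict[str, ChromosomeAnalysis]
    markers_by_chromosome: dict[str, list[AnchoredMarker]]
    scan: IntrogressionScan
    table1: pd.DataFrame
    rearrangement_events: list
    restricted_events: list
    permutation: rearrange.PermutationResult | None
    depth_ratio: np.ndarray
    depth_comparison: dict | None
    pairing: list[tuple[str, str]]
    simulator: CaptureSimulator

    def group_names(self, species_code: str = "Fsim") -> dict[str, str]:
        names = {}
        for g in self.major_groups:
            if g.subgenome_label in SUBGENOMES and g.primary_chromosome:
                ci = int(g.primary_chromosome.replace("chr", "")) - 1
                names[g.group_id] = name_group(
                    species_code, ROMAN[ci], g.subgenome_label, g.parent
                )
        return names


def run_simulated_pipeline(config: SimulationConfig) -> PipelineResult:
    lineages = simulate_lineages(config)
    cross = simulate_cross(lineages, config)
    sim = CaptureSimulator(cross)
    n_prog = config.n_progeny

    # pass 1: genotype calling + central depths
    site_records = []
    central_depths = np.zeros(
        (len(sim.sample_names), config.n_chromosomes, config.targets_per_chromosome)
    )
    for block in sim.blocks():
        counts = block.counts()
        chrom = sim.chromosome_name(block.chromosome)
        central_depths[:, block.chromosome, block.target_index] = block.central_depth
        for j, site in enumerate(block.sites):
            site_records.append(
                (GenomeCoordinate(chrom, int(site)), counts[:, j, :])
            )
    selection = call_sites_from_counts(site_records, n_prog)
    assign_regions(selection)
    del site_records

    # pass 2: linkage groups
    maternal = [s for s in selection.lg_snps if s.parent_of_origin is ParentOfOrigin.MATERNAL]
    paternal = [s for s in selection.lg_snps if s.parent_of_origin is ParentOfOrigin.PATERNAL]
    groups = build_linkage_groups(maternal, "m") + build_linkage_groups(paternal, "p")
    major = [g for g in groups if g.is_major]

    # pass 3: anchored markers per chromosome
    spacing = config.chromosome_length // config.targets_per_chromosome
    markers_by_chromosome: dict[str, list[AnchoredMarker]] = {}
    diploid_by_chromosome: dict[str, dict[str, dict[int, str]]] = {}
    snp_positions_by_chrom: dict[str, set[int]] = {}
    for snp in selection.lg_snps:
        snp_positions_by_chrom.setdefault(snp.coordinate.chromosome, set()).add(
            snp.coordinate.position
        )
    anchors_by_target: dict[tuple[int, int], list[tuple[int, str, str]]] = {}
    for g in major:
        for snp in g.snps:
            chrom = snp.coordinate.chromosome
            ci = int(chrom.replace("chr", "")) - 1
            t = snp.coordinate.position // spacing
            if 0 <= t < config.targets_per_chromosome:
                anchors_by_target.setdefault((ci, t), []).append(
                    (snp.coordinate.position, snp.minor_allele, g.group_id)
                )
    for ci in range(config.n_chromosomes):
        chrom = sim.chromosome_name(ci)
        markers: list[AnchoredMarker] = []
        excluded = frozenset(snp_positions_by_chrom.get(chrom, set()))
        for t in range(config.targets_per_chromosome):
            anchors = anchors_by_target.get((ci, t))
            if not anchors:
                continue
            block = sim.block(ci, t)
            rb = block.read_block(chrom, sim.octoploid_samples)
            markers.extend(anchoring.anchor_block(rb, anchors, excluded))
        markers_by_chromosome[chrom] = markers
        diploid_by_chromosome[chrom] = sim.diploid_calls(ci)

    # pass 4: per-chromosome matrices, trees, labels
    analyses: dict[str, ChromosomeAnalysis] = {}
    for ci in range(config.n_chromosomes):
        chrom = sim.chromosome_name(ci)
        chrom_groups = [g for g in major if g.primary_chromosome == chrom]
        analyses[chrom] = label_chromosome(
            chrom,
            chrom_groups,
            markers_by_chromosome[chrom],
            diploid_by_chromosome[chrom],
        )

    labels = {g.group_id: g.subgenome_label for g in major}
    parents = {g.group_id: g.parent for g in major}

    # pass 5: introgression scan + report table
    scan = scan_introgression(
        markers_by_chromosome, labels, parents, diploid_by_chromosome
    )
    informative = _informative_regions_per_chromosome(scan.region_calls)
    table1 = make_table1(
        scan.region_calls,
        scan.clusters,
        chromosomes=[sim.chromosome_name(ci) for ci in range(config.n_chromosomes)],
        informative_regions_per_chromosome=informative,
    )

    # pass 6: rearrangement scan
    targets = sim.target_regions()
    snps_with_groups = [
        (snp, g.group_id, g.primary_chromosome)
        for g in major
        for snp in g.snps
    ]
    events, restricted = rearrange.detect_rearrangements(snps_with_groups, targets)
    occupied = _regions_with_lg_snps(selection.lg_snps, targets)
    permutation = None
    if restricted:
        permutation = rearrange.permutation_clustering_test(
            len(restricted), max(len(occupied), 1), reps=1000, seed=config.seed
        )
    depths = {
        name: central_depths[i].ravel()
        for i, name in enumerate(sim.sample_names)
        if name in ("mother", "father", "vesca_ref")
    }
    _, ratio = rearrange.normalize_depth(depths, ["mother", "father"], "vesca_ref")
    comparison = None
    rearranged_keys = {
        (e.nearest_target.chromosome, e.nearest_target.central_site.position)
        for e in restricted
    }
    flat_keys = [
        (t.chromosome, t.central_site.position) for t in targets
    ]
    in_mask = np.array([k in rearranged_keys for k in flat_keys])
    valid = ~np.isnan(ratio)
    if in_mask.sum() >= 2 and ((~in_mask) & valid).sum() >= 2:
        comparison = rearrange.compare_ratio_distributions(
            ratio[in_mask & valid], ratio[~in_mask & valid]
        )

    pairing = _pair_groups(selection.biparental, major, targets)

    return PipelineResult(
        config, selection, groups, major, analyses, markers_by_chromosome,
        scan, table1, events, restricted, permutation, ratio, comparison,
        pairing, sim,
    )


def _informative_regions_per_chromosome(
    region_calls: Sequence[RegionCall],
) -> dict[str, int]:
    """Distinct 1-kb genomic regions with informative markers, pooling
    subgenomes (overlapping per-subgenome regions merge)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for rc in region_calls:
        by_chrom.setdefault(rc.chromosome, []).append((rc.first_site, rc.last_site))
    out = {}
    for chrom, ivs in by_chrom.items():
        merged: list[list[int]] = []
        for a, b in sorted(ivs):
            if merged and a - merged[-1][1] < 1000:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        out[chrom] = len(merged)
    return out


def _regions_with_lg_snps(
    lg_snps: Sequence[LGSNP], targets: Sequence[TargetRegion]
) -> set[tuple[str, int]]:
    by_chrom: dict[str, list[TargetRegion]] = {}
    for t in targets:
        by_chrom.setdefault(t.chromosome, []).append(t)
    starts = {
        chrom: [t.start for t in sorted(ts, key=lambda t: t.start)]
        for chrom, ts in by_chrom.items()
    }
    sorted_ts = {
        chrom: sorted(ts, key=lambda t: t.start) for chrom, ts in by_chrom.items()
    }
    occupied: set[tuple[str, int]] = set()
    for snp in lg_snps:
        chrom = snp.coordinate.chromosome
        if chrom not in starts:
            continue
        i = bisect.bisect_right(starts[chrom], snp.coordinate.position) - 1
        if i >= 0:
            t = sorted_ts[chrom][i]
            if t.start <= snp.coordinate.position <= t.end:
                occupied.add((chrom, t.central_site.position))
    return occupied


def _pair_groups(
    biparental: Sequence[LGSNP],
    major: Sequence[LinkageGroup],
    targets: Sequence[TargetRegion],
    min_agreement: float = 0.65,
) -> list[tuple[str, str]]:
    """Weight maternal/paternal group pairs through biparental SNPs.

    A biparental SNP's homozygous progeny inherited neither parent's minor
    haplotype, so its HOM indicator co-segregates (in one phase or the
    other) with the true linkage group of *both* parents at that locus.
    For each biparental SNP the nearby candidate group with the strongest
    phase-maximised agreement (>= ``min_agreement``) is picked per parent
    and the winning (maternal, paternal) pair gets one vote; votes feed a
    maximum-weight bipartite matching.
    """
    snp_group: dict[tuple[str, int], list[tuple[int, str, LGSNP]]] = {}
    for g in major:
        for snp in g.snps:
            key = (snp.coordinate.chromosome, snp.coordinate.position // 1000)
            snp_group.setdefault(key, []).append(
                (snp.coordinate.position, g.group_id, snp)
            )
    parent_of = {g.group_id: g.parent for g in major}
    weights: dict[tuple[str, str], int] = {}
    for bsnp in biparental:
        chrom = bsnp.coordinate.chromosome
        kb = bsnp.coordinate.position // 1000
        hom = np.array(
            [c.state is GenotypeState.HOM for c in bsnp.progeny_calls], dtype=bool
        )
        valid_b = np.array(
            [c.state is not GenotypeState.MISSING for c in bsnp.progeny_calls],
            dtype=bool,
        )
        best: dict[str, tuple[float, str]] = {}
        for d in (-1, 0, 1):
            for pos, gid, gsnp in snp_group.get((chrom, kb + d), []):
                states, missing = gsnp.segregation()
                het = np.asarray(states, dtype=bool)
                ok = valid_b & ~np.asarray(missing, dtype=bool)
                n = int(ok.sum())
                if n == 0:
                    continue
                match = int((hom[ok] == het[ok]).sum())
                agreement = max(match, n - match) / n
                parent = parent_of[gid]
                if agreement >= min_agreement and (
                    parent not in best or agreement > best[parent][0]
                ):
                    best[parent] = (agreement, gid)
        if "m" in best and "p" in best:
            key = (best["m"][1], best["p"][1])
            weights[key] = weights.get(key, 0) + 1
    return linkage.pair_parental_groups(weights)


# ---------------------------------------------------------------------------
# Artifact writers


def write_lg_snp_table(selection: SiteSelection, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tparent\tminor_allele\tregion_id\tprogeny\n")
        for snp in selection.lg_snps:
            states, missing = snp.segregation()
            prog = "".join(
                "-" if m else str(s) for s, m in zip(states, missing)
            )
            fh.write(
                f"{snp.coordinate.chromosome}\t{snp.coordinate.position}\t"
                f"{snp.parent_of_origin.value}\t{snp.minor_allele}\t"
                f"{snp.region_id}\t{prog}\n"
            )


def write_map_table(groups: Sequence[LinkageGroup], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("group\tparent\tprimary_chrom\tsubgenome\tchrom\tpos\tcM\n")
        for g in groups:
            for snp, cm in zip(g.snps, g.cm_positions):
                fh.write(
                    f"{g.group_id}\t{g.parent}\t{g.primary_chromosome}\t"
                    f"{g.subgenome_label or 'NA'}\t{snp.coordinate.chromosome}\t"
                    f"{snp.coordinate.position}\t{cm:.3f}\n"
                )


def write_cluster_bed(clusters: Sequence[IntrogressionCluster], path: Path) -> None:
    with open(path, "w") as fh:
        for c in sorted(clusters, key=lambda c: (c.chromosome, c.first_site)):
            fh.write(
                f"{c.chromosome}\t{c.first_site - 1}\t{c.last_site}\t"
                f"{c.subgenome};regions={c.region_count};maps={','.join(sorted(c.maps))}\n"
            )


def write_report(result: PipelineResult, outdir: Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    p = outdir / "lg_snps.tsv"
    write_lg_snp_table(result.selection, p)
    paths.append(p)
    p = outdir / "map.tsv"
    write_map_table(result.major_groups, p)
    paths.append(p)
    p = outdir / "table1.tsv"
    result.table1.to_csv(p, sep="\t", index=False)
    paths.append(p)
    p = outdir / "clusters.bed"
    write_cluster_bed(result.scan.clusters, p)
    paths.append(p)
    for chrom, analysis in sorted(result.analyses.items()):
        if analysis.matrix is not None and analysis.matrix.shape[1] > 0:
            p = outdir / f"matrix_{chrom}.phy"
            write_phylip_matrix(analysis.matrix, p)
            paths.append(p)
    p = outdir / "rearrangements.tsv"
    with open(p, "w") as fh:
        fh.write("chrom\tpos\tgroup\tgroup_chrom\tdistance_to_target\n")
        for e in result.restricted_events:
            fh.write(
                f"{e.snp_chromosome}\t{e.snp_position}\t{e.linkage_group_id}\t"
                f"{e.group_primary_chromosome}\t{e.distance_to_target}\n"
            )
    paths.append(p)
    return paths
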