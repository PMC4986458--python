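"""Synthetic allo-octoploid cross with targeted-capture sequencing.

The generator embodies a fixed subgenome history: an ancestor splits into a
F. vesca-like lineage (giving the vesca-like diploid taxon and subgenome Av)
and a F. iinumae-like lineage, whose radiation yields subgenomes B1 and B2
and a clade containing the iinumae-like diploid taxon and subgenome Bi; a
distant outgroup taxon hangs off the root.  Substitutions are placed
independently along each branch with equal rates across bases (a
Jukes-Cantor-like model; downstream logic only uses base-identity
partitions).

Introgression is modelled as wholesale tract replacement: inside a planted
tract the recipient subgenome's sequence is replaced by the vesca-lineage
ancestral sequence (or, for the reverse direction, by the iinumae-lineage
ancestral sequence).  Transpositions are copy-and-paste: a capture-target
window of one subgenome is duplicated onto an acceptor chromosome of a
carrier haplotype, inflating depth at the donor window and planting a marker
there that segregates with the acceptor chromosome.

Two octoploid parents are crossed disomically: each progeny inherits, per
parent per subgenome, one recombinant haplotype (Poisson crossovers at
uniform positions), with no exchange between subgenomes.  Capture reads are
drawn per target with every read covering the target's central site, so the
``depth`` parameter is the expected per-individual coverage at the centre.
A diploid vesca-like reference individual is sequenced alongside the cross
for depth normalisation.

Single-subgenome heterozygous sites are planted at fixed small offsets from
each target centre (one offset per parent x subgenome combination), so every
target yields candidate LG SNPs for all eight parental maps; biparental
sites are planted on every fourth target.  Everything is deterministic
given ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterator, Sequence

import numpy as np

from .anchoring import ReadBlock
from .formats_io import BASES, GenomeCoordinate, TargetRegion, format_pileup_column

SUBGENOME_ORDER = ("Av", "B1", "B2", "Bi")
# planted-het offsets from the target centre, one per (parent, subgenome)
HET_OFFSETS = {"m": (-20, -14, -8, -2), "p": (4, 10, 16, 22)}
BIPARENTAL_OFFSET = -26
TRANSPOSITION_OFFSET = 28
WINDOW_PAD = 150


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 7
    chromosome_length: int = 1_000_000
    targets_per_chromosome: int = 300
    n_progeny: int = 48
    depth: float = 80.0
    error_rate: float = 0.002           # per base per read
    read_length: int = 100
    recomb_per_chromosome: float = 1.0  # mean crossovers per gamete
    # branch substitution probabilities (per site)
    rate_outgroup: float = 0.06
    rate_vesca_stem: float = 0.02
    rate_vesca: float = 0.006
    rate_av: float = 0.006
    rate_iinumae_stem: float = 0.015
    rate_b1: float = 0.010
    rate_b2: float = 0.006
    rate_ii_bi_stem: float = 0.004
    rate_iinumae: float = 0.004
    rate_bi: float = 0.004
    rate_parental: float = 0.0005       # parent-private homozygous variation
    # planted structural truth
    n_tracts: int = 6
    tract_length: int = 60_000
    tract_direction: str = "b_to_vesca"  # or "bidirectional"
    n_transpositions: int = 4

    def __post_init__(self) -> None:
        rates = [
            self.rate_outgroup, self.rate_vesca_stem, self.rate_vesca,
            self.rate_av, self.rate_iinumae_stem, self.rate_b1, self.rate_b2,
            self.rate_ii_bi_stem, self.rate_iinumae, self.rate_bi,
            self.rate_parental,
        ]
        if any(not (0 <= r < 0.5) for r in rates):
            raise ValueError("branch rates must lie in [0, 0.5)")
        if self.tract_direction not in ("b_to_vesca", "bidirectional"):
            raise ValueError("tract_direction must be b_to_vesca or bidirectional")


@dataclass(frozen=True)
class Tract:
    chromosome: int       # 0-based chromosome index
    start: int            # 1-based closed interval
    end: int
    subgenome: str
    direction: str        # "to_vesca" (B subgenome vescafied) or "to_iinumae"


@dataclass(frozen=True)
class Transposition:
    donor_chromosome: int
    donor_target: int     # target index on donor chromosome
    acceptor_chromosome: int
    subgenome: str
    parent: str           # 'm' or 'p'
    zygosity: str         # "segregating" (one parental haplotype) or "fixed"
    marker_position: int  # reference position of the planted copy marker


@dataclass(frozen=True)
class PlantedSNP:
    chromosome: int
    position: int
    parent: str           # 'm', 'p' or 'both'
    subgenome: str
    minor_base: str


@dataclass
class Lineages:
    config: SimulationConfig
    centers: list[np.ndarray]            # per chromosome, target centres
    positions: list[np.ndarray]          # per chromosome, window positions
    sequences: dict[str, list[np.ndarray]]  # taxon -> per-chromosome codes
    tracts: list[Tract]

    def base_at(self, taxon: str, chromosome: int, position: int) -> str:
        pos = self.positions[chromosome]
        i = int(np.searchsorted(pos, position))
        if i >= len(pos) or pos[i] != position:
            raise KeyError(f"position {position} outside simulated windows")
        return BASES[self.sequences[taxon][chromosome][i]]


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    if rate > 0:
        mask = rng.random(seq.shape) < rate
        out[mask] = (out[mask] + rng.integers(1, 4, int(mask.sum()))) % 4
    return out


def simulate_lineages(config: SimulationConfig) -> Lineages:
    """Generate taxon/subgenome sequences over all capture-target windows."""
    rng = np.random.default_rng([config.seed, 1])
    spacing = config.chromosome_length // config.targets_per_chromosome
    if spacing <= 2 * WINDOW_PAD:
        raise ValueError("targets too dense for non-overlapping windows")
    centers, positions = [], []
    for _ in range(config.n_chromosomes):
        c = np.arange(config.targets_per_chromosome) * spacing + spacing // 2
        centers.append(c)
        positions.append(
            (c[:, None] + np.arange(-WINDOW_PAD, WINDOW_PAD + 1)[None, :]).ravel()
        )
    tracts = _plan_tracts(config, rng)
    sequences: dict[str, list[np.ndarray]] = {
        k: [] for k in (
            "ancestor", "outgroup", "vesca_ancestor", "vesca", "Av",
            "iinumae_ancestor", "B1", "B2", "ii_bi_ancestor", "iinumae", "Bi",
        )
    }
    for ci in range(config.n_chromosomes):
        n = len(positions[ci])
        root = rng.integers(0, 4, n).astype(np.uint8)
        vesca_anc = _mutate(root, config.rate_vesca_stem, rng)
        b_anc = _mutate(root, config.rate_iinumae_stem, rng)
        ii_bi = _mutate(b_anc, config.rate_ii_bi_stem, rng)
        seqs = {
            "ancestor": root,
            "outgroup": _mutate(root, config.rate_outgroup, rng),
            "vesca_ancestor": vesca_anc,
            "vesca": _mutate(vesca_anc, config.rate_vesca, rng),
            "Av": _mutate(vesca_anc, config.rate_av, rng),
            "iinumae_ancestor": b_anc,
            "B1": _mutate(b_anc, config.rate_b1, rng),
            "B2": _mutate(b_anc, config.rate_b2, rng),
            "ii_bi_ancestor": ii_bi,
            "iinumae": _mutate(ii_bi, config.rate_iinumae, rng),
            "Bi": _mutate(ii_bi, config.rate_bi, rng),
        }
        for t in tracts:
            if t.chromosome != ci:
                continue
            inside = (positions[ci] >= t.start) & (positions[ci] <= t.end)
            source = "vesca_ancestor" if t.direction == "to_vesca" else "iinumae_ancestor"
            seqs[t.subgenome][inside] = seqs[source][inside]
        for k, v in seqs.items():
            sequences[k].append(v)
    return Lineages(config, centers, positions, sequences, tracts)


def _plan_tracts(config: SimulationConfig, rng: np.random.Generator) -> list[Tract]:
    tracts: list[Tract] = []
    b_subs = ("B1", "B2", "Bi")
    for k in range(config.n_tracts):
        ci = k % config.n_chromosomes
        if config.tract_direction == "bidirectional" and k % 4 == 3:
            sub, direction = "Av", "to_iinumae"
        else:
            sub, direction = b_subs[k % 3], "to_vesca"
        lo = WINDOW_PAD + 1
        hi = config.chromosome_length - config.tract_length - WINDOW_PAD - 1
        start = int(rng.integers(lo, max(hi, lo + 1)))
        tracts.append(Tract(ci, start, start + config.tract_length, sub, direction))
    return tracts


# ---------------------------------------------------------------------------


@dataclass
class Gamete:
    """One recombinant haplotype choice along a chromosome."""

    start_hap: int
    breakpoints: np.ndarray

    def hap_at(self, position) -> np.ndarray:
        k = np.searchsorted(self.breakpoints, position, side="right")
        return (self.start_hap + k) % 2


@dataclass
class Cross:
    config: SimulationConfig
    lineages: Lineages
    # parental haplotypes: (parent, subgenome, hap) -> per-chromosome codes
    haplotypes: dict[tuple[str, str, int], list[np.ndarray]]
    planted: list[PlantedSNP]
    biparental: list[PlantedSNP]
    transpositions: list[Transposition]
    # gametes[(progeny, parent, subgenome)][chromosome]
    gametes: dict[tuple[int, str, str], list[Gamete]]

    @property
    def expected_labels(self) -> dict[str, str]:
        return {s: s for s in SUBGENOME_ORDER}


def simulate_cross(lineages: Lineages, config: SimulationConfig | None = None) -> Cross:
    """Build phased parents (with planted heterozygosity and transpositions)
    and disomic recombinant gametes for every progeny."""
    config = config or lineages.config
    rng = np.random.default_rng([config.seed, 2])
    haplotypes: dict[tuple[str, str, int], list[np.ndarray]] = {}
    for parent in ("m", "p"):
        for sub in SUBGENOME_ORDER:
            per_parent = [
                _mutate(seq, config.rate_parental, rng)
                for seq in lineages.sequences[sub]
            ]
            haplotypes[(parent, sub, 0)] = [s.copy() for s in per_parent]
            haplotypes[(parent, sub, 1)] = [s.copy() for s in per_parent]

    planted: list[PlantedSNP] = []
    biparental: list[PlantedSNP] = []
    for ci in range(config.n_chromosomes):
        pos = lineages.positions[ci]
        for t, center in enumerate(lineages.centers[ci]):
            for parent in ("m", "p"):
                for si, sub in enumerate(SUBGENOME_ORDER):
                    p = int(center) + HET_OFFSETS[parent][si]
                    idx = int(np.searchsorted(pos, p))
                    hap = (t + si) % 2
                    arr = haplotypes[(parent, sub, hap)][ci]
                    minor = (int(arr[idx]) + 1 + (t + si) % 3) % 4
                    arr[idx] = minor
                    planted.append(PlantedSNP(ci, p, parent, sub, BASES[minor]))
            if t % 4 == 2:
                sub = SUBGENOME_ORDER[(t // 4) % 4]
                p = int(center) + BIPARENTAL_OFFSET
                idx = int(np.searchsorted(pos, p))
                cur = int(haplotypes[("m", sub, 0)][ci][idx])
                minor = (cur + 1) % 4
                for par in ("m", "p"):
                    haplotypes[(par, sub, 0)][ci][idx] = minor
                biparental.append(PlantedSNP(ci, p, "both", sub, BASES[minor]))

    transpositions = _plan_transpositions(lineages, config, rng, haplotypes)
    gametes: dict[tuple[int, str, str], list[Gamete]] = {}
    for prog in range(config.n_progeny):
        for parent in ("m", "p"):
            for sub in SUBGENOME_ORDER:
                per_chrom = []
                for ci in range(config.n_chromosomes):
                    n_x = rng.poisson(config.recomb_per_chromosome)
                    breaks = np.sort(
                        rng.integers(1, config.chromosome_length + 1, n_x)
                    )
                    per_chrom.append(Gamete(int(rng.integers(0, 2)), breaks))
                gametes[(prog, parent, sub)] = per_chrom
    return Cross(
        config, lineages, haplotypes, planted, biparental, transpositions, gametes
    )


def _plan_transpositions(
    lineages: Lineages,
    config: SimulationConfig,
    rng: np.random.Generator,
    haplotypes: dict[tuple[str, str, int], list[np.ndarray]],
) -> list[Transposition]:
    events = []
    n_chrom = config.n_chromosomes
    if n_chrom < 2:
        return []
    for e in range(config.n_transpositions):
        donor = int(rng.integers(0, n_chrom))
        acceptor = int((donor + 1 + rng.integers(0, n_chrom - 1)) % n_chrom)
        target = int(rng.integers(0, config.targets_per_chromosome))
        sub = SUBGENOME_ORDER[int(rng.integers(0, 4))]
        parent = "m" if e % 2 == 0 else "p"
        center = int(lineages.centers[donor][target])
        marker = _invariant_marker_site(lineages, haplotypes, donor, center)
        events.append(
            Transposition(donor, target, acceptor, sub, parent, "segregating", marker)
        )
    return events


def _invariant_marker_site(
    lineages: Lineages,
    haplotypes: dict[tuple[str, str, int], list[np.ndarray]],
    chromosome: int,
    center: int,
) -> int:
    """Pick a copy-marker position near the target centre that is invariant
    across all parental haplotypes, so the planted copy mutation is the only
    variant there and segregates with the acceptor chromosome alone."""
    pos = lineages.positions[chromosome]
    for offset in range(TRANSPOSITION_OFFSET, TRANSPOSITION_OFFSET + 10):
        p = center + offset
        idx = int(np.searchsorted(pos, p))
        column = {int(arr[chromosome][idx]) for arr in haplotypes.values()}
        if len(column) == 1:
            return p
    return center + TRANSPOSITION_OFFSET


# ---------------------------------------------------------------------------


@dataclass
class TargetBlock:
    """All simulated sequencing evidence at one capture target."""

    chromosome: int
    target_index: int
    center: int
    sites: np.ndarray          # variant positions (global, sorted)
    reference: np.ndarray      # vesca-like reference base codes at sites
    sample_names: list[str]
    starts: np.ndarray         # per read
    samples: np.ndarray        # per read, index into sample_names
    bases: np.ndarray          # (n_reads, n_sites) uint8 codes incl. errors
    central_depth: np.ndarray  # per sample
    read_length: int = 100

    def read_block(self, chromosome_name: str, sample_subset: Sequence[int]) -> ReadBlock:
        keep = np.isin(self.samples, np.asarray(sample_subset))
        return ReadBlock(
            chromosome_name,
            self.sites.astype(np.int64),
            self.starts[keep].astype(np.int64),
            self.bases[keep],
            read_length=self.read_length,
        )

    def counts(self) -> np.ndarray:
        """(n_samples, n_sites, 4) coverage-resolved base counts."""
        n_samples = len(self.sample_names)
        n_sites = len(self.sites)
        out = np.zeros((n_samples, n_sites, 4), dtype=np.int32)
        if len(self.starts) == 0:
            return out
        rl = self.read_length
        cov = (self.starts[:, None] <= self.sites[None, :]) & (
            self.sites[None, :] < self.starts[:, None] + rl
        )
        code = self.samples[:, None] * 4 + self.bases
        for j in range(n_sites):
            sel = cov[:, j]
            cnt = np.bincount(code[sel, j], minlength=n_samples * 4)
            out[:, j, :] = cnt.reshape(n_samples, 4)
        return out


class CaptureSimulator:
    """Streams per-target read blocks; deterministic per (seed, chrom, target)."""

    def __init__(self, cross: Cross):
        self.cross = cross
        self.config = cross.config
        self.lineages = cross.lineages
        cfg = self.config
        self.progeny_names = [f"prog{i:02d}" for i in range(cfg.n_progeny)]
        self.sample_names = ["mother", "father"] + self.progeny_names + ["vesca_ref"]
        self.octoploid_samples = list(range(2 + cfg.n_progeny))
        self.diploid_sample = 2 + cfg.n_progeny
        # registry: 16 parental haplotype arrays + vesca reference
        self.hap_keys = [
            (parent, sub, hap)
            for parent in ("m", "p")
            for sub in SUBGENOME_ORDER
            for hap in (0, 1)
        ]
        self.hap_index = {k: i for i, k in enumerate(self.hap_keys)}
        self.vesca_index = len(self.hap_keys)

    def chromosome_name(self, ci: int) -> str:
        return f"chr{ci + 1}"

    # -- per-target machinery -------------------------------------------

    def _window(self, ci: int, t: int) -> slice:
        w = 2 * WINDOW_PAD + 1
        return slice(t * w, (t + 1) * w)

    def _seq_matrix(self, ci: int, t: int) -> tuple[np.ndarray, list[np.ndarray]]:
        """Stacked window sequences: 16 parental haps, vesca ref, then one
        row per transposition copy active at this target."""
        win = self._window(ci, t)
        rows = [self.cross.haplotypes[k][ci][win] for k in self.hap_keys]
        rows.append(self.lineages.sequences["vesca"][ci][win])
        copies = []
        pos = self.lineages.positions[ci][win]
        for tp in self.cross.transpositions:
            if tp.donor_chromosome == ci and tp.donor_target == t:
                src = self.cross.haplotypes[(tp.parent, tp.subgenome, 0)][ci][win].copy()
                m = int(np.searchsorted(pos, tp.marker_position))
                src[m] = (src[m] + 1) % 4
                copies.append((tp, src))
        mat = np.stack(rows + [c for _, c in copies])
        return mat, copies

    def variant_sites(self, ci: int, t: int) -> np.ndarray:
        """Window positions variable among taxa, parental haplotypes and
        active transposition copies (the scored site set)."""
        win = self._window(ci, t)
        mat, copies = self._seq_matrix(ci, t)
        taxa = [
            self.lineages.sequences[k][ci][win]
            for k in ("outgroup", "vesca", "iinumae", "Av", "B1", "B2", "Bi")
        ]
        all_rows = np.vstack([mat] + [np.stack(taxa)])
        variable = (all_rows != all_rows[0]).any(axis=0)
        return self.lineages.positions[ci][win][variable]

    def block(self, ci: int, t: int) -> TargetBlock:
        cfg = self.config
        rng = np.random.default_rng([cfg.seed, 3, ci, t])
        center = int(self.lineages.centers[ci][t])
        win = self._window(ci, t)
        pos = self.lineages.positions[ci][win]
        mat, copies = self._seq_matrix(ci, t)
        sites = self.variant_sites(ci, t)
        site_cols = np.searchsorted(pos, sites)
        ref = self.lineages.sequences["vesca"][ci][win][site_cols]

        starts_all, samples_all, source_all = [], [], []
        for s_idx, sample in enumerate(self.sample_names):
            pool, probs = self._pool(sample, ci, t, copies)
            lam = cfg.depth * len(pool) / (2 if sample == "vesca_ref" else 8)
            n = rng.poisson(lam)
            if n == 0:
                continue
            slots = rng.integers(0, len(pool), n)
            starts = rng.integers(center - cfg.read_length + 1, center + 1, n)
            src = self._resolve_sources(sample, pool, slots, starts, ci)
            starts_all.append(starts)
            samples_all.append(np.full(n, s_idx, dtype=np.int16))
            source_all.append(src)
        if starts_all:
            starts = np.concatenate(starts_all)
            samples = np.concatenate(samples_all)
            sources = np.concatenate(source_all)
            bases = mat[sources[:, None], site_cols[None, :]].copy()
            if cfg.error_rate > 0:
                err = rng.random(bases.shape) < cfg.error_rate
                n_err = int(err.sum())
                if n_err:
                    bases[err] = (bases[err] + rng.integers(1, 4, n_err)) % 4
        else:
            starts = np.empty(0, dtype=np.int64)
            samples = np.empty(0, dtype=np.int16)
            bases = np.empty((0, len(sites)), dtype=np.uint8)
        central_depth = np.bincount(samples, minlength=len(self.sample_names))
        return TargetBlock(
            ci, t, center, sites.astype(np.int64), ref,
            self.sample_names, starts.astype(np.int64), samples,
            bases.astype(np.uint8), central_depth, cfg.read_length,
        )

    def _pool(self, sample: str, ci: int, t: int, copies) -> tuple[list, None]:
        """Haplotype slots available to a sample at this target."""
        if sample == "vesca_ref":
            return [("vesca",), ("vesca",)], None
        pool: list[tuple] = []
        if sample in ("mother", "father"):
            parent = "m" if sample == "mother" else "p"
            for sub in SUBGENOME_ORDER:
                pool.append(("hap", parent, sub, 0))
                pool.append(("hap", parent, sub, 1))
            for k, (tp, _) in enumerate(copies):
                if tp.zygosity == "fixed":
                    pool.extend([("copy", k)] * 8)
                elif tp.parent == parent:
                    pool.append(("copy", k))
        else:
            prog = int(sample[4:])
            for parent in ("m", "p"):
                for sub in SUBGENOME_ORDER:
                    pool.append(("gamete", prog, parent, sub))
            for k, (tp, _) in enumerate(copies):
                if tp.zygosity == "fixed":
                    pool.extend([("copy", k)] * 8)
                elif self._carries(prog, tp):
                    pool.append(("copy", k))
        return pool, None

    def _carries(self, prog: int, tp: Transposition) -> bool:
        """Carrier haplotype is hap 0 of (parent, subgenome) at the middle of
        the acceptor chromosome; the progeny carries the copy iff its gamete
        from that parent took hap 0 there."""
        g = self.cross.gametes[(prog, tp.parent, tp.subgenome)][tp.acceptor_chromosome]
        locus = self.config.chromosome_length // 2
        return int(g.hap_at(locus)) == 0

    def _resolve_sources(
        self, sample: str, pool: list, slots: np.ndarray, starts: np.ndarray, ci: int
    ) -> np.ndarray:
        """Map (slot, read start) to a row of the per-target sequence matrix."""
        n_base = len(self.hap_keys) + 1  # + vesca row
        out = np.empty(len(slots), dtype=np.int32)
        for slot_id in np.unique(slots):
            mask = slots == slot_id
            slot = pool[slot_id]
            if slot[0] == "vesca":
                out[mask] = self.vesca_index
            elif slot[0] == "hap":
                _, parent, sub, hap = slot
                out[mask] = self.hap_index[(parent, sub, hap)]
            elif slot[0] == "copy":
                out[mask] = n_base + slot[1]
            else:  # gamete
                _, prog, parent, sub = slot
                g = self.cross.gametes[(prog, parent, sub)][ci]
                haps = g.hap_at(starts[mask])
                base0 = self.hap_index[(parent, sub, 0)]
                out[mask] = base0 + haps
        return out

    # -- streams ----------------------------------------------------------

    def blocks(self) -> Iterator[TargetBlock]:
        for ci in range(self.config.n_chromosomes):
            for t in range(self.config.targets_per_chromosome):
                yield self.block(ci, t)

    def write_pileup(self, stream: IO[str]) -> None:
        """Emit mpileup text at every scored variant site (multi-sample)."""
        for block in self.blocks():
            self.write_block_pileup(block, stream)

    def write_block_pileup(self, block: TargetBlock, stream: IO[str]) -> None:
        counts = block.counts()
        chrom = self.chromosome_name(block.chromosome)
        for j, site in enumerate(block.sites):
            per_sample = [
                {BASES[b]: int(counts[s, j, b]) for b in range(4)}
                for s in range(len(self.sample_names))
            ]
            line = format_pileup_column(
                GenomeCoordinate(chrom, int(site)), BASES[block.reference[j]], per_sample
            )
            stream.write(line + "\n")

    def write_alignments(self, stream: IO[str]) -> None:
        """Tab-separated read alignments (sample, chrom, start, sequence);
        sequencing errors appear at scored variant sites."""
        for block in self.blocks():
            chrom = self.chromosome_name(block.chromosome)
            win = self._window(block.chromosome, block.target_index)
            pos = self.lineages.positions[block.chromosome][win]
            for i in range(len(block.starts)):
                start = int(block.starts[i])
                i0 = int(np.searchsorted(pos, start))
                # reference backbone with the read's scored-site bases patched in
                seq = self.lineages.sequences["vesca"][block.chromosome][win][
                    i0 : i0 + self.config.read_length
                ].copy()
                inside = (block.sites >= start) & (
                    block.sites < start + self.config.read_length
                )
                seq[np.searchsorted(pos[i0:], block.sites[inside])] = block.bases[
                    i, inside
                ]
                stream.write(
                    "\t".join(
                        [
                            self.sample_names[int(block.samples[i])],
                            chrom,
                            str(start),
                            "".join(np.array(list(BASES))[seq]),
                        ]
                    )
                    + "\n"
                )

    def diploid_calls(self, ci: int) -> dict[str, dict[int, str]]:
        """Truth-derived site calls for the diploid reference taxa at every
        scored variant site of a chromosome."""
        calls: dict[str, dict[int, str]] = {"vesca": {}, "iinumae": {}, "outgroup": {}}
        for t in range(self.config.targets_per_chromosome):
            sites = self.variant_sites(ci, t)
            for taxon in calls:
                seq = self.lineages.sequences[taxon][ci]
                pos = self.lineages.positions[ci]
                idx = np.searchsorted(pos, sites)
                for p, b in zip(sites, seq[idx]):
                    calls[taxon][int(p)] = BASES[b]
        return calls

    def target_regions(self) -> list[TargetRegion]:
        out = []
        for ci in range(self.config.n_chromosomes):
            chrom = self.chromosome_name(ci)
            for c in self.lineages.centers[ci]:
                out.append(
                    TargetRegion(
                        chrom, int(c) - WINDOW_PAD, int(c) + WINDOW_PAD,
                        GenomeCoordinate(chrom, int(c)),
                    )
                )
        return out


def simulate_capture_pileup(cross: Cross) -> CaptureSimulator:
    """Factory mirroring the staged API: lineages -> cross -> capture."""
    return CaptureSimulator(cross)
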