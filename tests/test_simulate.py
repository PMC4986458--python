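"""Generator properties: lineage substitution model, disomic cross, capture."""

import io

import numpy as np
import pytest

from polymaps.formats_io import read_pileup
from polymaps.simulate import (
    CaptureSimulator,
    SimulationConfig,
    SUBGENOME_ORDER,
    simulate_cross,
    simulate_lineages,
)

SMALL = SimulationConfig(
    seed=5,
    n_chromosomes=2,
    chromosome_length=100_000,
    targets_per_chromosome=12,
    n_progeny=20,
    depth=64.0,
    error_rate=0.0,
    n_tracts=2,
    tract_length=20_000,
    n_transpositions=1,
)


class TestLineages:
    def test_zero_rates_give_identical_sequences(self):
        cfg = SimulationConfig(
            seed=1, n_chromosomes=1, chromosome_length=50_000,
            targets_per_chromosome=6, rate_outgroup=0.0, rate_vesca_stem=0.0,
            rate_vesca=0.0, rate_av=0.0, rate_iinumae_stem=0.0, rate_b1=0.0,
            rate_b2=0.0, rate_ii_bi_stem=0.0, rate_iinumae=0.0, rate_bi=0.0,
            n_tracts=0,
        )
        lin = simulate_lineages(cfg)
        root = lin.sequences["ancestor"][0]
        for name, seqs in lin.sequences.items():
            assert (seqs[0] == root).all(), name

    def test_branch_substitution_count_is_binomial(self):
        cfg = SimulationConfig(
            seed=2, n_chromosomes=1, chromosome_length=500_000,
            targets_per_chromosome=100, n_tracts=0, rate_outgroup=0.05,
        )
        lin = simulate_lineages(cfg)
        n = len(lin.positions[0])
        diffs = int((lin.sequences["outgroup"][0] != lin.sequences["ancestor"][0]).sum())
        mean = n * 0.05
        sd = (n * 0.05 * 0.95) ** 0.5
        assert abs(diffs - mean) < 5 * sd

    def test_tract_equals_vesca_lineage_inside(self):
        lin = simulate_lineages(SMALL)
        tract = lin.tracts[0]
        pos = lin.positions[tract.chromosome]
        inside = (pos >= tract.start) & (pos <= tract.end)
        assert inside.any()
        sub = lin.sequences[tract.subgenome][tract.chromosome]
        src = lin.sequences["vesca_ancestor"][tract.chromosome]
        assert (sub[inside] == src[inside]).all()

    def test_determinism(self):
        a = simulate_lineages(SMALL)
        b = simulate_lineages(SMALL)
        for k in a.sequences:
            for s1, s2 in zip(a.sequences[k], b.sequences[k]):
                assert (s1 == s2).all()


class TestCross:
    def test_zero_recombination_gives_intact_haplotypes(self):
        cfg = SimulationConfig(
            seed=3, n_chromosomes=1, chromosome_length=100_000,
            targets_per_chromosome=10, n_progeny=8, recomb_per_chromosome=0.0,
            n_tracts=0, n_transpositions=0,
        )
        cross = simulate_cross(simulate_lineages(cfg), cfg)
        for key, gametes in cross.gametes.items():
            for g in gametes:
                assert len(g.breakpoints) == 0

    def test_planted_het_segregates_mendelian(self):
        """At a planted maternal het, the fraction of progeny inheriting the
        minor haplotype is binomial around one half."""
        cfg = SimulationConfig(
            seed=4, n_chromosomes=1, chromosome_length=200_000,
            targets_per_chromosome=20, n_progeny=400, n_tracts=0,
            n_transpositions=0,
        )
        lin = simulate_lineages(cfg)
        cross = simulate_cross(lin, cfg)
        s = next(x for x in cross.planted if x.parent == "m")
        sub_i = SUBGENOME_ORDER.index(s.subgenome)
        idx = int(np.searchsorted(lin.positions[0], s.position))
        h0 = cross.haplotypes[("m", s.subgenome, 0)][0][idx]
        h1 = cross.haplotypes[("m", s.subgenome, 1)][0][idx]
        minor_hap = 0 if "ACGT"[h0] == s.minor_base else 1
        carriers = sum(
            int(cross.gametes[(p, "m", s.subgenome)][0].hap_at(s.position)) == minor_hap
            for p in range(cfg.n_progeny)
        )
        frac = carriers / cfg.n_progeny
        assert abs(frac - 0.5) < 4 * (0.25 / cfg.n_progeny) ** 0.5

    def test_crossover_count_matches_rate(self):
        cfg = SimulationConfig(
            seed=6, n_chromosomes=1, chromosome_length=1_000_000,
            targets_per_chromosome=10, n_progeny=300,
            recomb_per_chromosome=2.0, n_tracts=0, n_transpositions=0,
        )
        cross = simulate_cross(simulate_lineages(cfg), cfg)
        counts = [
            len(g.breakpoints)
            for gametes in cross.gametes.values()
            for g in gametes
        ]
        assert np.mean(counts) == pytest.approx(2.0, abs=0.15)


class TestCapture:
    def _sim(self, cfg=SMALL):
        return CaptureSimulator(simulate_cross(simulate_lineages(cfg), cfg))

    def test_single_subgenome_het_frequency_near_one_eighth(self):
        """With zero error, the minor-allele read fraction at a planted het
        in the carrier parent is binomial around 1/8 (one of eight
        haplotypes)."""
        sim = self._sim()
        cross = sim.cross
        fracs = []
        for s in cross.planted[:40]:
            if s.parent != "m":
                continue
            t = int(
                np.searchsorted(sim.lineages.centers[s.chromosome], s.position)
            )
            t = max(0, min(t, SMALL.targets_per_chromosome - 1))
            for cand in (t - 1, t, t + 1):
                if 0 <= cand < SMALL.targets_per_chromosome and abs(
                    int(sim.lineages.centers[s.chromosome][cand]) - s.position
                ) <= 30:
                    t = cand
                    break
            block = sim.block(s.chromosome, t)
            j = int(np.searchsorted(block.sites, s.position))
            if j >= len(block.sites) or block.sites[j] != s.position:
                continue
            counts = block.counts()[0, j]  # mother
            depth = counts.sum()
            if depth == 0:
                continue
            minor = counts["ACGT".index(s.minor_base)]
            fracs.append(minor / depth)
        assert len(fracs) >= 10
        assert np.mean(fracs) == pytest.approx(1 / 8, abs=0.03)

    def test_pileup_text_round_trips_through_parser(self):
        sim = self._sim()
        block = sim.block(0, 0)
        buf = io.StringIO()
        sim.write_block_pileup(block, buf)
        buf.seek(0)
        cols = list(read_pileup(buf, sim.sample_names))
        counts = block.counts()
        assert len(cols) == len(block.sites)
        for j, col in enumerate(cols):
            for si, name in enumerate(sim.sample_names):
                expected = dict(zip("ACGT", (int(x) for x in counts[si, j])))
                assert col.per_sample_counts[name] == expected

    def test_fixed_seed_is_byte_identical(self):
        out1, out2 = io.StringIO(), io.StringIO()
        self._sim().write_pileup(out1)
        self._sim().write_pileup(out2)
        assert out1.getvalue() == out2.getvalue()

    def test_error_rate_perturbs_reads(self):
        cfg_err = SimulationConfig(**{**SMALL.__dict__, "error_rate": 0.01})
        sim0 = self._sim()
        sim1 = self._sim(cfg_err)
        b0 = sim0.block(0, 0)
        b1 = sim1.block(0, 0)
        assert (b0.bases != b1.bases).any()

    def test_fixed_transposition_doubles_donor_depth(self):
        cfg = SimulationConfig(
            seed=9, n_chromosomes=2, chromosome_length=100_000,
            targets_per_chromosome=10, n_progeny=12, depth=60.0,
            error_rate=0.0, n_tracts=0, n_transpositions=1,
        )
        lin = simulate_lineages(cfg)
        cross = simulate_cross(lin, cfg)
        tp = cross.transpositions[0]
        fixed = tp.__class__(**{**tp.__dict__, "zygosity": "fixed"})
        cross.transpositions[0] = fixed
        sim = CaptureSimulator(cross)
        donor_block = sim.block(fixed.donor_chromosome, fixed.donor_target)
        other_t = (fixed.donor_target + 3) % cfg.targets_per_chromosome
        other_block = sim.block(fixed.donor_chromosome, other_t)
        octo = sim.octoploid_samples
        d_dup = donor_block.central_depth[octo].mean()
        d_ref = other_block.central_depth[octo].mean()
        assert d_dup / d_ref == pytest.approx(2.0, abs=0.25)
        # the diploid reference is unaffected
        dip = sim.diploid_sample
        assert donor_block.central_depth[dip] == pytest.approx(
            other_block.central_depth[dip], abs=35
        )


def test_depth_zero_target_gives_missing_downstream():
    from polymaps.calling import call_octoploid_genotype

    assert call_octoploid_genotype({}).state.value == "missing"
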