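"""R-QTL LD walk, four-gamete blocks, candidate-gene windows."""

import numpy as np
import pandas as pd
import pytest

from napusgwas import sim
from napusgwas.genotypes import GenotypeMatrix
from napusgwas.intervals import (
    build_rqtl_set,
    candidate_genes,
    four_gamete_blocks,
    hwe_exact_p,
    interval_length_kb,
    rqtl_walk,
    two_locus_em,
)


def _map_for(pos, chrom="A05"):
    return pd.DataFrame(
        {
            "id": [f"m{i}" for i in range(len(pos))],
            "chrom": chrom,
            "pos": pos,
            "major_allele": "A",
            "minor_allele": "C",
        }
    )


def _haps_to_matrix(haps):
    """Phased haplotype array (2n x m) to an unphased GenotypeMatrix."""
    return GenotypeMatrix((haps[0::2] + haps[1::2]).astype(np.int8))


def _blocky_genotypes(n, block_sizes, seed, p=0.4, switch_noise=0.02):
    """Chromosome built from perfect-LD blocks: markers within a block share
    the same underlying haplotype indicator (small noise keeps them
    polymorphic but tightly linked); independent indicators across blocks."""
    rng = np.random.default_rng(seed)
    haps = []
    for size in block_sizes:
        base = rng.binomial(1, p, size=2 * n)
        block = np.repeat(base[:, None], size, axis=1)
        noise = rng.random((2 * n, size)) < switch_noise
        haps.append(np.where(noise, 1 - block, block))
    return np.concatenate(haps, axis=1)


class TestIntervalLength:
    @pytest.mark.parametrize(
        "start, end, kb",
        [
            (20169332, 20243410, 74.08),
            (20243410, 20265627, 22.22),
            (40099068, 40267266, 168.20),
            (15753918, 15758520, 4.60),
            (12058887, 12315563, 256.68),
        ],
    )
    def test_reported_interval_lengths(self, start, end, kb):
        assert interval_length_kb(start, end) == kb

    def test_half_up_rounding(self):
        assert interval_length_kb(0, 12345) == 12.35
        assert interval_length_kb(0, 12344) == 12.34

    def test_reversed_rejected(self):
        with pytest.raises(ValueError):
            interval_length_kb(100, 50)


class TestRQTLWalk:
    def test_immediate_neighbors_below_threshold(self):
        haps = _blocky_genotypes(200, [1, 1, 1], seed=0, switch_noise=0.5)  # ~independent markers
        G = _haps_to_matrix(haps)
        mm = _map_for([1000, 5000, 9000])
        iv = rqtl_walk("m1", G, mm, r2_min=0.1)
        assert (iv.left_border_pos, iv.right_border_pos) == (1000, 9000)

    def test_lead_at_chromosome_edge(self):
        haps = _blocky_genotypes(150, [3], seed=1)
        G = _haps_to_matrix(haps)
        mm = _map_for([100, 200, 300])
        iv = rqtl_walk("m2", G, mm)
        assert iv.right_border_pos == 300  # lead is the last marker
        iv0 = rqtl_walk("m0", G, mm)
        assert iv0.left_border_pos == 100

    def test_all_linked_to_chromosome_end(self):
        haps = _blocky_genotypes(200, [5], seed=2)
        G = _haps_to_matrix(haps)
        mm = _map_for([100, 200, 300, 400, 500])
        iv = rqtl_walk("m2", G, mm)
        assert (iv.left_border_pos, iv.right_border_pos) == (100, 500)

    def test_unknown_lead_rejected(self):
        haps = _blocky_genotypes(50, [2], seed=3)
        with pytest.raises(KeyError):
            rqtl_walk("nope", _haps_to_matrix(haps), _map_for([1, 2]))

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_exhaustive_oracle(self, seed):
        """Walk borders equal a brute-force scan for the first sub-threshold
        marker on each side of the lead, on random 50-marker chromosomes."""
        cfg = sim.SimConfig(
            n_samples=80, chromosomes=(("A01", 50, 600_000),),
            n_subpops=1, fst=0.0, ld_rho=0.85, missing_rate=0.03, seed=seed,
        )
        res = sim.simulate_genotypes(cfg)
        G, mm = res.genotypes, res.marker_map
        rng = np.random.default_rng(seed)
        lead = int(rng.integers(0, 50))
        iv = rqtl_walk(mm["id"].iloc[lead], G, mm, r2_min=0.1)

        def oracle_r2(i, j):
            g1, g2 = G.dosages[:, i].astype(float), G.dosages[:, j].astype(float)
            ok = (g1 >= 0) & (g2 >= 0)
            if ok.sum() < 3 or np.std(g1[ok]) == 0 or np.std(g2[ok]) == 0:
                return -1.0  # undefined: treated as below threshold
            return np.corrcoef(g1[ok], g2[ok])[0, 1] ** 2

        left = lead
        for j in range(lead - 1, -1, -1):
            left = j
            if oracle_r2(lead, j) < 0.1:
                break
        right = lead
        for j in range(lead + 1, 50):
            right = j
            if oracle_r2(lead, j) < 0.1:
                break
        pos = mm["pos"].to_numpy()
        assert (iv.left_border_pos, iv.right_border_pos) == (pos[left], pos[right])


class TestBuildRQTLSet:
    def test_single_lead_reduces_to_walk(self):
        haps = _blocky_genotypes(150, [4, 4], seed=4)
        G = _haps_to_matrix(haps)
        mm = _map_for(np.arange(1, 9) * 1000)
        lead = mm["id"].iloc[2]
        assert build_rqtl_set([lead], G, mm)[0].__dict__ == rqtl_walk(lead, G, mm).__dict__

    def test_map_adjacent_significant_pair_shares_boundary(self):
        haps = _blocky_genotypes(200, [6], seed=5)  # one tight LD block
        G = _haps_to_matrix(haps)
        mm = _map_for(np.arange(1, 7) * 1000)
        ivs = build_rqtl_set(["m2", "m3"], G, mm)
        assert len(ivs) == 2
        by_lead = {iv.lead_ids[0]: iv for iv in ivs}
        # each member bounds the other's interval on the shared side
        assert by_lead["m2"].right_border_pos == 4000  # m3's position
        assert by_lead["m3"].left_border_pos == 3000   # m2's position

    def test_two_ld_blocks_give_two_merged_intervals(self):
        """Two pairs of peak SNPs in two different LD blocks collapse to two
        distinct intervals, each pooling its pair of leads."""
        haps = _blocky_genotypes(300, [5, 5], seed=6, switch_noise=0.01)
        G = _haps_to_matrix(haps)
        mm = _map_for(np.arange(1, 11) * 1000)
        # leads: two in block 1 (markers 1, 3), two in block 2 (markers 6, 8)
        ivs = build_rqtl_set(["m1", "m3", "m6", "m8"], G, mm)
        assert len(ivs) == 2
        lead_sets = sorted(tuple(sorted(iv.lead_ids)) for iv in ivs)
        assert lead_sets == [("m1", "m3"), ("m6", "m8")]

    def test_every_lead_in_exactly_one_interval(self):
        haps = _blocky_genotypes(150, [3, 4, 3], seed=7)
        G = _haps_to_matrix(haps)
        mm = _map_for(np.arange(1, 11) * 500)
        leads = ["m0", "m4", "m5", "m9"]
        ivs = build_rqtl_set(leads, G, mm)
        seen = [mid for iv in ivs for mid in iv.lead_ids]
        assert sorted(seen) == sorted(leads)


class TestHWEExact:
    @pytest.mark.parametrize(
        "het, hom_min, hom_maj",
        [(10, 5, 85), (50, 25, 25), (0, 50, 50), (20, 0, 80)],
    )
    def test_matches_full_enumeration_oracle(self, het, hom_min, hom_maj):
        from math import comb

        n = het + hom_min + hom_maj
        rare = min(2 * hom_min + het, 2 * hom_maj + het)

        def prob(h):  # P(h hets | allele counts), Levene/Haldane
            if (rare - h) % 2:
                return 0.0
            hr = (rare - h) // 2
            hc = n - h - hr
            if hr < 0 or hc < 0:
                return 0.0
            return comb(n, hr) * comb(n - hr, h) * 2**h / comb(2 * n, rare)

        probs = np.array([prob(h) for h in range(rare + 1)])
        probs /= probs.sum()
        obs = het
        expected = probs[probs <= probs[obs] * (1 + 1e-12)].sum()
        assert hwe_exact_p(het, hom_min, hom_maj) == pytest.approx(expected, rel=1e-8)

    def test_equilibrium_not_rejected(self):
        # 480 AA / 160 Aa / ~13 aa is near-perfect HWE at p~0.15
        assert hwe_exact_p(160, 13, 480) > 0.5


class TestTwoLocusEM:
    def test_recovers_phased_truth_frequencies(self):
        cfg = sim.SimConfig(
            n_samples=500, chromosomes=(("A01", 30, 300_000),),
            n_subpops=1, fst=0.0, ld_rho=0.8, missing_rate=0.0, seed=9,
        )
        res = sim.simulate_genotypes(cfg)
        haps = res.haplotypes
        G = res.genotypes
        worst = 0.0
        for j in range(29):
            est = two_locus_em(G.dosages[:, j], G.dosages[:, j + 1])
            a, b = haps[:, j], haps[:, j + 1]
            truth = np.array(
                [
                    np.mean((a == 1) & (b == 1)),
                    np.mean((a == 1) & (b == 0)),
                    np.mean((a == 0) & (b == 1)),
                    np.mean((a == 0) & (b == 0)),
                ]
            )
            worst = max(worst, np.max(np.abs(est - truth)))
        assert worst < 0.02


class TestFourGameteBlocks:
    def test_perfect_ld_pair_is_one_block(self):
        haps = _blocky_genotypes(300, [2], seed=10, switch_noise=0.0)
        G = _haps_to_matrix(haps)
        blocks = four_gamete_blocks(G, _map_for([1000, 2000]))
        assert len(blocks) == 1
        assert blocks[0].marker_ids == ("m0", "m1")

    def test_four_equal_gametes_split_into_singletons(self):
        rng = np.random.default_rng(11)
        haps = rng.binomial(1, 0.5, size=(600, 2))  # independent loci at 0.5
        G = _haps_to_matrix(haps)
        blocks = four_gamete_blocks(G, _map_for([1000, 2000]))
        assert len(blocks) == 2
        assert all(len(b.marker_ids) == 1 for b in blocks)

    def test_partitions_retained_markers_contiguously(self, qc_panel):
        G, mm = qc_panel
        sub = np.arange(80)
        blocks = four_gamete_blocks(G.take_markers(sub), mm.iloc[sub].reset_index(drop=True))
        flat = [mid for b in blocks for mid in b.marker_ids]
        assert len(flat) == len(set(flat))
        order = {mid: i for i, mid in enumerate(mm["id"].iloc[sub])}
        idx = [order[mid] for mid in flat]
        assert idx == sorted(idx)
        for b in blocks:
            assert b.start_pos <= b.end_pos

    def test_too_few_markers_empty(self):
        dos = np.random.default_rng(12).binomial(2, 0.3, (60, 1)).astype(np.int8)
        assert four_gamete_blocks(GenotypeMatrix(dos), _map_for([1000])) == []


class TestCandidateGenes:
    def _ann(self):
        return pd.DataFrame(
            {
                "gene_id": ["g1", "g2", "g3"],
                "chrom": ["A05", "A05", "A09"],
                "start": [100_000, 320_000, 50_000],
                "end": [110_000, 330_000, 60_000],
                "strand": ["+", "-", "+"],
            }
        )

    def test_empty_annotation(self):
        assert candidate_genes(1000, "A05", pd.DataFrame(columns=["gene_id", "chrom", "start", "end"])) == []

    def test_containing_gene_distance_zero(self):
        hits = candidate_genes(105_000, "A05", self._ann())
        assert hits[0].gene_id == "g1"
        assert hits[0].distance_bp == 0 and hits[0].relation == "contains"

    def test_exact_offset_distance(self):
        # gene placed 9,270 bp downstream of the query
        ann = pd.DataFrame(
            {"gene_id": ["gx"], "chrom": ["A05"], "start": [20_231_812], "end": [20_233_000], "strand": ["+"]}
        )
        hits = candidate_genes(20_222_542, "A05", ann)
        assert hits[0].distance_bp == 9270 and hits[0].relation == "downstream"

    def test_window_excludes_far_genes(self):
        hits = candidate_genes(105_000, "A05", self._ann(), window_bp=250_000)
        assert {h.gene_id for h in hits} == {"g1", "g2"}
        hits_small = candidate_genes(105_000, "A05", self._ann(), window_bp=100_000)
        assert {h.gene_id for h in hits_small} == {"g1"}

    def test_unknown_chromosome_warns_empty(self):
        with pytest.warns(UserWarning):
            assert candidate_genes(1000, "C99", self._ann()) == []
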