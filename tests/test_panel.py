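"""Genotype panel I/O, linkage map, filters and allele frequencies."""

import numpy as np
import pytest

import msatld as m
from msatld.panel import (
    MISSING,
    GenePopFormatError,
    Locus,
    filter_panel,
    read_genepop,
    read_map,
    write_genepop,
    write_map,
)


def _write(tmp_path, text, name="panel.gen"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestGenePop:
    def test_missing_genotype_counted(self, tmp_path):
        path = _write(tmp_path, "title\nlocA\nlocB\nPOP\ni1 , 0101 0000\ni2 , 0102 0303\n")
        gm = read_genepop(path)
        assert (gm.genotypes[:, :, 0] == MISSING).sum() == 1
        assert gm.genotype("i1", "locB") is None

    def test_pop_blocks_become_population_tags(self, tmp_path):
        path = _write(
            tmp_path,
            "t\nL1\nPOP\na , 0101\nb , 0102\nc , 0202\nPOP\nd , 0101\ne , 0102\n",
        )
        gm = read_genepop(path)
        assert gm.n_individuals == 5
        assert gm.populations == ["pop1"] * 3 + ["pop2"] * 2

    def test_two_digit_alleles_round_trip(self, tmp_path):
        path = _write(tmp_path, "t\nL1\nPOP\na , 9912\n")
        gm = read_genepop(path)
        assert gm.genotype("a", "L1") == (99, 12)
        out = tmp_path / "rt.gen"
        write_genepop(gm, out)
        assert read_genepop(out).genotype("a", "L1") == (99, 12)

    def test_three_digit_codes(self, tmp_path):
        path = _write(tmp_path, "t\nL1\nPOP\na , 101245\nb , 000000\n")
        gm = read_genepop(path)
        assert gm.genotype("a", "L1") == (101, 245)
        assert gm.genotype("b", "L1") is None

    @pytest.mark.parametrize(
        "body, message",
        [
            ("t\nL1\nPOP\na , 0101 0202\n", "genotypes for"),
            ("t\nL1\nL2\nPOP\na , 0101 010203\n", "width"),
            ("t\nL1\nPOP\nno-comma-line\n", "expected"),
            ("t\nL1\nPOP\na , 01x1\n", "non-numeric"),
        ],
    )
    def test_malformed_inputs_raise_with_context(self, tmp_path, body, message):
        with pytest.raises(GenePopFormatError, match=message):
            read_genepop(_write(tmp_path, body))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_round_trip_identity_on_random_panels(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        n, L = 12, 5
        genos = rng.integers(1, 9, size=(n, L, 2)).astype(np.int32)
        miss = rng.random((n, L)) < 0.2
        genos[miss] = MISSING
        gm = m.GenotypeMatrix([f"i{i}" for i in range(n)], [f"L{j}" for j in range(L)], genos)
        path = tmp_path / f"rt{seed}.gen"
        write_genepop(gm, path)
        back = read_genepop(path)
        assert back.individuals == gm.individuals
        assert back.loci == gm.loci
        # genotypes are unordered pairs: compare sorted
        assert np.array_equal(np.sort(back.genotypes, axis=2), np.sort(gm.genotypes, axis=2))


class TestLinkageMap:
    def test_distance_and_synteny(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text(
            "marker\tchromosome\tposition_cM\nm1\t1\t0\nm2\t1\t10\nm3\t1\t25\nm4\t2\t5\n"
        )
        lmap = read_map(p)
        assert lmap.distance("m1", "m3") == 25
        assert lmap.distance("m1", "m4") is None
        assert lmap.synteny_class("m1", "m4") == "nonsyntenic"
        assert lmap.synteny_class("m1", "m2") == "syntenic_lt50"

    def test_duplicate_and_negative_errors(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("marker\tchromosome\tposition_cM\nm1\t1\t0\nm1\t1\t5\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_map(p)
        p.write_text("marker\tchromosome\tposition_cM\nm1\t1\t-2\n")
        with pytest.raises(ValueError, match="negative"):
            read_map(p)

    def test_generator_map_has_eight_markers_per_chromosome(self):
        sim_map = m.simulate_population(
            m.Scenario(name="mapcheck", census=[(0, 10), (1, 10)], sampled_years=(1, 1)),
            seed=0,
        ).lmap
        assert len(sim_map) == 208
        per_chrom = [sum(1 for l in sim_map.loci if l.chromosome == c) for c in range(1, 27)]
        assert np.mean(per_chrom) == 8

    def test_map_round_trip(self, tmp_path):
        lmap = m.LinkageMap([Locus("a", 1, 0.0), Locus("b", 1, 12.5), Locus("c", 2, 3.0)])
        p = tmp_path / "m.tsv"
        write_map(lmap, p)
        back = read_map(p)
        assert [(l.id, l.chromosome, l.position) for l in back.loci] == [
            ("a", 1, 0.0), ("b", 1, 12.5), ("c", 2, 3.0)
        ]


class TestFilterPanel:
    def _panel_with_missing(self, locus_rates, ind_rates, n=50, L=10, seed=0):
        rng = np.random.default_rng(seed)
        genos = rng.integers(1, 5, size=(n, L, 2)).astype(np.int32)
        for j, rate in locus_rates.items():
            hit = rng.choice(n, size=int(rate * n), replace=False)
            genos[hit, j] = MISSING
        for i, rate in ind_rates.items():
            hit = rng.choice(L, size=int(rate * L), replace=False)
            genos[i, hit] = MISSING
        return m.GenotypeMatrix([f"i{i}" for i in range(n)], [f"L{j}" for j in range(L)], genos)

    def test_threshold_boundary(self):
        gm = self._panel_with_missing({0: 0.16}, {})
        out = filter_panel(gm, max_locus_missing=0.15)
        assert "L0" not in out.loci and out.n_loci == 9

    def test_fully_typed_panel_is_identity(self):
        gm = self._panel_with_missing({}, {})
        out = filter_panel(gm)
        assert out.loci == gm.loci and out.individuals == gm.individuals

    def test_planted_loci_then_individuals_removed(self):
        # 5 loci at 20% missing; 3 individuals missing 20% of the REMAINING loci
        n, L = 50, 40
        rng = np.random.default_rng(3)
        genos = rng.integers(1, 5, size=(n, L, 2)).astype(np.int32)
        bad_loci = [0, 7, 13, 21, 33]
        for j in bad_loci:
            genos[rng.choice(n, size=10, replace=False), j] = MISSING
        good = [j for j in range(L) if j not in bad_loci]
        bad_inds = [2, 11, 29]
        for i in bad_inds:
            genos[i, rng.choice(good, size=7, replace=False)] = MISSING  # 7/35 = 20%
        gm = m.GenotypeMatrix([f"i{i}" for i in range(n)], [f"L{j}" for j in range(L)], genos)
        out, report = filter_panel(gm, return_report=True)
        assert sorted(report.dropped_loci) == sorted(f"L{j}" for j in bad_loci)
        assert sorted(report.dropped_individuals) == sorted(f"i{i}" for i in bad_inds)

    def test_idempotent(self):
        gm = self._panel_with_missing({0: 0.2, 3: 0.18}, {1: 0.3})
        once = filter_panel(gm)
        twice = filter_panel(once)
        assert once.loci == twice.loci and once.individuals == twice.individuals

    def test_empty_panel_error(self):
        gm = self._panel_with_missing({j: 0.5 for j in range(10)}, {})
        with pytest.raises(ValueError, match="all loci"):
            filter_panel(gm, max_locus_missing=0.1)


class TestAlleleFrequencies:
    def test_hand_count(self):
        genos = np.array([[[1, 1]], [[1, 2]]], dtype=np.int32)
        gm = m.GenotypeMatrix(["a", "b"], ["L"], genos)
        st = m.allele_frequencies(gm, "L")
        assert st.freqs == {1: 0.75, 2: 0.25}
        assert st.heterozygosity == pytest.approx(0.375)

    def test_monomorphic_has_zero_heterozygosity(self):
        genos = np.full((4, 1, 2), 7, dtype=np.int32)
        gm = m.GenotypeMatrix(list("abcd"), ["L"], genos)
        assert m.allele_frequencies(gm, "L").heterozygosity == 0.0

    def test_no_data_error(self):
        genos = np.full((3, 1, 2), MISSING, dtype=np.int32)
        gm = m.GenotypeMatrix(list("abc"), ["L"], genos)
        with pytest.raises(ValueError, match="no non-missing"):
            m.allele_frequencies(gm, "L")

    def test_programmed_frequencies_recovered(self):
        rng = np.random.default_rng(8)
        p = np.array([0.5, 0.3, 0.2])
        genos = (rng.choice(3, size=(5000, 1, 2), p=p) + 1).astype(np.int32)
        gm = m.GenotypeMatrix([f"i{i}" for i in range(5000)], ["L"], genos)
        st = m.allele_frequencies(gm, "L")
        for allele, truth in zip((1, 2, 3), p):
            assert abs(st.freqs[allele] - truth) < 0.02  # ~3 SE at 10^4 genes

    def test_sum_to_one_and_bounds(self, small_sim):
        gm = small_sim.gm
        for locus in gm.loci[:6]:
            st = m.allele_frequencies(gm, locus)
            assert sum(st.freqs.values()) == pytest.approx(1.0, abs=1e-9)
            k = len(st.freqs)
            assert 0 <= st.heterozygosity <= 1 - 1 / k + 1e-12


class TestPedigreeStructure:
    def test_topological_order_parents_first(self):
        ped = m.Pedigree([("c", "a", "b"), ("a", None, None), ("b", None, None), ("d", "c", "b")])
        order = ped.topological_order()
        assert order.index("a") < order.index("c") < order.index("d")

    def test_cycle_detected_and_named(self):
        ped = m.Pedigree([("a", "b", None), ("b", "a", None)])
        with pytest.raises(ValueError, match="cycle"):
            ped.topological_order()
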