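import numpy as np
import pandas as pd
import pytest

from palaeokit import fstats as fs
from palaeokit import simulate as sim


def _toy_table():
    """Two SNPs with p_O = (1, 0), p_X = (0.5, 0.5), p_Y = (0, 1)."""
    snps = pd.DataFrame({"chrom": ["1", "2"], "pos": [0, 0], "ref": "A", "alt": "G"})
    geno = np.array([
        [1, 1, 1, 0, 0, 0],
        [0, 0, 1, 0, 1, 1],
    ])
    inds = [("o1", "U", "O"), ("o2", "U", "O"), ("x1", "U", "X"),
            ("x2", "U", "X"), ("y1", "U", "Y"), ("y2", "U", "Y")]
    return fs.GenoTable(snps=snps, geno=geno, individuals=inds)


@pytest.fixture(scope="module")
def drift_table():
    tree = sim.PopNode("root", 0.0, [
        sim.PopNode("O", 0.3),
        sim.PopNode("anc", 0.05, [
            sim.PopNode("inner", 0.05, [sim.PopNode("X", 0.02), sim.PopNode("Y", 0.02)]),
            sim.PopNode("Z", 0.1),
        ]),
    ])
    table, _ = sim.simulate_genotypes(tree, 20_000, samples_per_pop=5, seed=11)
    return table


class TestPseudohaploidCall:
    def test_terminal_base_trimmed(self):
        # SNP falls at read position 2 of a 30 bp fragment: inside the
        # 3 bp trim -> no usable base
        assert fs.pseudohaploid_call([("G", 2, 30)], "A", "G") == 9

    def test_unanimous_interior_alt(self):
        reads = [("G", 10, 30), ("G", 15, 30), ("G", 20, 30)]
        assert fs.pseudohaploid_call(reads, "A", "G", rng=1) == 1

    def test_other_base_is_missing(self):
        assert fs.pseudohaploid_call([("T", 10, 30)], "A", "G") == 9

    def test_random_sampling_is_fair(self):
        reads = [("A", 10, 30), ("G", 15, 30)]
        rng = np.random.default_rng(5)
        n = 10_000
        draws = [fs.pseudohaploid_call(reads, "A", "G", rng=rng) for _ in range(n)]
        frac_ref = np.mean(np.array(draws) == 0)
        assert abs(frac_ref - 0.5) < 3 * np.sqrt(0.25 / n)


class TestOutgroupF3:
    def test_two_snp_worked_example(self):
        res = fs.outgroup_f3(_toy_table(), "X", "Y", "O", block_size=10)
        assert res.value == pytest.approx(0.5)

    def test_self_comparison_nonnegative(self, drift_table):
        res = fs.outgroup_f3(drift_table, "X", "X", "O")
        assert res.value >= 0

    def test_sister_exceeds_distant(self, drift_table):
        sister = fs.outgroup_f3(drift_table, "X", "Y", "O")
        distant = fs.outgroup_f3(drift_table, "X", "Z", "O")
        sep = (sister.value - distant.value) / np.hypot(sister.se, distant.se)
        assert sister.value > distant.value
        assert sep > 3

    def test_missing_population_rejected(self, drift_table):
        with pytest.raises(fs.ValidationError):
            fs.outgroup_f3(drift_table, "X", "Y", "nope")


class TestDStat:
    def test_identical_populations_give_zero(self):
        snps = pd.DataFrame({"chrom": ["1"] * 4, "pos": [0, 10, 20, 30],
                             "ref": "A", "alt": "G"})
        # W and X have identical interior frequencies (two individuals with
        # mixed calls each) -> numerator 0 per SNP with nonzero denominator
        geno = np.array([
            [1, 0, 1, 0, 1, 1],
            [0, 1, 0, 1, 1, 0],
            [1, 0, 1, 0, 0, 1],
            [0, 1, 0, 1, 1, 1],
        ])
        inds = [("w1", "U", "W"), ("w2", "U", "W"), ("x1", "U", "X"),
                ("x2", "U", "X"), ("y", "U", "Y"), ("z", "U", "Z")]
        t = fs.GenoTable(snps=snps, geno=geno, individuals=inds)
        res = fs.d_stat(t, "W", "X", "Y", "Z", block_size=15)
        assert res.value == pytest.approx(0.0)

    def test_antisymmetry_under_wx_swap(self, drift_table):
        d1 = fs.d_stat(drift_table, "X", "Y", "Z", "O")
        d2 = fs.d_stat(drift_table, "Y", "X", "Z", "O")
        assert d1.value == pytest.approx(-d2.value)

    def test_bounded_by_one(self, drift_table):
        res = fs.d_stat(drift_table, "X", "Y", "Z", "O")
        assert -1.0 <= res.value <= 1.0

    def test_gene_flow_detected_with_expected_sign(self):
        tree = sim.PopNode("root", 0.0, [
            sim.PopNode("O", 0.3),
            sim.PopNode("anc", 0.05, [
                sim.PopNode("inner", 0.05,
                            [sim.PopNode("X", 0.02), sim.PopNode("Y", 0.02)]),
                sim.PopNode("Z", 0.1),
            ]),
        ])
        table, _ = sim.simulate_genotypes(tree, 20_000, samples_per_pop=5, seed=11,
                                          admixture=("Z", "X", 0.3))
        # flow Z -> X correlates p_X with p_Z: (p_X-p_Y)(p_Z-p_O) sums positive
        res = fs.d_stat(table, "X", "Y", "Z", "O")
        assert res.value > 0
        assert res.z > 3

    def test_null_tree_z_calibrated(self):
        tree = sim.PopNode("root", 0.0, [sim.PopNode(p, 0.05)
                                         for p in ("W", "X", "Y", "Z")])
        inside = 0
        n_rep = 40
        for s in range(n_rep):
            t, _ = sim.simulate_genotypes(tree, 5_000, samples_per_pop=4, seed=500 + s)
            if abs(fs.d_stat(t, "W", "X", "Y", "Z").z) < 3:
                inside += 1
        assert inside / n_rep >= 0.95


class TestBlockJackknife:
    def test_identical_blocks_zero_se(self):
        terms = np.tile([1.0, 2.0], 10)
        blocks = np.repeat(np.arange(10), 2)
        est, se = fs.block_jackknife(terms, blocks)
        assert est == pytest.approx(1.5)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_iid_terms_match_analytic_se(self):
        rng = np.random.default_rng(3)
        n, reps = 5_000, 30
        ratios = []
        for _ in range(reps):
            terms = rng.normal(0.0, 1.0, n)
            blocks = np.repeat(np.arange(50), n // 50)
            _, se = fs.block_jackknife(terms, blocks)
            ratios.append(se / (1 / np.sqrt(n)))
        assert abs(np.mean(ratios) - 1.0) < 0.1

    def test_estimate_equals_full_sample_mean(self):
        rng = np.random.default_rng(4)
        terms = rng.normal(2.0, 1.0, 400)
        blocks = np.repeat(np.arange(8), 50)
        est, _ = fs.block_jackknife(terms, blocks)
        assert est == pytest.approx(terms.mean(), rel=1e-9)

    def test_single_block_rejected(self):
        with pytest.raises(fs.ValidationError):
            fs.block_jackknife(np.ones(10), np.zeros(10))


class TestStability:
    def test_half_snp_subsample_within_two_se(self, drift_table):
        full = fs.outgroup_f3(drift_table, "X", "Y", "O")
        rng = np.random.default_rng(9)
        keep = rng.random(len(drift_table.snps)) < 0.5
        sub = fs.GenoTable(snps=drift_table.snps[keep].reset_index(drop=True),
                           geno=drift_table.geno[keep],
                           individuals=drift_table.individuals)
        half = fs.outgroup_f3(sub, "X", "Y", "O")
        assert abs(half.value - full.value) < 2 * np.hypot(half.se, full.se)
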