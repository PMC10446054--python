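"""Diversity, exclusion-probability, HWE and Weir-Cockerham θ against
independently coded brute-force / textbook oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pedconnect as pc
from pedconnect import popgen

from conftest import make_table


# ---------------------------------------------------------------------------
# oracles (independent of the implementation)
# ---------------------------------------------------------------------------


def tally_freqs(g, locus):
    """Brute-force allele tally over raw calls."""
    j = g.loci.index(locus)
    counts = {}
    for i in range(g.n_individuals):
        a, b = g.alleles[i, j]
        if a == pc.MISSING:
            continue
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}, total


def ppexp_enumeration(freq):
    """Exhaustive enumeration over (true parents, offspring, candidate pair)
    genotype combinations weighted by HWE frequencies."""
    k = len(freq)
    genos = [(a, b) for a in range(k) for b in range(a, k)]

    def gprob(geno):
        a, b = geno
        return freq[a] ** 2 if a == b else 2 * freq[a] * freq[b]

    def offspring_dist(g1, g2):
        out = {}
        for x in g1:
            for y in g2:
                key = (min(x, y), max(x, y))
                out[key] = out.get(key, 0.0) + 0.25
        return out

    def can_produce(g1, g2, off):
        x, y = off
        return (x in g1 and y in g2) or (y in g1 and x in g2)

    total = 0.0
    for tp1 in genos:
        for tp2 in genos:
            w_parents = gprob(tp1) * gprob(tp2)
            for off, w_off in offspring_dist(tp1, tp2).items():
                p_excl = sum(
                    gprob(c1) * gprob(c2)
                    for c1 in genos
                    for c2 in genos
                    if not can_produce(c1, c2, off)
                )
                total += w_parents * w_off * p_excl
    return total


def wc_theta_naive(g, pops):
    """Textbook Weir-Cockerham variance components, scalar loops."""
    pop_labels = sorted(set(pops.values()))
    per_locus = []
    for j, locus in enumerate(g.loci):
        cells = {}
        for i, ind in enumerate(g.ids):
            a, b = g.alleles[i, j]
            if a == pc.MISSING:
                continue
            cells.setdefault(pops[ind], []).append((a, b))
        present = [p for p in pop_labels if cells.get(p)]
        r = len(present)
        if r < 2:
            per_locus.append((0.0, 0.0, 0.0))
            continue
        alleles = sorted({a for rows in cells.values() for pair in rows for a in pair})
        n_i = np.array([len(cells[p]) for p in present], float)
        nbar = n_i.mean()
        nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
        a_s = b_s = c_s = 0.0
        for allele in alleles:
            p_i = np.array(
                [
                    sum(int(x == allele) + int(y == allele) for x, y in cells[p])
                    / (2 * len(cells[p]))
                    for p in present
                ]
            )
            h_i = np.array(
                [
                    sum(1 for x, y in cells[p] if x != y and allele in (x, y)) / len(cells[p])
                    for p in present
                ]
            )
            pbar = (n_i * p_i).sum() / (r * nbar)
            s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (n_i * h_i).sum() / (r * nbar)
            a_s += (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            b_s += (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c_s += hbar / 2
        per_locus.append((a_s, b_s, c_s))
    A = sum(x[0] for x in per_locus)
    D = sum(sum(x) for x in per_locus)
    return A / D, per_locus


@pytest.fixture(scope="module")
def fixture30(small_sim):
    """30-individual, 5-locus fixture cut from the simulated table."""
    _, genotypes, records, _ = small_sim
    g = genotypes.select(ids=genotypes.ids[:30], loci=genotypes.loci[:5])
    pops = records.loc[g.ids, "patch"]
    return g, pops


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------


class TestAlleleFreqs:
    def test_hand_count(self):
        g = make_table({"x": [(1, 1)], "y": [(1, 2)]})
        f = pc.allele_freqs(g).pooled("L1")
        assert f[1] == pytest.approx(0.75)
        assert f[2] == pytest.approx(0.25)

    def test_monomorphic(self):
        g = make_table({"x": [(5, 5)], "y": [(5, 5)]})
        f = pc.allele_freqs(g).pooled("L1")
        assert list(f.index) == [5] and f[5] == 1.0

    def test_matches_brute_force_tally(self, fixture30):
        g, pops = fixture30
        af = pc.allele_freqs(g)
        for locus in g.loci:
            expected, total = tally_freqs(g, locus)
            got = af.pooled(locus)
            assert got.sum() == pytest.approx(1.0)
            for allele, freq in expected.items():
                assert got[allele] == pytest.approx(freq, abs=1e-12)

    def test_zero_gene_cell_flagged(self):
        g = make_table({"x": [(1, 2)], "y": [None]})
        af = pc.allele_freqs(g, pops={"x": "A", "y": "B"})
        assert ("L1", "B") in af.undefined


class TestDiversity:
    def test_biallelic_half_limits(self):
        # frequencies p=q=0.5 in the large-n limit: Hexp -> 0.5, PIC = 0.375
        freq = np.array([0.5, 0.5])
        assert popgen._hexp(freq, 10**9) == pytest.approx(0.5, abs=1e-6)
        assert popgen._pic(freq) == pytest.approx(0.375)

    def test_monomorphic_zeroes(self):
        g = make_table({f"i{k}": [(7, 7)] for k in range(10)})
        res = pc.diversity(g)
        row = res.markers.loc["L1"]
        assert row["Hexp"] == 0 and row["Hobs"] == 0 and row["PIC"] == 0

    def test_matches_formula_oracle(self, fixture30):
        g, pops = fixture30
        res = pc.diversity(g, pops=pops)
        for locus in g.loci:
            freq_map, n_genes = tally_freqs(g, locus)
            p = np.array(list(freq_map.values()))
            hexp = n_genes / (n_genes - 1) * (1 - (p**2).sum())
            a2, a4 = (p**2).sum(), (p**4).sum()
            pic = 1 - a2 - (a2**2 - a4)
            j = g.loci.index(locus)
            typed = g.alleles[:, j, 0] != pc.MISSING
            hobs = (g.alleles[typed, j, 0] != g.alleles[typed, j, 1]).mean()
            row = res.markers.loc[locus]
            assert row["Hexp"] == pytest.approx(hexp, abs=1e-12)
            assert row["PIC"] == pytest.approx(pic, abs=1e-12)
            assert row["Hobs"] == pytest.approx(hobs, abs=1e-12)
            assert row["A"] == len(p)
        # PIC never exceeds Hexp
        assert (res.markers["PIC"] <= res.markers["Hexp"] + 1e-12).all()

    def test_hs_is_mean_over_loci(self, fixture30):
        g, pops = fixture30
        res = pc.diversity(g, pops=pops)
        one_pop = pops.unique()[0]
        sub_ids = [i for i in g.ids if pops[i] == one_pop]
        sub = g.select(ids=sub_ids)
        per_locus = []
        for locus in sub.loci:
            freq_map, n_genes = tally_freqs(sub, locus)
            if n_genes > 1:
                p = np.array(list(freq_map.values()))
                per_locus.append(n_genes / (n_genes - 1) * (1 - (p**2).sum()))
        assert res.hs.loc[one_pop, "Hs"] == pytest.approx(np.mean(per_locus), abs=1e-12)


class TestExclusionProbability:
    def test_monomorphic_is_zero(self):
        assert popgen.ppexp_locus(np.array([1.0])) == 0.0

    def test_cumulative_complement_product(self):
        assert popgen.cumulative_ppexp([0.5, 0.5]) == pytest.approx(0.75)

    @pytest.mark.parametrize(
        "freq",
        [
            [0.5, 0.5],
            [0.9, 0.1],
            [0.5, 0.3, 0.2],
            [0.25, 0.25, 0.25, 0.25],
        ],
    )
    def test_matches_enumeration_oracle(self, freq):
        freq = np.array(freq)
        assert popgen.ppexp_locus(freq) == pytest.approx(
            ppexp_enumeration(freq), abs=1e-9
        )

    def test_cumulative_monotone_in_panel_size(self, small_sim):
        _, genotypes, _, _ = small_sim
        per_locus = pc.exclusion_probability(pc.allele_freqs(genotypes)).per_locus
        cums = [popgen.cumulative_ppexp(per_locus[: k + 1]) for k in range(len(per_locus))]
        assert all(b >= a - 1e-15 for a, b in zip(cums, cums[1:]))

    def test_18_locus_panel_exceeds_0999(self, small_sim):
        _, genotypes, _, _ = small_sim
        res = pc.exclusion_probability(pc.allele_freqs(genotypes))
        assert res.cumulative > 0.999


class TestHWE:
    def test_perfect_proportions_high_p(self):
        # 25 AA, 50 AB, 25 BB at p=0.5: exactly HWE
        rows = {}
        for k in range(25):
            rows[f"aa{k}"] = [(1, 1)]
        for k in range(50):
            rows[f"ab{k}"] = [(1, 2)]
        for k in range(25):
            rows[f"bb{k}"] = [(2, 2)]
        res = pc.hwe_test(make_table(rows), "L1")
        assert res.p_value > 0.5

    def test_all_heterozygotes_rejected(self):
        g = make_table({f"i{k}": [(1, 2)] for k in range(100)})
        res = pc.hwe_test(g, "L1")
        assert res.method == "exact"
        assert res.p_value < 0.001

    def test_chi2_statistic_matches_hand_computation(self):
        # 3 alleles, counts chosen so every expected class is >= 5
        rows = {}
        idx = 0
        genos = {(1, 1): 20, (1, 2): 30, (2, 2): 15, (1, 3): 20, (2, 3): 10, (3, 3): 5}
        for geno, count in genos.items():
            for _ in range(count):
                rows[f"i{idx}"] = [geno]
                idx += 1
        g = make_table(rows)
        n = 100
        counts = {1: 2 * 20 + 30 + 20, 2: 30 + 2 * 15 + 10, 3: 20 + 10 + 2 * 5}
        p = {a: c / 200 for a, c in counts.items()}
        exp = {}
        for (a, b), _ in genos.items():
            exp[(a, b)] = n * (p[a] ** 2 if a == b else 2 * p[a] * p[b])
        chi2 = sum((genos[k] - exp[k]) ** 2 / exp[k] for k in genos)
        res = pc.hwe_test(g, "L1", exact="never")
        assert res.method == "chi2"
        assert res.statistic == pytest.approx(chi2, abs=1e-9)
        assert res.df == 3  # 6 classes - 3 alleles

    def test_exact_matches_enumeration(self):
        # small case: n=5, nA=4 -> enumerate heterozygote counts directly
        g = make_table(
            {"a": [(1, 1)], "b": [(1, 2)], "c": [(1, 2)], "d": [(2, 2)], "e": [(2, 2)]}
        )
        res = pc.hwe_test(g, "L1")
        # oracle: P(h | nA=4, n=5) proportional to 2^h * binomial structure
        from math import factorial

        def prob(h, na, n):
            nb = 2 * n - na
            return (
                2**h
                * factorial(n)
                / (factorial((na - h) // 2) * factorial(h) * factorial((nb - h) // 2))
                * factorial(na)
                * factorial(nb)
                / factorial(2 * n)
            )

        hs = [h for h in range(0, 5) if (4 - h) % 2 == 0]
        probs = {h: prob(h, 4, 5) for h in hs}
        z = sum(probs.values())
        obs = probs[2] / z
        expected_p = sum(v / z for v in probs.values() if v / z <= obs + 1e-12)
        assert res.p_value == pytest.approx(expected_p, abs=1e-9)


class TestWCTheta:
    def test_fixation_limit(self):
        rows = {f"a{k}": [(1, 1)] for k in range(10)}
        rows.update({f"b{k}": [(2, 2)] for k in range(10)})
        g = make_table(rows)
        pops = {i: i[0] for i in g.ids}
        res = pc.fst(g, pops, n_perm=0, filter_hwe=False, pairwise=False)
        assert res.theta == pytest.approx(1.0)

    def test_duplicated_population_near_zero(self, small_sim):
        _, genotypes, records, _ = small_sim
        ids = genotypes.ids[:60]
        g = genotypes.select(ids=ids)
        pops = {ind: ("A" if k % 2 == 0 else "B") for k, ind in enumerate(ids)}
        res = pc.fst(g, pops, n_perm=99, filter_hwe=False, pairwise=False,
                     rng=np.random.default_rng(0))
        assert abs(res.theta) < 0.02
        assert res.p_value > 0.05

    def test_components_match_naive_oracle(self, fixture30):
        g, pops = fixture30
        pops_dict = pops.to_dict()
        res = pc.fst(g, pops_dict, n_perm=0, filter_hwe=False, pairwise=False)
        theta_naive, comps = wc_theta_naive(g, pops_dict)
        assert res.theta == pytest.approx(theta_naive, abs=1e-12)
        for locus, (a, b, c) in zip(g.loci, comps):
            row = res.per_locus.loc[locus]
            assert row["a"] == pytest.approx(a, abs=1e-12)
            assert row["b"] == pytest.approx(b, abs=1e-12)
            assert row["c"] == pytest.approx(c, abs=1e-12)

    def test_three_pop_two_locus_microfixture_vs_oracle(self):
        g = make_table(
            {
                "a1": [(1, 1), (3, 4)], "a2": [(1, 2), (3, 3)], "a3": [(2, 2), (4, 4)],
                "b1": [(1, 1), (3, 3)], "b2": [(1, 1), (3, 4)], "b3": [(1, 2), (4, 4)],
                "c1": [(2, 2), (4, 4)], "c2": [(1, 2), (3, 4)], "c3": [(2, 2), (3, 3)],
            }
        )
        pops = {i: i[0] for i in g.ids}
        res = pc.fst(g, pops, n_perm=0, filter_hwe=False, pairwise=False)
        theta_naive, _ = wc_theta_naive(g, pops)
        assert res.theta == pytest.approx(theta_naive, abs=1e-12)

    def test_invariant_to_allele_relabeling_and_pop_order(self, fixture30):
        g, pops = fixture30
        pops_dict = pops.to_dict()
        base = pc.fst(g, pops_dict, n_perm=0, filter_hwe=False, pairwise=False).theta
        relabeled = pc.GenotypeTable(
            g.ids, g.loci, np.where(g.alleles == pc.MISSING, pc.MISSING, g.alleles * 3 + 7)
        )
        assert pc.fst(relabeled, pops_dict, n_perm=0, filter_hwe=False,
                      pairwise=False).theta == pytest.approx(base, abs=1e-12)
        renamed = {i: f"zz{p}" for i, p in pops_dict.items()}
        assert pc.fst(g, renamed, n_perm=0, filter_hwe=False,
                      pairwise=False).theta == pytest.approx(base, abs=1e-12)

    def test_pairwise_matrix_symmetric(self, small_sim):
        _, genotypes, records, _ = small_sim
        ids = genotypes.ids[:90]
        g = genotypes.select(ids=ids)
        res = pc.fst(g, records.loc[ids, "patch"], n_perm=0, filter_hwe=False)
        m = res.pairwise
        assert np.allclose(m.values, m.values.T, equal_nan=True)
        assert np.allclose(np.diag(m.values), 0.0)

    def test_isolation_increases_theta(self):
        # island model: strong migration must give lower theta than weak
        import warnings

        thetas = {}
        for m in (0.5, 0.0):
            vals = []
            for seed in range(3):
                cfg = pc.SimConfig(
                    rng_seed=seed, founders_per_patch=8, n_years=10, m_pollen=m,
                    capacity_per_patch=25,
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    g, rec, _ = pc.simulate(cfg)
                rf = pc.records_to_frame(rec)
                vals.append(
                    pc.fst(g, rf["patch"], n_perm=0, filter_hwe=False, pairwise=False).theta
                )
            thetas[m] = np.mean(vals)
        assert thetas[0.5] < thetas[0.0]

    def test_null_permutation_pvalues_uniform(self):
        # random partitions of one panmictic pool: p-values ~ U(0,1)
        rng = np.random.default_rng(11)
        freq = np.array([0.4, 0.3, 0.2, 0.1])
        pvals = []
        for _ in range(200):
            alleles = rng.choice(4, size=(30, 2, 2), p=freq) + 1
            g = pc.GenotypeTable(
                [f"i{k}" for k in range(30)], ["L1", "L2"],
                alleles.transpose(0, 2, 1).astype(np.int32),
            )
            pops = {f"i{k}": ("A" if k < 15 else "B") for k in range(30)}
            res = pc.fst(g, pops, n_perm=99, filter_hwe=False, pairwise=False, rng=rng)
            pvals.append(res.p_value)
        stat, p = stats.kstest(pvals, "uniform")
        assert p > 0.01
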