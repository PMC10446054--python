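"""Triad likelihoods against enumeration oracles, and assignment contracts."""

import itertools

import numpy as np
import pandas as pd
import pytest

import pedconnect as pc
from pedconnect import parentage
from pedconnect.parentage import _LocusModel, model_codes, triad_likelihood

from conftest import make_table


def hwe_table(rng, n, loci, extra=None):
    """Unrelated individuals drawn from given LocusSpec frequencies."""
    rows = {}
    for k in range(n):
        cells = []
        for spec in loci:
            a, b = rng.choice(len(spec.frequencies), size=2, p=spec.frequencies)
            cells.append((spec.allele_sizes[a], spec.allele_sizes[b]))
        rows[f"u{k:03d}"] = cells
    if extra:
        rows.update(extra)
    return make_table(rows, loci=[s.name for s in loci])


def mate(rng, spec_list, geno1, geno2):
    """Mendelian offspring of two genotype rows."""
    cells = []
    for j, _ in enumerate(spec_list):
        cells.append((geno1[j][rng.integers(2)], geno2[j][rng.integers(2)]))
    return cells


class TestTriadLikelihood:
    def _model(self, g):
        return _LocusModel(g, pc.allele_freqs(g))

    def test_forced_transmission_probability_one(self):
        g = make_table({"off": [(1, 2)], "p1": [(1, 1)], "p2": [(2, 2)]})
        ll = parentage.triad_loglik_from_table(g, "off", "p1", "p2", error_rate=0.0)
        assert ll == pytest.approx(0.0, abs=1e-12)

    def test_mendelian_exclusion_zero(self):
        g = make_table({"off": [(1, 1)], "p1": [(2, 2)], "p2": [(2, 2)]})
        ll = parentage.triad_loglik_from_table(g, "off", "p1", "p2", error_rate=0.0)
        assert ll == -np.inf

    def test_unsampled_parent_uses_hwe(self):
        # off AA, known parent AA, other unsampled: P = freq(A)
        g = make_table({"off": [(1, 1)], "p1": [(1, 1)], "x": [(1, 2)], "y": [(2, 2)]})
        freqs = pc.allele_freqs(g)
        pA = freqs.pooled("L1")[1]
        ll = parentage.triad_loglik_from_table(g, "off", "p1", None, error_rate=0.0)
        assert ll == pytest.approx(np.log(pA), abs=1e-12)

    def test_matches_enumeration_oracle_with_error(self):
        rng = np.random.default_rng(3)
        loci = pc.default_loci([4, 3, 5, 2, 6])
        g = hwe_table(rng, 12, loci)
        model = _LocusModel(g, pc.allele_freqs(g))
        e = 0.02

        def oracle(off_row, p1_row, p2_row):
            total_ll = 0.0
            for j in range(model.n_loci):
                off = model.codes[j][off_row]
                p1 = model.codes[j][p1_row]
                p2 = model.codes[j][p2_row]
                p = model.freq[j]
                k = p.size
                obs = (min(off), max(off))
                lik = 0.0
                # gametes from each parent, then independent per-allele error
                for x in p1:
                    for y in p2:
                        for u in range(k):  # observed copy from x
                            pu = (1 - e) * (u == x) + e * p[u]
                            for v in range(k):
                                pv = (1 - e) * (v == y) + e * p[v]
                                if (min(u, v), max(u, v)) == obs:
                                    lik += 0.25 * pu * pv
                total_ll += np.log(lik)
            return total_ll

        for off_row, p1_row, p2_row in [(0, 1, 2), (3, 4, 5), (6, 7, 8)]:
            got = triad_likelihood(
                model_codes(model, off_row), model_codes(model, p1_row),
                model_codes(model, p2_row), model, e,
            )
            assert got == pytest.approx(oracle(off_row, p1_row, p2_row), abs=1e-9)

    def test_missing_offspring_locus_skipped(self):
        g = make_table({"off": [(1, 2), None], "p1": [(1, 1), (9, 9)], "p2": [(2, 2), (8, 8)]})
        ll = parentage.triad_loglik_from_table(g, "off", "p1", "p2", error_rate=0.0)
        assert ll == pytest.approx(0.0, abs=1e-12)


@pytest.fixture(scope="module")
def clean_scenario():
    """Two unrelated parents, their offspring, and 20 unrelated candidates."""
    rng = np.random.default_rng(42)
    loci = pc.default_loci()  # 18 informative microsatellite loci
    mother = [
        tuple(
            spec.allele_sizes[a]
            for a in rng.choice(len(spec.frequencies), size=2, p=spec.frequencies)
        )
        for spec in loci
    ]
    father = [
        tuple(
            spec.allele_sizes[a]
            for a in rng.choice(len(spec.frequencies), size=2, p=spec.frequencies)
        )
        for spec in loci
    ]
    child = mate(rng, loci, mother, father)
    g = hwe_table(
        rng, 20, loci, extra={"mom": mother, "dad": father, "kid": child}
    )
    records = pd.DataFrame(
        {
            "patch": 1,
            "x": 0.0,
            "y": 0.0,
            "first_year": [2010] * 22 + [2015],
        },
        index=pd.Index(g.ids, name="id"),
    )
    return g, records


class TestAssignParents:
    def test_true_pair_recovered_above_095(self, clean_scenario):
        g, records = clean_scenario
        res = pc.assign_parents(g, records, pc.AssignmentConfig(error_rate=0.01))
        (a,) = [x for x in res.assignments if x.offspring == "kid"]
        assert {a.parent1, a.parent2} == {"mom", "dad"}
        assert a.posterior > 0.95

    def test_removed_parents_mean_no_triad(self, clean_scenario):
        g, records = clean_scenario
        keep = [i for i in g.ids if i not in ("mom", "dad")]
        res = pc.assign_parents(
            g.select(ids=keep), records.loc[keep], pc.AssignmentConfig(error_rate=0.01)
        )
        (a,) = [x for x in res.assignments if x.offspring == "kid"]
        assert a.n_identified == 0

    def test_identical_candidate_genotypes_split_posterior(self, clean_scenario):
        g, records = clean_scenario
        # clone both parents: two indistinguishable candidate pairs
        idx = g.id_index()
        alleles = np.concatenate(
            [g.alleles, g.alleles[idx["mom"]][None], g.alleles[idx["dad"]][None]], axis=0
        )
        g2 = pc.GenotypeTable(g.ids + ["mom2", "dad2"], g.loci, alleles)
        rec2 = pd.concat(
            [records, records.loc[["mom", "dad"]].rename(index={"mom": "mom2", "dad": "dad2"})]
        )
        res = pc.assign_parents(g2, rec2, pc.AssignmentConfig(error_rate=0.01))
        (a,) = [x for x in res.assignments if x.offspring == "kid"]
        assert a.n_identified == 0  # four equally good pairs, none above 0.95

    def test_posterior_sums_to_one(self, clean_scenario):
        g, records = clean_scenario
        res = pc.assign_parents(
            g, records, pc.AssignmentConfig(error_rate=0.01), keep_posteriors=True
        )
        for off, table in res.posteriors.items():
            assert table["posterior"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_threshold_monotone(self, small_sim):
        _, genotypes, records, _ = small_sim
        ids = genotypes.ids[:300]
        g = genotypes.select(ids=ids)
        rec = records.loc[ids]
        counts = []
        for thr in (0.6, 0.95, 0.999):
            res = pc.assign_parents(
                g, rec, pc.AssignmentConfig(posterior_threshold=thr)
            )
            counts.append(len(res.triads()))
        assert counts[0] >= counts[1] >= counts[2]

    def test_invariant_to_candidate_order(self, clean_scenario):
        g, records = clean_scenario
        rng = np.random.default_rng(0)
        perm = rng.permutation(g.n_individuals)
        ids = [g.ids[i] for i in perm]
        g2 = g.select(ids=ids)
        res1 = pc.assign_parents(g, records, pc.AssignmentConfig(error_rate=0.01))
        res2 = pc.assign_parents(g2, records.loc[ids], pc.AssignmentConfig(error_rate=0.01))
        a1 = {(a.offspring, frozenset((a.parent1, a.parent2))) for a in res1.triads()}
        a2 = {(a.offspring, frozenset((a.parent1, a.parent2))) for a in res2.triads()}
        assert a1 == a2

    def test_min_typed_loci_excludes_sparse_candidates(self):
        loci = pc.default_loci([3, 3, 3])
        rng = np.random.default_rng(1)
        g = hwe_table(rng, 5, loci)
        records = pd.DataFrame(
            {"patch": 1, "x": 0.0, "y": 0.0, "first_year": [2010] * 4 + [2015]},
            index=pd.Index(g.ids, name="id"),
        )
        res = pc.assign_parents(
            g, records, pc.AssignmentConfig(min_typed_loci=4, error_rate=0.01)
        )
        # only 3 loci available -> no candidate reaches 4 shared typed loci
        assert all(a.n_identified == 0 for a in res.assignments)


class TestAssignmentRates:
    def _records(self, ids, year=2015):
        return pd.DataFrame(
            {"patch": 1, "x": 0.0, "y": 0.0, "first_year": year},
            index=pd.Index(ids, name="id"),
        )

    def test_all_assigned_gives_zero_two_unidentified(self):
        res = parentage.AssignmentResult(
            assignments=[
                parentage.ParentageAssignment("a", "p", "q", 0.99, -1.0, 18, 0),
                parentage.ParentageAssignment("b", "p", "q", 0.99, -1.0, 18, 0),
            ],
            config=pc.AssignmentConfig(),
        )
        rates = pc.assignment_rates(res, self._records(["a", "b"]))
        row = rates[rates["year"] == 2015].iloc[0]
        assert row["frac_two_unidentified"] == 0.0
        assert row["frac_both_identified"] == 1.0

    def test_no_assignments_gives_fraction_one(self):
        res = parentage.AssignmentResult(assignments=[], config=pc.AssignmentConfig())
        rates = pc.assignment_rates(res, self._records(["a", "b"]))
        row = rates[rates["year"] == 2015].iloc[0]
        assert row["frac_two_unidentified"] == 1.0

    def test_deletion_experiment_matches_truth_expectation(self):
        """Deleting half the parents of a single-generation cohort pushes the
        two-parent assignment rate down to the truth-derived expectation:
        only offspring whose two parents survive the deletion can be triads
        (with unrelated candidates no substitute pair can clear 0.95)."""
        rng = np.random.default_rng(5)
        loci = pc.default_loci()
        founders = {}
        genos = []
        for k in range(60):
            geno = [
                tuple(
                    spec.allele_sizes[a]
                    for a in rng.choice(len(spec.frequencies), size=2, p=spec.frequencies)
                )
                for spec in loci
            ]
            founders[f"f{k:02d}"] = geno
            genos.append(geno)
        offspring_parents = {}
        rows = dict(founders)
        for k in range(100):
            i, j = rng.choice(60, size=2, replace=False)
            rows[f"o{k:02d}"] = mate(rng, loci, genos[i], genos[j])
            offspring_parents[f"o{k:02d}"] = {f"f{i:02d}", f"f{j:02d}"}
        g = make_table(rows, loci=[s.name for s in loci])
        records = pd.DataFrame(
            {
                "patch": 1, "x": 0.0, "y": 0.0,
                "first_year": [2010] * 60 + [2015] * 100,
            },
            index=pd.Index(g.ids, name="id"),
        )
        removed = {f"f{k:02d}" for k in rng.choice(60, size=30, replace=False)}
        keep = [i for i in g.ids if i not in removed]
        res = pc.assign_parents(
            g.select(ids=keep), records.loc[keep], pc.AssignmentConfig(error_rate=0.01)
        )
        triads = {a.offspring for a in res.triads()}
        expected_possible = {
            o for o, ps in offspring_parents.items() if not (ps & removed)
        }
        # every offspring with a deleted parent must stay unassigned,
        assert not (triads - expected_possible)
        # and the observed two-parent rate tracks the deletion expectation
        observed = len(triads) / 100
        expected = len(expected_possible) / 100
        assert observed == pytest.approx(expected, abs=0.05)
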