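"""Between-population statistics against brute-force oracles: explicit
Weir-Cockerham components, direct sums-of-squares partitions, contingency
table enumeration, and exact classical-MDS solutions."""
import itertools
import math

import numpy as np
import pytest
from scipy import stats

from adnapop import AdnapopError, UndefinedStatisticError
from adnapop.data_io import HaplotypeDataset
from adnapop.differentiation import (DistanceMatrix, amova_hierarchical,
                                     assign_lineage, chi2_yates,
                                     exact_genic_test, mc_exact_table_test,
                                     mds_from_phist, phi_st, wc_fst)

from conftest import haplotype_dataset_from_counts, two_pop_genotypes


# ---------------------------------------------------------------------------
# Weir & Cockerham theta
# ---------------------------------------------------------------------------

def wc_theta_oracle_two_pops(genos1, genos2):
    """Direct transcription of the two-population biallelic estimator:
    per-allele a/b/c components from sample sizes, frequencies and observed
    heterozygote proportions."""
    r = 2
    n1, n2 = len(genos1), len(genos2)
    nbar = (n1 + n2) / 2
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    alleles = sorted({x for g in genos1 + genos2 for x in g})
    A = B = C = 0.0
    for al in alleles:
        p1 = sum(g.count(al) for g in genos1) / (2 * n1)
        p2 = sum(g.count(al) for g in genos2) / (2 * n2)
        h1 = sum(1 for g in genos1 if (g[0] == al) != (g[1] == al)) / n1
        h2 = sum(1 for g in genos2 if (g[0] == al) != (g[1] == al)) / n2
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - 1 / (nbar - 1)
                           * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        A, B, C = A + a, B + b, C + hbar / 2
    return A / (A + B + C)


class TestWcFst:
    def test_identical_compositions_give_theta_at_or_below_zero(self):
        genos = [("A", "A"), ("A", "a"), ("a", "a"), ("A", "a")]
        ds = two_pop_genotypes({"p1": genos, "p2": genos})
        res = wc_fst(ds)
        assert res.theta <= 1e-12
        assert res.theta > -0.2

    def test_fixed_difference_gives_theta_one(self):
        ds = two_pop_genotypes({"p1": [("A", "A")] * 5, "p2": [("a", "a")] * 5})
        res = wc_fst(ds)
        assert res.theta == pytest.approx(1.0)
        locus = res.per_locus.iloc[0]
        assert locus["b"] == pytest.approx(0.0) and locus["c"] == pytest.approx(0.0)

    def test_matches_component_oracle_on_all_small_two_pop_datasets(self):
        genos = [("A", "A"), ("A", "a"), ("a", "a")]
        pools = []
        for n in (2, 3):
            pools += list(itertools.combinations_with_replacement(genos, n))
        checked = 0
        for g1, g2 in itertools.product(pools, repeat=2):
            alleles = {x for g in g1 + g2 for x in g}
            if len(alleles) < 2:
                continue
            ds = two_pop_genotypes({"p1": list(g1), "p2": list(g2)})
            denom_ok = True
            try:
                theta = wc_fst(ds).theta
            except UndefinedStatisticError:
                denom_ok = False
            if denom_ok:
                assert theta == pytest.approx(wc_theta_oracle_two_pops(list(g1), list(g2)),
                                              abs=1e-12)
                checked += 1
        assert checked > 100

    def test_monomorphic_everywhere_is_undefined(self):
        ds = two_pop_genotypes({"p1": [("A", "A")] * 3, "p2": [("A", "A")] * 3})
        with pytest.raises(UndefinedStatisticError):
            wc_fst(ds)


# ---------------------------------------------------------------------------
# Exact genic differentiation
# ---------------------------------------------------------------------------

def enumerate_table_exact_p(table):
    """Full enumeration oracle: P(tables as or less probable | margins)."""
    table = np.asarray(table)
    rows, cols = table.sum(1), table.sum(0)

    def log_prob(t):
        return -sum(math.lgamma(x + 1) for x in t.ravel())

    obs = log_prob(table)
    total_p = 0.0
    hit_p = 0.0
    const = (sum(math.lgamma(x + 1) for x in rows)
             + sum(math.lgamma(x + 1) for x in cols)
             - math.lgamma(table.sum() + 1))
    ranges = [range(min(rows[0], c) + 1) for c in cols]
    for top in itertools.product(*ranges):
        if sum(top) != rows[0]:
            continue
        bottom = cols - np.array(top)
        if np.any(bottom < 0):
            continue
        t = np.vstack([top, bottom])
        p = math.exp(const + log_prob(t))
        total_p += p
        if log_prob(t) <= obs + 1e-9:
            hit_p += p
    assert abs(total_p - 1) < 1e-9
    return hit_p


class TestExactGenicTest:
    def test_identical_allele_counts_give_p_near_one(self):
        genos = [("A", "A"), ("A", "a"), ("a", "a")] * 3
        ds = two_pop_genotypes({"p1": genos, "p2": genos})
        res = exact_genic_test(ds, mc_reps=2000, seed=0)
        assert res.p_overall > 0.5

    def test_alternately_fixed_alleles_highly_significant(self):
        ds = two_pop_genotypes({"p1": [("A", "A")] * 5, "p2": [("a", "a")] * 5})
        res = exact_genic_test(ds, mc_reps=20000, seed=0)
        # closed form two-sided value is 2 / C(20,10) ~ 1.1e-5
        assert res.per_locus["p"].iloc[0] < 1e-3

    @pytest.mark.parametrize("table", [
        [[3, 2, 1], [1, 2, 3]],
        [[4, 0, 2], [0, 4, 2]],
        [[1, 1, 1], [3, 3, 3]],
        [[5, 1, 0], [0, 1, 5]],
    ])
    def test_monte_carlo_within_3se_of_enumeration(self, table):
        exact = enumerate_table_exact_p(table)
        m = 8000
        p_mc = mc_exact_table_test(np.array(table), mc_reps=m, seed=3)
        se = math.sqrt(max(exact * (1 - exact), 1e-6) / m)
        assert abs(p_mc - exact) <= 3 * se + 2 / m


# ---------------------------------------------------------------------------
# Phi_ST and AMOVA
# ---------------------------------------------------------------------------

def ss_partition_oracle(ind_haps_by_pop, D, grouping=None):
    """Direct SS partition over expanded individuals (independent of the
    count-matrix shortcut used by the implementation)."""
    pops = list(ind_haps_by_pop)
    all_inds = [(p, h) for p in pops for h in ind_haps_by_pop[p]]
    N = len(all_inds)

    def ss(members):
        tot = 0.0
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                tot += D[members[i], members[j]]
        return tot / len(members)

    ss_total = ss([h for _, h in all_inds])
    ss_within = sum(ss(ind_haps_by_pop[p]) for p in pops)
    if grouping is None:
        return ss_total, ss_within
    groups = sorted({grouping[p] for p in pops})
    ss_wg = sum(ss([h for p in pops if grouping[p] == g
                    for h in ind_haps_by_pop[p]]) for g in groups)
    return ss_total, ss_within, ss_wg


class TestPhiSt:
    def _dataset(self, counts):
        haps = {"H1": "AAAA", "H2": "AAAT", "H3": "ATTT"}
        return haplotype_dataset_from_counts(counts, haps)

    def test_identical_compositions_give_phi_near_zero(self):
        ds = self._dataset({"p1": {"H1": 30, "H2": 20}, "p2": {"H1": 30, "H2": 20}})
        phi, p = phi_st(ds, ("p1", "p2"), n_perm=199, seed=0)
        assert abs(phi) < 0.05  # small negative values reflect estimator bias
        assert p > 0.3

    def test_fixed_distinct_haplotypes_give_phi_one(self):
        ds = self._dataset({"p1": {"H1": 4}, "p2": {"H3": 4}})
        phi, p = phi_st(ds, ("p1", "p2"), n_perm=499, seed=0)
        assert phi == pytest.approx(1.0)
        assert p < 0.05

    def test_matches_direct_ss_partition(self):
        ds = self._dataset({"p1": {"H1": 2, "H2": 2}, "p2": {"H2": 1, "H3": 3}})
        D = DistanceMatrix.from_haplotypes(ds).d.astype(float)
        phi, _ = phi_st(ds, ("p1", "p2"), n_perm=9, seed=0)
        inds = {"p1": [0, 0, 1, 1], "p2": [1, 2, 2, 2]}
        ss_total, ss_within = ss_partition_oracle(inds, D)
        n_tot, P = 8, 2
        ms_w = ss_within / (n_tot - P)
        ms_a = (ss_total - ss_within) / (P - 1)
        n_prime = (n_tot - (16 + 16) / n_tot) / (P - 1)
        sigma_a = (ms_a - ms_w) / n_prime
        assert phi == pytest.approx(sigma_a / (sigma_a + ms_w), abs=1e-10)

    def test_population_below_two_rejected(self):
        ds = self._dataset({"p1": {"H1": 1}, "p2": {"H2": 4}})
        with pytest.raises(AdnapopError):
            phi_st(ds, ("p1", "p2"), n_perm=9, seed=0)

    def test_null_permutation_pvalues_uniform(self, rng):
        # a haplotype pool rich enough that the permutation distribution is
        # nearly continuous; tiny pools give heavily tied, conservative p
        haps = {f"H{i + 1}": "".join(rng.choice(list("ACGT"), 20))
                for i in range(6)}
        freqs = [0.3, 0.25, 0.15, 0.1, 0.1, 0.1]
        pvals = []
        for _ in range(100):
            pool = rng.choice(6, size=16, p=freqs)
            counts = {}
            for name, arr in (("p1", pool[:8]), ("p2", pool[8:])):
                counts[name] = {f"H{i + 1}": int(np.sum(arr == i)) for i in range(6)
                                if np.sum(arr == i) > 0}
            ds = haplotype_dataset_from_counts(counts, haps)
            _, p = phi_st(ds, ("p1", "p2"), n_perm=199,
                          seed=int(rng.integers(2 ** 31)))
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 1e-3
        # and never anti-conservative at the usual level
        assert np.mean(np.array(pvals) <= 0.05) <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 100)


class TestHierarchicalAmova:
    haps = {"H1": "AAAAA", "H2": "AAAAT", "H3": "AATTT", "H4": "TTTTT"}

    def test_all_identical_sequences_degenerate_zero(self):
        ds = haplotype_dataset_from_counts(
            {"p1": {"H1": 3}, "p2": {"H1": 3}, "p3": {"H1": 3}, "p4": {"H1": 3}},
            {"H1": "AAAA"})
        res = amova_hierarchical(ds, {"p1": "g1", "p2": "g1", "p3": "g2", "p4": "g2"},
                                 n_perm=0, seed=0)
        assert res.degenerate
        assert res.sigma_a == res.sigma_b == res.sigma_c == 0.0

    def test_forced_partition_fct_one_fsc_zero(self):
        ds = haplotype_dataset_from_counts(
            {"p1": {"H1": 4}, "p2": {"H1": 4}, "p3": {"H4": 4}, "p4": {"H4": 4}},
            self.haps)
        res = amova_hierarchical(ds, {"p1": "g1", "p2": "g1", "p3": "g2", "p4": "g2"},
                                 n_perm=99, seed=1)
        assert res.f_ct == pytest.approx(1.0)
        assert res.f_sc == pytest.approx(0.0, abs=1e-12)

    def test_components_match_brute_force_partition(self, rng):
        for _ in range(10):
            counts = {}
            inds = {}
            for pi in range(4):
                draws = rng.integers(0, 4, size=int(rng.integers(3, 7)))
                inds[f"p{pi + 1}"] = list(draws)
                counts[f"p{pi + 1}"] = {f"H{h + 1}": int(np.sum(draws == h))
                                        for h in range(4) if np.sum(draws == h)}
            ds = haplotype_dataset_from_counts(counts, self.haps)
            grouping = {"p1": "g1", "p2": "g1", "p3": "g2", "p4": "g2"}
            res = amova_hierarchical(ds, grouping, n_perm=0, seed=0)
            D = DistanceMatrix.from_haplotypes(ds).d.astype(float)
            ss_total, ss_wp, ss_wg = ss_partition_oracle(inds, D, grouping)
            n_p = np.array([len(inds[p]) for p in counts])
            n_g = np.array([sum(len(inds[p]) for p in counts if grouping[p] == g)
                            for g in ("g1", "g2")])
            N, P, G = n_p.sum(), 4, 2
            sigma_c = ss_wp / (N - P)
            sum_np2_g = [sum(len(inds[p]) ** 2 for p in counts if grouping[p] == g)
                         / n_g[gi] for gi, g in enumerate(("g1", "g2"))]
            n1 = (N - sum(sum_np2_g)) / (P - G)
            sigma_b = ((ss_wg - ss_wp) / (P - G) - sigma_c) / n1
            n2 = (sum(sum_np2_g) - np.sum(n_p ** 2) / N) / (G - 1)
            n3 = (N - np.sum(n_g ** 2) / N) / (G - 1)
            sigma_a = ((ss_total - ss_wg) / (G - 1) - sigma_c - n2 * sigma_b) / n3
            assert res.sigma_c == pytest.approx(sigma_c, abs=1e-9)
            assert res.sigma_b == pytest.approx(sigma_b, abs=1e-9)
            assert res.sigma_a == pytest.approx(sigma_a, abs=1e-9)
            # SS additivity of the partition itself
            assert ss_total == pytest.approx(ss_wp + (ss_wg - ss_wp)
                                             + (ss_total - ss_wg), abs=1e-9)

    def test_one_group_per_population_reduces_to_phi_st(self):
        counts = {"p1": {"H1": 3, "H2": 2}, "p2": {"H3": 2, "H4": 3}}
        ds = haplotype_dataset_from_counts(counts, self.haps)
        res = amova_hierarchical(ds, {"p1": "g1", "p2": "g2"}, n_perm=0, seed=0)
        phi, _ = phi_st(ds, ("p1", "p2"), n_perm=9, seed=0)
        assert res.f_ct == pytest.approx(phi, abs=1e-12)

    def test_single_group_falls_back_with_warning_flag(self):
        counts = {"p1": {"H1": 3, "H2": 2}, "p2": {"H3": 2, "H4": 3}}
        ds = haplotype_dataset_from_counts(counts, self.haps)
        res = amova_hierarchical(ds, {"p1": "g1", "p2": "g1"}, n_perm=0, seed=0)
        assert res.degenerate
        assert res.f_st == pytest.approx(phi_st(ds, ("p1", "p2"), n_perm=9, seed=0)[0])


# ---------------------------------------------------------------------------
# MDS
# ---------------------------------------------------------------------------

class TestMds:
    def test_zero_matrix_degenerate(self):
        res = mds_from_phist(np.zeros((4, 4)))
        assert res.degenerate
        assert np.allclose(res.coordinates, 0)

    def test_equilateral_triangle_recovered_exactly(self):
        D = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        res = mds_from_phist(D)
        d = np.linalg.norm(res.coordinates[:, None] - res.coordinates[None], axis=-1)
        assert np.allclose(d[np.triu_indices(3, 1)], 1.0, atol=1e-9)
        assert res.r_squared == pytest.approx(1.0)
        assert np.allclose(res.coordinates.mean(axis=0), 0, atol=1e-12)

    def test_planar_points_recovered_with_high_r2(self, rng):
        pts = rng.normal(size=(4, 2))
        D = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        res = mds_from_phist(D)
        assert res.r_squared > 0.999
        assert res.stress < 1e-6

    def test_negative_entries_clipped_not_propagated(self):
        D = np.array([[0, -0.02, 0.5], [-0.02, 0, 0.5], [0.5, 0.5, 0]])
        res = mds_from_phist(D)
        assert np.isfinite(res.coordinates).all()

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(AdnapopError):
            mds_from_phist([[0, 1], [2, 0]])


# ---------------------------------------------------------------------------
# Lineage assignment
# ---------------------------------------------------------------------------

class TestAssignLineage:
    # alignment covers reference coordinates 15660..15860 (offset 15660)
    offset = 15660
    ref_states = {15670: "T", 15682: "T", 15823: "A", 15831: "C",
                  15838: "A", 15841: "T"}

    def _seq(self, overrides):
        seq = list("A" * 201)
        for pos, base in {**self.ref_states, **overrides}.items():
            seq[pos - self.offset] = base
        return "".join(seq)

    def test_c_lineage_diagnostics(self):
        seq = self._seq({15670: "C", 15823: "G", 15831: "T"})
        assert assign_lineage(seq, self.offset, self.ref_states).lineage == "C"

    def test_a_lineage_diagnostics(self):
        seq = self._seq({15682: "C", 15841: "C", 15838: "G"})
        assert assign_lineage(seq, self.offset, self.ref_states).lineage == "A"

    def test_reference_states_give_lineage_b(self):
        assert assign_lineage(self._seq({}), self.offset, self.ref_states).lineage == "B"

    def test_mixed_diagnostics_unassigned(self):
        seq = self._seq({15682: "C", 15670: "C"})  # one A-site + one C-site
        assert assign_lineage(seq, self.offset, self.ref_states).lineage == "unassigned"

    def test_ambiguity_at_diagnostic_site_unassigned(self):
        seq = self._seq({15670: "N"})
        assert assign_lineage(seq, self.offset, self.ref_states).lineage == "unassigned"

    def test_site_outside_alignment_is_an_error(self):
        with pytest.raises(AdnapopError, match="falls outside"):
            assign_lineage("ACGT", 15660, self.ref_states)


class TestChi2Yates:
    def test_balanced_table_gives_zero(self):
        chi2, df, p = chi2_yates([[10, 10], [10, 10]])
        assert chi2 == 0.0 and df == 1 and p == pytest.approx(1.0)

    def test_hand_computed_corrected_cells(self):
        chi2, df, p = chi2_yates([[20, 5], [10, 15]])
        assert chi2 == pytest.approx(6.75)
        assert df == 1
        assert p == pytest.approx(stats.chi2.sf(6.75, 1))

    def test_2xk_degrees_of_freedom(self):
        chi2, df, p = chi2_yates([[10, 12, 8, 9], [2, 3, 4, 1]])
        assert df == 3

    def test_zero_margin_rejected(self):
        with pytest.raises(AdnapopError):
            chi2_yates([[0, 0], [5, 5]])
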