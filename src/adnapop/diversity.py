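"""Within-population diversity statistics and Hardy-Weinberg exact testing.

Sequence side: haplotype diversity ``h = n(1 - sum p_i^2)/(n - 1)`` (Nei's
unbiased estimator) and nucleotide diversity ``pi``, the mean proportion of
differing sites over all unordered sequence pairs.  Sites carrying a gap or
ambiguity code in either member of a pair are excluded pairwise, with the
per-pair alignment length adjusted accordingly.

Genotype side: observed heterozygosity Ho, Nei's unbiased expected
heterozygosity ``He = 2n(1 - sum p_i^2)/(2n - 1)``, the within-population
inbreeding coefficient F_IS as Weir & Cockerham's small-sample ``f`` (the
``1 - Ho/He`` variant is also exposed), and exact Hardy-Weinberg tests:
full enumeration of the conditional genotype distribution for biallelic
loci, Monte-Carlo (allele shuffling) otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from ._util import VALID_BASES, UndefinedStatisticError, as_rng
from .data_io import GenotypeDataset, HaplotypeDataset


# ---------------------------------------------------------------------------
# Sequence diversity
# ---------------------------------------------------------------------------

def haplotype_diversity(counts) -> float:
    """Nei's unbiased haplotype diversity from a vector of haplotype counts."""
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    n = counts.sum()
    if n < 2:
        raise UndefinedStatisticError(f"haplotype diversity needs n >= 2, got n={int(n)}")
    p = counts / n
    return float(n * (1.0 - np.sum(p ** 2)) / (n - 1.0))


def _pairwise_site_stats(seq_a: str, seq_b: str) -> tuple[int, int]:
    """(differing sites, comparable sites) with pairwise deletion of
    non-ACGT positions."""
    a = np.frombuffer(seq_a.encode(), dtype="S1")
    b = np.frombuffer(seq_b.encode(), dtype="S1")
    valid_chars = np.array([c.encode() for c in sorted(VALID_BASES)], dtype="S1")
    ok = np.isin(a, valid_chars) & np.isin(b, valid_chars)
    diffs = int(np.sum((a != b) & ok))
    return diffs, int(ok.sum())


def nucleotide_diversity(dataset: HaplotypeDataset,
                         population: str | None = None) -> float:
    """Mean per-site pairwise difference (pi) for one population or pooled."""
    counts = dataset.count_vector(population)
    ids = dataset.haplotype_ids
    n = int(counts.sum())
    if n < 2:
        raise UndefinedStatisticError(f"nucleotide diversity needs n >= 2, got n={n}")
    if dataset.alignment_length < 1:
        raise UndefinedStatisticError("alignment length must be >= 1")
    total = 0.0
    for i, j in combinations(range(len(ids)), 2):
        if counts[i] == 0 or counts[j] == 0:
            continue
        d, L = _pairwise_site_stats(dataset.haplotypes[ids[i]],
                                    dataset.haplotypes[ids[j]])
        if L == 0:
            raise UndefinedStatisticError(
                f"haplotypes {ids[i]} and {ids[j]} share no comparable sites")
        total += counts[i] * counts[j] * (d / L)
    n_pairs = n * (n - 1) / 2
    return float(total / n_pairs)


def diversity_table(dataset: HaplotypeDataset) -> pd.DataFrame:
    """Per-population (plus pooled) n, haplotype count k, h and pi."""
    rows = []
    for pop in list(dataset.populations) + [None]:
        counts = dataset.count_vector(pop)
        n = int(counts.sum())
        k = int(np.sum(counts > 0))
        row = {"population": pop if pop is not None else "ALL", "n": n, "k": k}
        try:
            row["h"] = haplotype_diversity(counts)
            row["pi"] = nucleotide_diversity(dataset, pop)
        except UndefinedStatisticError:
            row["h"] = np.nan
            row["pi"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Genotype diversity
# ---------------------------------------------------------------------------

@dataclass
class DiversityResult:
    h: float
    pi: float
    n: int
    k: int
    per_population: pd.DataFrame | None = None


def _genotype_arrays(dataset: GenotypeDataset, locus: str,
                     population: str | None):
    genos = dataset.genotypes(locus, population)
    if not genos:
        raise UndefinedStatisticError(
            f"locus {locus}: no non-missing genotypes"
            + (f" in population {population}" if population else ""))
    return genos


def heterozygosities(dataset: GenotypeDataset, locus: str,
                     population: str | None = None) -> tuple[float, float]:
    """(Ho, He): observed het fraction and Nei's unbiased expected het."""
    genos = _genotype_arrays(dataset, locus, population)
    n = len(genos)
    ho = sum(1 for a, b in genos if a != b) / n
    counts = {}
    for a, b in genos:
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    p = np.array(list(counts.values()), dtype=float) / (2 * n)
    if n == 1:
        he = 0.0 if len(counts) == 1 else 1.0 - float(np.sum(p ** 2))
    else:
        he = 2 * n * (1.0 - float(np.sum(p ** 2))) / (2 * n - 1)
    return float(ho), float(he)


def _wc_single_pop_components(genos) -> tuple[float, float]:
    """Weir-Cockerham within-population components (b, c) summed over alleles
    for a single population; f = 1 - c/(b + c)."""
    n = len(genos)
    counts: dict[str, int] = {}
    het_counts: dict[str, int] = {}
    for a, b in genos:
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
        if a != b:
            het_counts[a] = het_counts.get(a, 0) + 1
            het_counts[b] = het_counts.get(b, 0) + 1
    b_sum = c_sum = 0.0
    for allele, cnt in counts.items():
        p = cnt / (2 * n)
        hbar = het_counts.get(allele, 0) / n
        b_sum += (n / (n - 1)) * (p * (1 - p) - (2 * n - 1) / (4 * n) * hbar)
        c_sum += hbar / 2
    return b_sum, c_sum


def fis(dataset: GenotypeDataset, locus: str,
        population: str | None = None) -> float:
    """Weir & Cockerham's small-sample inbreeding coefficient f at a locus."""
    genos = _genotype_arrays(dataset, locus, population)
    if len(genos) < 2:
        raise UndefinedStatisticError(f"locus {locus}: F_IS needs >= 2 genotypes")
    alleles = {a for g in genos for a in g}
    if len(alleles) < 2:
        raise UndefinedStatisticError(f"locus {locus}: monomorphic, F_IS undefined")
    b, c = _wc_single_pop_components(genos)
    if b + c == 0:
        raise UndefinedStatisticError(f"locus {locus}: zero within-population variance")
    return float(1.0 - c / (b + c))


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact tests
# ---------------------------------------------------------------------------

@dataclass
class HweResult:
    locus: str
    ho: float
    he: float
    fis: float | None
    fis_ho_he: float | None
    p_exact: float
    method: str           # enumeration | monte_carlo | monomorphic
    se: float | None = None
    monomorphic: bool = False


def _log_table_prob_const_part(genotype_counts: dict) -> float:
    """log P(genotype table | allele counts), Levene's conditional distribution.

    P = n! 2^het prod(a_i!) / ((2n)! prod(g_jk!)); only the table-dependent
    part (het * log 2 - sum log g!) is needed for comparisons, but the full
    value is returned for the biallelic enumeration.
    """
    n = sum(genotype_counts.values())
    allele_counts: dict[str, int] = {}
    het = 0
    for (a, b), g in genotype_counts.items():
        allele_counts[a] = allele_counts.get(a, 0) + g
        allele_counts[b] = allele_counts.get(b, 0) + g
        if a != b:
            het += g
    logp = (gammaln(n + 1) + het * np.log(2.0)
            + sum(gammaln(c + 1) for c in allele_counts.values())
            - gammaln(2 * n + 1)
            - sum(gammaln(g + 1) for g in genotype_counts.values()))
    return float(logp)


def hwe_exact_from_counts(genotype_counts: dict, mc_reps: int = 100_000,
                          seed=None) -> tuple[float, str, float | None]:
    """Exact HWE p-value from a {(allele_a, allele_b): count} table.

    Biallelic tables are fully enumerated (probability-ordered tail,
    conditional on allele counts); multiallelic tables use Monte-Carlo
    allele shuffling.  Returns (p, method, mc standard error).
    """
    genotype_counts = {tuple(sorted(k)): v for k, v in genotype_counts.items() if v > 0}
    alleles = sorted({a for g in genotype_counts for a in g})
    n = sum(genotype_counts.values())
    if len(alleles) < 2:
        return 1.0, "monomorphic", None
    if len(alleles) == 2:
        return _hwe_enumerate_biallelic(genotype_counts, alleles), "enumeration", None
    return _hwe_monte_carlo(genotype_counts, mc_reps, seed)


def _hwe_enumerate_biallelic(genotype_counts: dict, alleles: list) -> float:
    a1, a2 = alleles
    n = sum(genotype_counts.values())
    n11 = genotype_counts.get((a1, a1), 0)
    n12 = genotype_counts.get((a1, a2), 0)
    n22 = genotype_counts.get((a2, a2), 0)
    nA = 2 * n11 + n12
    na = 2 * n22 + n12
    obs_logp = _log_table_prob_const_part({(a1, a1): n11, (a1, a2): n12, (a2, a2): n22})
    max_het = min(nA, na)
    start = max_het % 2  # het count parity is fixed by the allele counts
    p = 0.0
    for het in range(start, max_het + 1, 2):
        t11 = (nA - het) // 2
        t22 = (na - het) // 2
        logp = _log_table_prob_const_part({(a1, a1): t11, (a1, a2): het, (a2, a2): t22})
        if logp <= obs_logp + 1e-9:
            p += np.exp(logp)
    return float(min(p, 1.0))


def _hwe_monte_carlo(genotype_counts: dict, mc_reps: int, seed):
    rng = as_rng(seed)
    allele_pool = []
    for (a, b), g in genotype_counts.items():
        allele_pool.extend([a] * g + [b] * g)
    allele_pool = np.array(allele_pool)
    n = sum(genotype_counts.values())

    def _stat(counts: dict) -> float:  # table-dependent part of log-probability
        het = sum(g for (a, b), g in counts.items() if a != b)
        return float(het * np.log(2.0) - sum(gammaln(g + 1) for g in counts.values()))

    obs = _stat(genotype_counts)
    hits = 0
    for _ in range(mc_reps):
        perm = rng.permutation(allele_pool)
        table: dict[tuple, int] = {}
        for i in range(n):
            key = tuple(sorted((perm[2 * i], perm[2 * i + 1])))
            table[key] = table.get(key, 0) + 1
        if _stat(table) <= obs + 1e-9:
            hits += 1
    p = (hits + 1) / (mc_reps + 1)
    se = float(np.sqrt(p * (1 - p) / mc_reps))
    return float(p), "monte_carlo", se


def hwe_exact(dataset: GenotypeDataset, locus: str,
              population: str | None = None, mc_reps: int = 100_000,
              seed=None) -> HweResult:
    """Exact HWE test plus Ho/He/F_IS bookkeeping for one locus."""
    genos = _genotype_arrays(dataset, locus, population)
    table: dict[tuple, int] = {}
    for g in genos:
        table[g] = table.get(g, 0) + 1
    ho, he = heterozygosities(dataset, locus, population)
    try:
        f = fis(dataset, locus, population)
    except UndefinedStatisticError:
        f = None
    fis_alt = 1.0 - ho / he if he > 0 else None
    p, method, se = hwe_exact_from_counts(table, mc_reps=mc_reps, seed=seed)
    return HweResult(locus=locus, ho=ho, he=he, fis=f, fis_ho_he=fis_alt,
                     p_exact=p, method=method, se=se,
                     monomorphic=(method == "monomorphic"))


def hwe_table(dataset: GenotypeDataset, mc_reps: int = 100_000,
              seed=None) -> pd.DataFrame:
    """One row per population x locus: n, Ho, He, f, 1-Ho/He, exact p."""
    rng = as_rng(seed)
    rows = []
    for pop in dataset.populations:
        for locus in dataset.loci:
            try:
                res = hwe_exact(dataset, locus, pop, mc_reps=mc_reps, seed=rng)
            except UndefinedStatisticError:
                continue
            n = len(dataset.genotypes(locus, pop))
            rows.append({"population": pop, "locus": locus, "n": n,
                         "Ho": res.ho, "He": res.he, "Fis": res.fis,
                         "Fis_1_minus_HoHe": res.fis_ho_he,
                         "p_exact": res.p_exact, "method": res.method})
    return pd.DataFrame(rows)
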