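"""Between-population structure.

* Weir & Cockerham's theta (F_ST) from variance components a/b/c, multi-locus
  as the ratio of summed components.
* Monte-Carlo exact tests of genic differentiation on allele-count
  contingency tables, per-locus p-values combined by Fisher's method.
* Phi_ST and hierarchical AMOVA from pairwise molecular distances, with
  permutation significance.  Negative variance components are retained in
  the F-ratios rather than truncated.
* Classical (Torgerson) multidimensional scaling of a Phi_ST matrix.
* Diagnostic-site lineage assignment for mtDNA haplotypes.
* Yates-corrected chi-square on 2 x k success/failure tables.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from ._util import VALID_BASES, AdnapopError, UndefinedStatisticError, as_rng
from .data_io import GenotypeDataset, HaplotypeDataset


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Pairwise site differences between haplotypes (pairwise deletion of
    non-ACGT positions)."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d)
        if self.d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("self-distances must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be >= 0")

    @classmethod
    def from_haplotypes(cls, dataset: HaplotypeDataset) -> "DistanceMatrix":
        ids = dataset.haplotype_ids
        arrs = []
        valid_chars = np.array([c.encode() for c in sorted(VALID_BASES)], dtype="S1")
        for h in ids:
            a = np.frombuffer(dataset.haplotypes[h].encode(), dtype="S1")
            arrs.append((a, np.isin(a, valid_chars)))
        k = len(ids)
        d = np.zeros((k, k), dtype=int)
        for i in range(k):
            for j in range(i + 1, k):
                ok = arrs[i][1] & arrs[j][1]
                d[i, j] = d[j, i] = int(np.sum((arrs[i][0] != arrs[j][0]) & ok))
        return cls(ids, d)


# ---------------------------------------------------------------------------
# Weir & Cockerham theta
# ---------------------------------------------------------------------------

@dataclass
class WcFstResult:
    theta: float
    per_locus: pd.DataFrame  # locus, a, b, c, theta


def _wc_locus_components(pop_genotypes: list[list[tuple[str, str]]]):
    """Summed (a, b, c) variance components over alleles for one locus.

    ``pop_genotypes`` holds the non-missing genotype tuples of each
    population.  Populations without data are dropped.
    """
    pops = [g for g in pop_genotypes if g]
    r = len(pops)
    if r < 2:
        raise UndefinedStatisticError("theta needs >= 2 populations with data")
    n_i = np.array([len(g) for g in pops], dtype=float)
    nbar = n_i.mean()
    if nbar <= 1:
        raise UndefinedStatisticError("theta needs more than one genotype per population")
    nc = (r * nbar - np.sum(n_i ** 2) / (r * nbar)) / (r - 1)
    alleles = sorted({a for pop in pops for g in pop for a in g})
    a_sum = b_sum = c_sum = 0.0
    for allele in alleles:
        p_i = np.array([sum((a == allele) + (b == allele) for a, b in pop) / (2 * n)
                        for pop, n in zip(pops, n_i)])
        h_i = np.array([sum(1 for a, b in pop if (a == allele) != (b == allele)) / n
                        for pop, n in zip(pops, n_i)])
        pbar = np.sum(n_i * p_i) / (r * nbar)
        s2 = np.sum(n_i * (p_i - pbar) ** 2) / ((r - 1) * nbar)
        hbar = np.sum(n_i * h_i) / (r * nbar)
        a_sum += (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                                / (nbar - 1))
        b_sum += (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                        - (2 * nbar - 1) / (4 * nbar) * hbar)
        c_sum += hbar / 2
    return a_sum, b_sum, c_sum


def wc_fst(dataset: GenotypeDataset,
           populations: list[str] | None = None) -> WcFstResult:
    """Multi-locus Weir-Cockerham theta as the ratio of summed components."""
    dataset.require_single_run("Weir-Cockerham theta")
    pops = populations if populations is not None else dataset.populations
    if len(pops) < 2:
        raise UndefinedStatisticError("theta needs >= 2 populations")
    rows = []
    tot_a = tot_abc = 0.0
    for locus in dataset.loci:
        pop_genos = [dataset.genotypes(locus, p) for p in pops]
        alleles = {al for pg in pop_genos for g in pg for al in g}
        if len(alleles) < 2:
            continue  # monomorphic locus carries no information
        a, b, c = _wc_locus_components(pop_genos)
        denom = a + b + c
        rows.append({"locus": locus, "a": a, "b": b, "c": c,
                     "theta": a / denom if denom != 0 else np.nan})
        tot_a += a
        tot_abc += denom
    if not rows or tot_abc == 0:
        raise UndefinedStatisticError("all loci monomorphic: theta undefined")
    return WcFstResult(theta=float(tot_a / tot_abc), per_locus=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Exact genic differentiation
# ---------------------------------------------------------------------------

@dataclass
class GenicTestResult:
    p_overall: float
    per_locus: pd.DataFrame  # locus, p, method
    method: str = "fisher_combination"


def _log_table_prob(table: np.ndarray) -> float:
    """log probability of a contingency table under fixed margins
    (multivariate hypergeometric); constant terms depending only on the
    margins are omitted."""
    return float(-np.sum(gammaln(table + 1.0)))


def mc_exact_table_test(table: np.ndarray, mc_reps: int = 10_000,
                        seed=None) -> float:
    """Monte-Carlo exact test on an r x c allele-count table: probability of
    tables as or less probable than the observed, conditional on margins."""
    table = np.asarray(table, dtype=int)
    if table.sum() == 0:
        raise AdnapopError("empty contingency table")
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    keep_r, keep_c = rows > 0, cols > 0
    table = table[keep_r][:, keep_c]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 1.0  # no variation to test
    rng = as_rng(seed)
    sampler = stats.random_table(table.sum(axis=1), table.sum(axis=0))
    sims = sampler.rvs(mc_reps, random_state=rng)
    obs = _log_table_prob(table)
    sim_logp = -np.sum(gammaln(sims + 1.0), axis=(1, 2))
    hits = int(np.sum(sim_logp <= obs + 1e-9))
    return float((hits + 1) / (mc_reps + 1))


def fisher_combine(p_values) -> float:
    """Fisher's method across independent tests."""
    p = np.asarray([x for x in p_values if not np.isnan(x)], dtype=float)
    if p.size == 0:
        return float("nan")
    chi2 = -2.0 * np.sum(np.log(np.clip(p, 1e-300, 1.0)))
    return float(stats.chi2.sf(chi2, 2 * p.size))


def exact_genic_test(dataset: GenotypeDataset,
                     pop_pair: tuple[str, str] | None = None,
                     mc_reps: int = 10_000, seed=None) -> GenicTestResult:
    """Exact test of genic differentiation between two populations.

    Builds the alleles x populations count table per locus, applies the
    Monte-Carlo exact test, and combines loci by Fisher's method.
    """
    dataset.require_single_run("exact genic test")
    pops = list(pop_pair) if pop_pair is not None else dataset.populations
    if len(pops) != 2:
        raise AdnapopError("exact_genic_test compares exactly two populations")
    rng = as_rng(seed)
    rows = []
    for locus in dataset.loci:
        counts = [dataset.allele_counts(locus, p) for p in pops]
        alleles = sorted(set(counts[0]) | set(counts[1]))
        if not alleles:
            raise AdnapopError(f"locus {locus}: empty allele table")
        table = np.array([[c.get(a, 0) for a in alleles] for c in counts])
        p = mc_exact_table_test(table, mc_reps=mc_reps, seed=rng)
        rows.append({"locus": locus, "p": p})
    per_locus = pd.DataFrame(rows)
    return GenicTestResult(p_overall=fisher_combine(per_locus["p"]),
                           per_locus=per_locus)


# ---------------------------------------------------------------------------
# AMOVA / Phi_ST
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    sigma_a: float          # among groups
    sigma_b: float          # among populations within groups
    sigma_c: float          # within populations
    f_ct: float
    f_sc: float
    f_st: float
    p_ct: float | None = None
    p_sc: float | None = None
    p_st: float | None = None
    n_permutations: int = 0
    degenerate: bool = False


def _pair_sum(counts: np.ndarray, D: np.ndarray) -> float:
    """Sum of pairwise distances over all unordered individual pairs in a
    pooled set described by haplotype counts (same-haplotype pairs are 0)."""
    return 0.5 * float(counts @ D @ counts)


def _one_level_ss(count_matrix: np.ndarray, D: np.ndarray):
    """(SSD_total, SSD_within, n_total, pop sizes) for pops x haplotypes counts."""
    n_p = count_matrix.sum(axis=1).astype(float)
    n_tot = n_p.sum()
    pooled = count_matrix.sum(axis=0).astype(float)
    ss_total = _pair_sum(pooled, D) / n_tot
    ss_within = sum(_pair_sum(count_matrix[i].astype(float), D) / n_p[i]
                    for i in range(count_matrix.shape[0]) if n_p[i] > 0)
    return ss_total, ss_within, n_tot, n_p


def _phi_from_counts(count_matrix: np.ndarray, D: np.ndarray) -> float:
    """One-level AMOVA Phi_ST from a pops x haplotypes count matrix."""
    P = count_matrix.shape[0]
    ss_total, ss_within, n_tot, n_p = _one_level_ss(count_matrix, D)
    df_among, df_within = P - 1, n_tot - P
    if df_within <= 0:
        raise UndefinedStatisticError("Phi_ST needs n > number of populations")
    ms_within = ss_within / df_within
    ms_among = (ss_total - ss_within) / df_among
    n_prime = (n_tot - np.sum(n_p ** 2) / n_tot) / df_among
    sigma_a = (ms_among - ms_within) / n_prime
    denom = sigma_a + ms_within
    if denom == 0:
        return 0.0
    return float(sigma_a / denom)


def phi_st(dataset: HaplotypeDataset, pop_pair: tuple[str, str],
           distances: DistanceMatrix | None = None,
           n_perm: int = 10_000, seed=None) -> tuple[float, float]:
    """Pairwise Phi_ST between two populations with a permutation p-value
    (individuals permuted between the populations; p = (b+1)/(m+1))."""
    if distances is None:
        distances = DistanceMatrix.from_haplotypes(dataset)
    if distances.ids != dataset.haplotype_ids:
        raise AdnapopError("distance matrix ids do not match dataset haplotypes")
    counts = np.vstack([dataset.count_vector(p) for p in pop_pair])
    n_p = counts.sum(axis=1)
    if np.any(n_p < 2):
        raise AdnapopError("both populations need n >= 2 for Phi_ST")
    D = distances.d.astype(float)
    obs = _phi_from_counts(counts, D)
    rng = as_rng(seed)
    # expand to individual haplotype indices for label permutation
    pooled = counts.sum(axis=0)
    individuals = np.repeat(np.arange(len(pooled)), pooled)
    k = len(pooled)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(individuals)
        c1 = np.bincount(perm[: n_p[0]], minlength=k)
        c2 = np.bincount(perm[n_p[0]:], minlength=k)
        if _phi_from_counts(np.vstack([c1, c2]), D) >= obs - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return float(obs), float(p)


def _hier_components(counts_by_pop: np.ndarray, pop_group: np.ndarray,
                     D: np.ndarray):
    """Three-level AMOVA variance components (sigma_a, sigma_b, sigma_c)
    from a pops x haplotypes count matrix and a pop -> group index vector."""
    P = counts_by_pop.shape[0]
    groups = np.unique(pop_group)
    G = len(groups)
    n_p = counts_by_pop.sum(axis=1).astype(float)
    n_tot = n_p.sum()
    pooled = counts_by_pop.sum(axis=0).astype(float)

    ss_total = _pair_sum(pooled, D) / n_tot
    ss_wp = sum(_pair_sum(counts_by_pop[i].astype(float), D) / n_p[i]
                for i in range(P) if n_p[i] > 0)
    ss_wg = 0.0
    n_g = np.zeros(G)
    for gi, g in enumerate(groups):
        sel = pop_group == g
        gc = counts_by_pop[sel].sum(axis=0).astype(float)
        n_g[gi] = gc.sum()
        ss_wg += _pair_sum(gc, D) / n_g[gi]
    ss_ap = ss_wg - ss_wp          # among populations within groups
    ss_ag = ss_total - ss_wg       # among groups

    df_ag, df_ap, df_wp = G - 1, P - G, n_tot - P
    if df_wp <= 0:
        raise UndefinedStatisticError("AMOVA needs n > number of populations")
    sigma_c = ss_wp / df_wp
    # coefficients of the expected mean squares (unbalanced design)
    sum_np2_by_group = np.zeros(G)
    for gi, g in enumerate(groups):
        sel = pop_group == g
        sum_np2_by_group[gi] = np.sum(n_p[sel] ** 2) / n_g[gi]
    if df_ap > 0:
        n_prime = (n_tot - np.sum(sum_np2_by_group)) / df_ap
        sigma_b = (ss_ap / df_ap - sigma_c) / n_prime
    else:
        sigma_b = 0.0
    if df_ag > 0:
        n_dprime = (np.sum(sum_np2_by_group) - np.sum(n_p ** 2) / n_tot) / df_ag
        n_tprime = (n_tot - np.sum(n_g ** 2) / n_tot) / df_ag
        sigma_a = (ss_ag / df_ag - sigma_c - n_dprime * sigma_b) / n_tprime
    else:
        sigma_a = 0.0
    return float(sigma_a), float(sigma_b), float(sigma_c)


def amova_hierarchical(dataset: HaplotypeDataset,
                       grouping: dict[str, str],
                       distances: DistanceMatrix | None = None,
                       n_perm: int = 10_000, seed=None) -> AmovaResult:
    """Hierarchical AMOVA: groups / populations within groups / individuals.

    Permutation schemes: whole populations among groups for F_CT;
    individuals among populations within their group for F_SC; individuals
    among all populations for F_ST.  A single-group grouping degrades to the
    one-level analysis (F_SC/F_CT flagged degenerate).
    """
    if distances is None:
        distances = DistanceMatrix.from_haplotypes(dataset)
    pops = dataset.populations
    missing = [p for p in pops if p not in grouping]
    if missing:
        raise AdnapopError(f"populations without group assignment: {missing}")
    group_labels = sorted({grouping[p] for p in pops})
    pop_group = np.array([group_labels.index(grouping[p]) for p in pops])
    counts = dataset.count_matrix().astype(float)
    D = distances.d.astype(float)
    rng = as_rng(seed)

    if len(group_labels) < 2:
        phi = _phi_from_counts(counts, D)
        # one-level fallback: report Phi_ST only
        sigma_c = _one_level_ss(counts, D)[1] / (counts.sum() - len(pops))
        return AmovaResult(sigma_a=0.0, sigma_b=np.nan, sigma_c=float(sigma_c),
                           f_ct=np.nan, f_sc=np.nan, f_st=float(phi),
                           degenerate=True)

    sigma_a, sigma_b, sigma_c = _hier_components(counts, pop_group, D)
    total = sigma_a + sigma_b + sigma_c
    if total == 0:
        return AmovaResult(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, degenerate=True)
    f_ct = sigma_a / total
    f_sc = sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) != 0 else 0.0
    f_st = (sigma_a + sigma_b) / total

    n_p = counts.sum(axis=1).astype(int)
    k = counts.shape[1]
    individuals = [np.repeat(np.arange(k), counts[i].astype(int))
                   for i in range(len(pops))]

    hits_st = hits_sc = hits_ct = 0
    for _ in range(n_perm):
        # F_ST: individuals among all populations
        pool = rng.permutation(np.concatenate(individuals))
        newc = np.vstack([np.bincount(pool[s - n: s], minlength=k)
                          for s, n in zip(np.cumsum(n_p), n_p)]).astype(float)
        sa, sb, sc = _hier_components(newc, pop_group, D)
        t = sa + sb + sc
        if t != 0 and (sa + sb) / t >= f_st - 1e-12:
            hits_st += 1
        # F_SC: individuals among populations within groups
        newc2 = counts.copy()
        for gi in range(len(group_labels)):
            sel = np.where(pop_group == gi)[0]
            if len(sel) < 2:
                continue
            pool_g = rng.permutation(np.concatenate([individuals[i] for i in sel]))
            sizes = n_p[sel]
            for row, s, n in zip(sel, np.cumsum(sizes), sizes):
                newc2[row] = np.bincount(pool_g[s - n: s], minlength=k)
        sa, sb, sc = _hier_components(newc2, pop_group, D)
        if (sb + sc) != 0 and sb / (sb + sc) >= f_sc - 1e-12:
            hits_sc += 1
        # F_CT: whole populations among groups
        perm_groups = rng.permutation(pop_group)
        sa, sb, sc = _hier_components(counts, perm_groups, D)
        t = sa + sb + sc
        if t != 0 and sa / t >= f_ct - 1e-12:
            hits_ct += 1

    m = n_perm
    return AmovaResult(sigma_a=sigma_a, sigma_b=sigma_b, sigma_c=sigma_c,
                       f_ct=float(f_ct), f_sc=float(f_sc), f_st=float(f_st),
                       p_ct=(hits_ct + 1) / (m + 1),
                       p_sc=(hits_sc + 1) / (m + 1),
                       p_st=(hits_st + 1) / (m + 1),
                       n_permutations=n_perm)


def amova_table(result: AmovaResult) -> pd.DataFrame:
    """Three-row summary mirroring the conventional hierarchical layout."""
    return pd.DataFrame([
        {"source": "Among populations (F_ST)", "statistic": result.f_st,
         "sigma2": result.sigma_a + result.sigma_b, "p": result.p_st},
        {"source": "Among populations within groups (F_SC)",
         "statistic": result.f_sc, "sigma2": result.sigma_b, "p": result.p_sc},
        {"source": "Between groups (F_CT)", "statistic": result.f_ct,
         "sigma2": result.sigma_a, "p": result.p_ct},
    ])


# ---------------------------------------------------------------------------
# Classical MDS
# ---------------------------------------------------------------------------

@dataclass
class MdsResult:
    ids: list[str]
    coordinates: np.ndarray   # n x 2, centred at the origin
    r_squared: float
    stress: float
    degenerate: bool = False


def mds_from_phist(matrix, ids: list[str] | None = None) -> MdsResult:
    """Classical (double-centering) 2-D embedding of a Phi_ST matrix.

    Negative entries are clipped to 0 before embedding; r^2 is the squared
    Pearson correlation between embedded and input distances and stress is
    Kruskal's stress-1.
    """
    D = np.asarray(matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise AdnapopError("Phi_ST matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise AdnapopError("Phi_ST matrix must be symmetric")
    n = D.shape[0]
    if ids is None:
        ids = [f"P{i + 1}" for i in range(n)]
    D = np.clip(D, 0.0, None)
    np.fill_diagonal(D, 0.0)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    lam = np.clip(vals[:2], 0.0, None)
    coords = vecs[:, :2] * np.sqrt(lam)
    coords -= coords.mean(axis=0)
    iu = np.triu_indices(n, k=1)
    d_in = D[iu]
    d_hat = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))[iu]
    if np.allclose(d_in, 0.0):
        return MdsResult(ids, np.zeros((n, 2)), float("nan"), 0.0, degenerate=True)
    if np.std(d_in) == 0 or np.std(d_hat) == 0:
        # constant distances: correlation undefined; perfect reconstruction
        # still deserves r^2 = 1 (e.g. an equilateral configuration)
        r2 = 1.0 if np.allclose(d_in, d_hat, atol=1e-8) else 0.0
    else:
        r2 = float(np.corrcoef(d_in, d_hat)[0, 1] ** 2)
    stress = float(np.sqrt(np.sum((d_in - d_hat) ** 2) / np.sum(d_in ** 2)))
    return MdsResult(ids, coords, r2, stress)


# ---------------------------------------------------------------------------
# Lineage assignment
# ---------------------------------------------------------------------------

# Diagnostic D-loop polymorphisms (positions on the Pacific-herring
# mitochondrial reference NC_009578, 1-based): lineage A and lineage C are
# each defined by three sites; lineage B matches the reference state at all
# six.  The reference states must be supplied (e.g. from an aligned copy of
# the reference), since only the derived states are fixed here.
DEFAULT_DIAGNOSTICS = {
    "A": {15682: "C", 15841: "C", 15838: "G"},
    "C": {15670: "C", 15823: "G", 15831: "T"},
}


@dataclass
class LineageCall:
    haplotype_id: str
    lineage: str                      # A | B | C | unassigned
    matched_sites: dict[int, str] = field(default_factory=dict)


def assign_lineage(sequence: str, offset: int,
                   reference_states: dict[int, str],
                   diagnostics: dict[str, dict[int, str]] | None = None,
                   haplotype_id: str = "") -> LineageCall:
    """Assign an mtDNA haplotype to lineage A, B or C from diagnostic sites.

    ``offset`` translates reference coordinates (1-based) into 0-based
    alignment positions: alignment index = position - offset.  A (then C) is
    called when *all* of that lineage's derived states match; B when the
    sequence carries the reference state at every diagnostic site; anything
    else (including ambiguity codes at diagnostic sites) is unassigned.
    """
    if diagnostics is None:
        diagnostics = DEFAULT_DIAGNOSTICS
    seq = sequence.upper()
    all_sites = sorted({p for tbl in diagnostics.values() for p in tbl}
                       | set(reference_states))

    def base_at(pos: int) -> str:
        idx = pos - offset
        if not 0 <= idx < len(seq):
            raise AdnapopError(
                f"diagnostic site {pos} falls outside the alignment "
                f"(index {idx}, length {len(seq)})")
        return seq[idx]

    for lineage in ("A", "C"):
        tbl = diagnostics.get(lineage, {})
        if tbl and all(base_at(p) == b for p, b in tbl.items()):
            return LineageCall(haplotype_id, lineage,
                               {p: base_at(p) for p in tbl})
    if all(p in reference_states and base_at(p) == reference_states[p]
           for p in all_sites):
        return LineageCall(haplotype_id, "B", {p: base_at(p) for p in all_sites})
    return LineageCall(haplotype_id, "unassigned",
                       {p: base_at(p) for p in all_sites})


# ---------------------------------------------------------------------------
# Yates-corrected chi-square
# ---------------------------------------------------------------------------

def chi2_yates(table) -> tuple[float, int, float]:
    """Yates-corrected chi-square on a 2 x k success/failure table.

    Statistic sum((|O-E| - 0.5)^2 / E) with the correction floored at zero,
    df = k - 1, upper-tail p.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] != 2 or obs.shape[1] < 2:
        raise AdnapopError("chi2_yates expects a 2 x k table with k >= 2")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise AdnapopError("chi2_yates: zero margin in contingency table")
    expected = np.outer(rows, cols) / obs.sum()
    corrected = np.clip(np.abs(obs - expected) - 0.5, 0.0, None)
    chi2 = float(np.sum(corrected ** 2 / expected))
    df = obs.shape[1] - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))
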