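"""Ancient-DNA genotyping quality control.

Degraded template produces three characteristic artefacts that this module
quantifies: allelic dropout (a heterozygote typed as a false homozygote,
preferentially hitting long microsatellite alleles), PCR stutter (alleles
shifted by one repeat unit), and miscoding lesions in sequence data
("Type 2" C->T/G->A transitions from cytosine deamination, "Type 1" A->G/T->C
transitions, and transversions).  The multitube defence against dropout is
replicate PCRs per sample with consensus rules; the per-reaction error rate
divides allelic mismatches against the consensus by the total number of
allele draws (ploidy x reactions), so a het scored as hom in one run is one
allelic mismatch.  A per-genotype discrepancy rate (discrepant samples /
samples compared) is reported alongside under its own name - the two are
deliberately not interchangeable.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import VALID_BASES, AdnapopError, as_rng, round_half_away
from .data_io import GenotypeDataset


# ---------------------------------------------------------------------------
# Consensus genotyping
# ---------------------------------------------------------------------------

@dataclass
class ConsensusCall:
    sample_id: str
    locus: str
    genotype: tuple[str, str] | None     # None == undetermined
    n_runs_used: int
    rule_fired: str  # duplicate_agreement | two_of_three | het_confirmed_third_run | undetermined


def consensus_genotype(runs, mode: str = "ancient_triplicate",
                       sample_id: str = "", locus: str = "") -> ConsensusCall:
    """Multitube consensus from 1-4 replicate run calls.

    ``modern_duplicate``: both of two (or more) runs must agree.
    ``ancient_triplicate``: any genotype called in >= 2 runs wins; a
    heterozygote/homozygote conflict resolved in the heterozygote's favour
    by an extra run is flagged ``het_confirmed_third_run``.  No majority
    (or no data) yields an undetermined call, not an error.
    """
    if not 1 <= len(runs) <= 4:
        raise AdnapopError("consensus expects 1-4 replicate run calls")
    calls = [tuple(sorted(g)) if g is not None else None for g in runs]
    present = [g for g in calls if g is not None]
    undet = ConsensusCall(sample_id, locus, None, len(present), "undetermined")
    if not present:
        return undet

    if mode == "modern_duplicate":
        if len(present) >= 2 and len(set(present)) == 1:
            return ConsensusCall(sample_id, locus, present[0], len(present),
                                 "duplicate_agreement")
        return undet
    if mode != "ancient_triplicate":
        raise ValueError(f"unknown consensus mode: {mode!r}")

    tally = Counter(present)
    winners = [g for g, c in tally.items() if c >= 2]
    if len(winners) != 1:
        return undet
    winner = winners[0]
    if len(present) >= 2 and len(set(present)) == 1:
        rule = "duplicate_agreement"
    elif winner[0] != winner[1] and any(g[0] == g[1] for g in present if g != winner):
        rule = "het_confirmed_third_run"
    else:
        rule = "two_of_three"
    return ConsensusCall(sample_id, locus, winner, len(present), rule)


def consensus_dataset(dataset: GenotypeDataset,
                      mode: str = "ancient_triplicate"
                      ) -> tuple[GenotypeDataset, list[ConsensusCall]]:
    """Collapse replicate runs to one consensus genotype per sample x locus."""
    pop_of = dataset.population_of()
    rows, calls = [], []
    for locus in dataset.loci:
        for sample, runs in dataset.runs_by_sample(locus).items():
            call = consensus_genotype(runs[:4], mode=mode,
                                      sample_id=sample, locus=locus)
            calls.append(call)
            a, b = call.genotype if call.genotype else (None, None)
            rows.append({"sample_id": sample, "population": pop_of[sample],
                         "locus": locus, "run_id": "consensus",
                         "allele_a": a, "allele_b": b})
    return GenotypeDataset(pd.DataFrame(rows)), calls


# ---------------------------------------------------------------------------
# Replicate error rates
# ---------------------------------------------------------------------------

@dataclass
class ReplicateComparison:
    locus: str
    n_samples_compared: int
    n_reactions: int
    ploidy: int
    allelic_mismatches: int
    discrepant_genotypes: int
    error_rate_per_reaction: float
    genotype_discrepancy_rate: float


def _allele_mismatch(g: tuple[str, str], ref: tuple[str, str]) -> int:
    """Allelic mismatches between two genotypes as multisets (het vs hom
    sharing an allele = 1)."""
    rem = list(ref)
    miss = 0
    for a in g:
        if a in rem:
            rem.remove(a)
        else:
            miss += 1
    return miss


def error_rate_per_reaction(runs_by_sample: dict, ploidy: int = 2,
                            consensus: dict | None = None,
                            locus: str = "") -> ReplicateComparison:
    """Per-reaction error rate from replicate runs.

    Mismatches are counted against each sample's consensus genotype; when no
    majority exists among the replicates the reference is the observed
    genotype minimising total mismatches (for two discrepant runs this
    attributes the minimal number of allele errors, e.g. one for a het/hom
    conflict).  Rate = allelic mismatches / (ploidy x reactions) over all
    samples with >= 2 non-missing runs.
    """
    n_reactions = 0
    mismatches = 0
    discrepant = 0
    n_samples = 0
    for sample, runs in runs_by_sample.items():
        present = [tuple(sorted(g)) for g in runs if g is not None]
        if len(present) < 2:
            continue
        n_samples += 1
        n_reactions += len(present)
        ref = None
        if consensus is not None and consensus.get(sample) is not None:
            ref = tuple(sorted(consensus[sample]))
        else:
            tally = Counter(present)
            top, top_n = tally.most_common(1)[0]
            if top_n >= 2:
                ref = top
            else:
                ref = min(set(present),
                          key=lambda cand: (sum(_allele_mismatch(g, cand)
                                                for g in present), cand))
        mm = sum(_allele_mismatch(g, ref) for g in present)
        mismatches += mm
        if len(set(present)) > 1:
            discrepant += 1
    if n_samples == 0:
        raise AdnapopError("no samples with replicate runs to compare")
    return ReplicateComparison(
        locus=locus, n_samples_compared=n_samples, n_reactions=n_reactions,
        ploidy=ploidy, allelic_mismatches=mismatches,
        discrepant_genotypes=discrepant,
        error_rate_per_reaction=mismatches / (ploidy * n_reactions),
        genotype_discrepancy_rate=discrepant / n_samples)


# ---------------------------------------------------------------------------
# Dropout / stutter screen
# ---------------------------------------------------------------------------

@dataclass
class DropoutStutterReport:
    locus: str
    n: int
    status: str                     # ok | monomorphic
    p_dropout: float | None = None
    p_stutter: float | None = None
    dropout_flag: bool = False
    stutter_flag: bool = False
    repeat_unit: int | None = None
    obs_large_homozygotes: int = 0
    obs_stutter_heterozygotes: int = 0


def dropout_stutter_screen(dataset: GenotypeDataset, locus: str,
                           mc_reps: int = 1000, seed=None,
                           alpha: float = 0.05,
                           repeat_unit: int | None = None) -> DropoutStutterReport:
    """Monte-Carlo screen for large-allele dropout and stutter mis-scoring.

    Dropout: one-sided test for homozygote excess concentrated in the top
    allele-size quartile, measured as the fraction of top-quartile allele
    copies that reside in homozygous genotypes, against genotypes simulated
    under HWE from the observed allele frequencies.  (Dropout converts
    large/small heterozygotes into small homozygotes, stripping large-allele
    copies out of heterozygotes while leaving large homozygotes intact, so
    this fraction rises; unlike a raw homozygote count it is not defeated by
    the dropout-deflated observed allele frequency.)  Stutter: one-sided
    test for a deficit of heterozygotes whose alleles are exactly one repeat
    unit apart, same null.  Allele labels must be sizes in bp.  A locus with
    < 2 alleles is declined as monomorphic rather than flagged.
    """
    dataset.require_single_run("dropout/stutter screen")
    genos = dataset.genotypes(locus)
    if len(genos) < 10:
        raise AdnapopError(f"locus {locus}: screen needs >= 10 genotypes")
    try:
        sizes = [(int(a), int(b)) for a, b in genos]
    except ValueError as exc:
        raise AdnapopError(
            f"locus {locus}: allele labels are not sizes in bp") from exc
    alleles = np.array([s for g in sizes for s in g])
    distinct = np.unique(alleles)
    if len(distinct) < 2:
        return DropoutStutterReport(locus, len(genos), "monomorphic")
    if repeat_unit is None:
        repeat_unit = int(np.min(np.diff(distinct)))
    large_cut = np.quantile(distinct, 0.75)

    geno_arr = np.array(sizes)
    hom_obs = geno_arr[:, 0] == geno_arr[:, 1]
    large_obs = geno_arr >= large_cut
    obs_hom_large = int(np.sum(hom_obs & large_obs[:, 0]))
    obs_ratio = ((large_obs & hom_obs[:, None]).sum()
                 / max(int(large_obs.sum()), 1))
    obs_stutter = int(np.sum(~hom_obs
                             & (np.abs(geno_arr[:, 0] - geno_arr[:, 1]) == repeat_unit)))

    rng = as_rng(seed)
    n = len(genos)
    freqs = np.array([np.mean(alleles == a) for a in distinct])
    sims = rng.choice(distinct, size=(mc_reps, n, 2), p=freqs)
    hom = sims[:, :, 0] == sims[:, :, 1]
    large = sims >= large_cut
    sim_ratio = ((large & hom[:, :, None]).sum(axis=(1, 2))
                 / np.maximum(large.sum(axis=(1, 2)), 1))
    sim_stutter = np.sum((~hom) & (np.abs(sims[:, :, 0] - sims[:, :, 1])
                                   == repeat_unit), axis=1)
    p_drop = (np.sum(sim_ratio >= obs_ratio - 1e-12) + 1) / (mc_reps + 1)
    p_stut = (np.sum(sim_stutter <= obs_stutter) + 1) / (mc_reps + 1)
    return DropoutStutterReport(
        locus=locus, n=n, status="ok",
        p_dropout=float(p_drop), p_stutter=float(p_stut),
        dropout_flag=bool(p_drop < alpha), stutter_flag=bool(p_stut < alpha),
        repeat_unit=repeat_unit, obs_large_homozygotes=obs_hom_large,
        obs_stutter_heterozygotes=obs_stutter)


# ---------------------------------------------------------------------------
# Damage classification
# ---------------------------------------------------------------------------

TYPE2 = {("C", "T"), ("G", "A")}   # cytosine-deamination signature
TYPE1 = {("A", "G"), ("T", "C")}   # complementary transition class


@dataclass
class DamageReport:
    type2: int = 0
    type1: int = 0
    transversion: int = 0
    mismatches: list = field(default_factory=list)  # (pos, ref, obs, class)

    @property
    def total(self) -> int:
        return self.type2 + self.type1 + self.transversion


def classify_damage(observed: str, reference: str) -> DamageReport:
    """Classify reference -> observed mismatches into damage classes.

    C->T / G->A = Type 2 (deamination-like); A->G / T->C = Type 1; all other
    substitutions are transversions.  Positions where either base is not a
    plain A/C/G/T are skipped.
    """
    if len(observed) != len(reference):
        raise AdnapopError(
            f"sequence length mismatch: observed {len(observed)}, "
            f"reference {len(reference)}")
    report = DamageReport()
    for i, (r, o) in enumerate(zip(reference.upper(), observed.upper())):
        if r == o or r not in VALID_BASES or o not in VALID_BASES:
            continue
        if (r, o) in TYPE2:
            report.type2 += 1
            cls = "type2"
        elif (r, o) in TYPE1:
            report.type1 += 1
            cls = "type1"
        else:
            report.transversion += 1
            cls = "transversion"
        report.mismatches.append((i, r, o, cls))
    return report


def classify_damage_batch(pairs) -> dict:
    """Aggregate damage classes over (observed, reference) pairs."""
    totals = {"type2": 0, "type1": 0, "transversion": 0}
    affected = 0
    for observed, reference in pairs:
        rep = classify_damage(observed, reference)
        totals["type2"] += rep.type2
        totals["type1"] += rep.type1
        totals["transversion"] += rep.transversion
        if rep.total:
            affected += 1
    n = len(list(pairs)) if not hasattr(pairs, "__len__") else len(pairs)
    totals["total"] = sum(totals.values())
    totals["n_sequences"] = n
    totals["fraction_affected"] = affected / n if n else float("nan")
    return totals


# ---------------------------------------------------------------------------
# Amplification success / Ct stratification
# ---------------------------------------------------------------------------

@dataclass
class AmplificationSummary:
    per_marker: dict                 # marker -> (successes, n, integer %)
    all_markers: tuple               # every marker succeeded
    any_marker: tuple                # at least one marker succeeded
    n_samples: int


def amplification_success(outcomes: pd.DataFrame) -> AmplificationSummary:
    """Success accounting from a samples x markers boolean table.

    Percentages are rounded half-away-from-zero to integer percent, the
    convention used when quoting e.g. 75/85 as 88%.
    """
    df = outcomes.astype(bool)
    n = len(df)

    def _pct(k: int) -> tuple:
        return (k, n, round_half_away(100.0 * k / n) if n else 0)

    per_marker = {m: _pct(int(df[m].sum())) for m in df.columns}
    return AmplificationSummary(
        per_marker=per_marker,
        all_markers=_pct(int(df.all(axis=1).sum())),
        any_marker=_pct(int(df.any(axis=1).sum())),
        n_samples=n)


def success_by_stratum(success: pd.Series, strata: pd.Series) -> np.ndarray:
    """2 x k success/failure table over strata (e.g. per-millennium age bins),
    ready for :func:`adnapop.differentiation.chi2_yates`."""
    tab = pd.crosstab(success.astype(bool), strata)
    tab = tab.reindex([True, False], fill_value=0)
    return tab.to_numpy()


@dataclass
class CtSummary:
    n: int
    mean_ct: float
    min_ct: float
    max_ct: float
    frac_problem_above_mean: float
    frac_problem_at_or_below_mean: float
    n_above_mean: int
    n_at_or_below_mean: int


def ct_stratified_summary(df: pd.DataFrame, ct_col: str = "ct_value",
                          problem_col: str = "problem") -> CtSummary:
    """Partition samples at the mean Ct and compare QC-problem fractions.

    ``problem`` flags samples with genotyping errors or undetermined calls.
    Whenever Ct varies the mean split is non-degenerate by construction.
    """
    sub = df[[ct_col, problem_col]].dropna(subset=[ct_col])
    if len(sub) < 2:
        raise AdnapopError("Ct summary needs >= 2 samples with Ct values")
    ct = sub[ct_col].astype(float)
    prob = sub[problem_col].astype(bool)
    mean = float(ct.mean())
    above = ct > mean
    n_above = int(above.sum())
    n_below = int((~above).sum())
    return CtSummary(
        n=len(sub), mean_ct=mean, min_ct=float(ct.min()), max_ct=float(ct.max()),
        frac_problem_above_mean=float(prob[above].mean()) if n_above else float("nan"),
        frac_problem_at_or_below_mean=float(prob[~above].mean()) if n_below else float("nan"),
        n_above_mean=n_above, n_at_or_below_mean=n_below)
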