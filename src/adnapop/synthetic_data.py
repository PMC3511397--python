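"""Synthetic inputs with the statistical structure the analyses assume.

Every generator is seeded and emits a machine-readable truth log so each
downstream estimator can be scored against known ground truth:

* haplotype datasets: k haplotype sequences with controlled pairwise site
  distances, sampled multinomially per population from a Dirichlet-drawn
  (or fixed) frequency spectrum;
* replicated diploid genotypes: true genotypes drawn under HWE (optionally
  with an inbreeding excess F_IS), each PCR run independently corrupted by
  allelic dropout - logistic in standardised Ct and allele-size rank, the
  two preservation effects degraded template shows - and by one-repeat
  stutter shifts;
* damaged sequence pairs: C/G sites flip to the deamination (Type 2) state
  with ``type2_rate``, A/T sites to the Type 1 state with ``type1_rate``.

Default Ct distributions are Normal(36.8, 3.5) for ancient cohorts and
Normal(25.7, 1.0) for modern ones, the preservation regimes the QC
summaries are designed to separate.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import AdnapopError, as_rng
from .data_io import (GenotypeDataset, HaplotypeDataset, SampleRecord,
                      write_fasta_with_metadata, write_genotypes)

_BASES = np.array(list("ACGT"))
_TYPE2 = {"C": "T", "G": "A"}
_TYPE1 = {"A": "G", "T": "C"}


@dataclass
class GeneratorSpec:
    """Knobs for all three generators (probabilities in [0, 1])."""

    # haplotype model
    n_samples: dict = field(default_factory=lambda: {"ancient": 30, "modern": 30})
    k_haplotypes: int = 8
    sequence_length: int = 350
    private_mutations: int = 2        # substitutions private to each haplotype
    dirichlet_conc: float = 1.0
    haplotype_freqs: np.ndarray | None = None   # overrides the Dirichlet draw
    # damage model
    type2_rate: float = 0.01
    type1_rate: float = 0.002
    # genotype model: locus -> (allele size labels, frequencies)
    loci: dict | None = None
    microsat_repeat: int = 4
    fis: float = 0.0
    # run corruption model
    runs_per_sample: int = 3
    dropout_baseline: float = -3.0    # logit scale
    dropout_size_coef: float = 0.0    # per standardised allele-size rank
    dropout_ct_coef: float = 0.0      # per standardised Ct
    stutter_prob: float = 0.0
    # Ct model
    ct_mean: dict = field(default_factory=lambda: {"ancient": 36.8, "modern": 25.7})
    ct_sd: dict = field(default_factory=lambda: {"ancient": 3.5, "modern": 1.0})
    seed: int = 0

    def __post_init__(self):
        for rate in (self.type2_rate, self.type1_rate, self.stutter_prob):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.k_haplotypes < 1:
            raise ValueError("k_haplotypes must be >= 1")
        if self.loci is None:
            sizes = [100 + self.microsat_repeat * i for i in range(6)]
            self.loci = {
                f"ms{i + 1}": (sizes, np.full(len(sizes), 1 / len(sizes)))
                for i in range(3)
            }


# ---------------------------------------------------------------------------
# Haplotype datasets
# ---------------------------------------------------------------------------

def gen_haplotype_dataset(spec: GeneratorSpec, outdir=None):
    """Generate aligned haplotype sequences and per-population samples.

    Haplotype i carries ``private_mutations * i`` substitutions at sites
    disjoint from every other haplotype, so the pairwise distance between
    haplotypes i and j is exactly ``private_mutations * (i + j)`` (i < j,
    0-indexed, haplotype 0 being the unmutated reference state).

    Returns (HaplotypeDataset, [SampleRecord], truth dict); with ``outdir``
    also writes ``haplotypes.fasta``, ``samples.tsv`` and ``truth.tsv``.
    """
    rng = as_rng(spec.seed)
    k, L, m = spec.k_haplotypes, spec.sequence_length, spec.private_mutations
    if m * (k - 1) * k // 2 * 0 + m * (k - 1) > L or m * sum(range(k)) > L:
        raise AdnapopError(
            f"requested distances need {m * sum(range(k))} mutated sites, "
            f"alignment length is only {L}")
    ref = rng.choice(_BASES, size=L)
    sites = rng.permutation(L)
    seqs = []
    cursor = 0
    for i in range(k):
        s = ref.copy()
        for pos in sites[cursor: cursor + m * i]:
            current = s[pos]
            s[pos] = rng.choice([b for b in _BASES if b != current])
        cursor += m * i
        seqs.append("".join(s))

    if spec.haplotype_freqs is not None:
        freqs = np.asarray(spec.haplotype_freqs, dtype=float)
        if len(freqs) != k:
            raise AdnapopError("haplotype_freqs length must equal k_haplotypes")
    else:
        freqs = rng.dirichlet([spec.dirichlet_conc] * k) if k > 1 else np.array([1.0])

    haplotypes = {f"H{i + 1}": s for i, s in enumerate(seqs)}
    counts: dict[str, dict[str, int]] = {}
    records: list[SampleRecord] = []
    assignments: dict[str, str] = {}
    for pop, n in spec.n_samples.items():
        draw = rng.multinomial(n, freqs)
        counts[pop] = {f"H{i + 1}": int(c) for i, c in enumerate(draw) if c > 0}
        idx = np.repeat(np.arange(k), draw)
        for j, hap_i in enumerate(idx):
            sid = f"{pop}_{j + 1:03d}"
            records.append(SampleRecord(sample_id=sid, population=pop, group=pop))
            assignments[sid] = f"H{hap_i + 1}"
    dataset = HaplotypeDataset(L, haplotypes, counts, assignments)
    truth = {"frequencies": freqs,
             "expected_sum_p2": float(np.sum(freqs ** 2)),
             "pairwise_distance_unit": m}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta_with_metadata(dataset, records,
                                  outdir / "haplotypes.fasta",
                                  outdir / "samples.tsv")
        pd.DataFrame({"haplotype": list(haplotypes),
                      "true_freq": freqs}).to_csv(
            outdir / "truth.tsv", sep="\t", index=False)
    return dataset, records, truth


# ---------------------------------------------------------------------------
# Replicated genotypes
# ---------------------------------------------------------------------------

def _draw_true_genotypes(rng, freqs: np.ndarray, n: int, fis: float) -> np.ndarray:
    """n diploid genotypes (allele indices, shape (n, 2)) under HWE with an
    optional within-population inbreeding excess."""
    k = len(freqs)
    a = rng.choice(k, size=n, p=freqs)
    ibd = rng.random(n) < fis
    b = np.where(ibd, a, rng.choice(k, size=n, p=freqs))
    return np.column_stack([a, b])


def gen_replicated_genotypes(spec: GeneratorSpec, outdir=None):
    """Replicate PCR genotype runs with injected dropout and stutter.

    Per run and per allele, dropout fires with probability
    ``logistic(baseline + size_coef * size_rank_z + ct_coef * ct_z)``; a
    dropped allele of a heterozygote leaves a false homozygote, loss of
    both alleles leaves a missing call.  Stutter shifts an allele down one
    repeat unit.  Returns (GenotypeDataset, truth_log DataFrame,
    [SampleRecord]); the truth log records the true genotype and every
    injected corruption event.
    """
    rng = as_rng(spec.seed)
    rows, truth_rows, records = [], [], []
    for pop, n in spec.n_samples.items():
        ct = rng.normal(spec.ct_mean.get(pop, 36.8), spec.ct_sd.get(pop, 3.5), n)
        ct = np.clip(ct, 20.0, None)
        ct_z = (ct - ct.mean()) / (ct.std() if ct.std() > 0 else 1.0)
        for j in range(n):
            records.append(SampleRecord(sample_id=f"{pop}_{j + 1:03d}",
                                        population=pop, group=pop,
                                        ct_value=float(ct[j])))
        for locus, (sizes, freqs) in spec.loci.items():
            sizes = np.asarray(sizes)
            freqs = np.asarray(freqs, dtype=float)
            order = np.argsort(sizes)
            rank_z = np.empty(len(sizes))
            ranks = np.empty(len(sizes))
            ranks[order] = np.arange(len(sizes))
            rank_z = (ranks - ranks.mean()) / (ranks.std() if len(sizes) > 1 else 1.0)
            true_g = _draw_true_genotypes(rng, freqs, n, spec.fis)
            for j in range(n):
                sid = f"{pop}_{j + 1:03d}"
                truth_rows.append({"sample_id": sid, "population": pop,
                                   "locus": locus, "event": "truth",
                                   "run_id": "", "detail":
                                   f"{sizes[true_g[j, 0]]}/{sizes[true_g[j, 1]]}"})
                for run in range(1, spec.runs_per_sample + 1):
                    obs = []
                    for allele_idx in true_g[j]:
                        logit = (spec.dropout_baseline
                                 + spec.dropout_size_coef * rank_z[allele_idx]
                                 + spec.dropout_ct_coef * ct_z[j])
                        p_drop = 1.0 / (1.0 + np.exp(-logit))
                        if rng.random() < p_drop:
                            truth_rows.append(
                                {"sample_id": sid, "population": pop,
                                 "locus": locus, "event": "dropout",
                                 "run_id": str(run),
                                 "detail": str(sizes[allele_idx])})
                            continue
                        size = int(sizes[allele_idx])
                        if rng.random() < spec.stutter_prob:
                            size -= spec.microsat_repeat
                            truth_rows.append(
                                {"sample_id": sid, "population": pop,
                                 "locus": locus, "event": "stutter",
                                 "run_id": str(run), "detail": str(size)})
                        obs.append(size)
                    if not obs:
                        a = b = None
                    elif len(obs) == 1:
                        a = b = str(obs[0])  # single surviving allele reads hom
                    else:
                        a, b = str(obs[0]), str(obs[1])
                    rows.append({"sample_id": sid, "population": pop,
                                 "locus": locus, "run_id": str(run),
                                 "allele_a": a, "allele_b": b})
    dataset = GenotypeDataset(pd.DataFrame(rows))
    truth_log = pd.DataFrame(truth_rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genotypes(dataset, outdir / "genotypes.tsv", dialect="long_table")
        truth_log.to_csv(outdir / "genotype_truth.tsv", sep="\t", index=False)
        pd.DataFrame([{"sample_id": r.sample_id, "population": r.population,
                       "group": r.group, "ct_value": r.ct_value}
                      for r in records]).to_csv(
            outdir / "samples.tsv", sep="\t", index=False)
    return dataset, truth_log, records


# ---------------------------------------------------------------------------
# Damaged sequences
# ---------------------------------------------------------------------------

def gen_damaged_sequences(spec: GeneratorSpec, n_pairs: int = 10, outdir=None):
    """(reference, observed) pairs with Bernoulli miscoding lesions.

    Type 2 lesions (C->T, G->A) fire per C/G site with ``type2_rate``;
    Type 1 lesions (A->G, T->C) per A/T site with ``type1_rate``.  Returns
    (pairs, truth DataFrame with injected per-pair class counts).
    """
    rng = as_rng(spec.seed)
    pairs, truth_rows = [], []
    for i in range(n_pairs):
        ref = rng.choice(_BASES, size=spec.sequence_length)
        obs = ref.copy()
        n2 = n1 = 0
        for pos, base in enumerate(ref):
            if base in _TYPE2 and rng.random() < spec.type2_rate:
                obs[pos] = _TYPE2[base]
                n2 += 1
            elif base in _TYPE1 and rng.random() < spec.type1_rate:
                obs[pos] = _TYPE1[base]
                n1 += 1
        pairs.append(("".join(obs), "".join(ref)))
        truth_rows.append({"pair": i, "type2": n2, "type1": n1, "transversion": 0})
    truth = pd.DataFrame(truth_rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "damaged_pairs.fasta", "w") as fh:
            for i, (obs, ref) in enumerate(pairs):
                fh.write(f">pair{i}_ref\n{ref}\n>pair{i}_obs\n{obs}\n")
        truth.to_csv(outdir / "damage_truth.tsv", sep="\t", index=False)
    return pairs, truth
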