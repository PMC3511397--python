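import numpy as np
import pandas as pd
import pytest

from adnapop.data_io import GenotypeDataset, HaplotypeDataset


def make_genotypes(rows):
    """rows: (sample, population, locus, run, allele_a, allele_b)."""
    return GenotypeDataset(pd.DataFrame(
        rows, columns=["sample_id", "population", "locus", "run_id",
                       "allele_a", "allele_b"]))


def single_pop_genotypes(genos, locus="L1", population="pop1"):
    """One-run dataset from a list of (a, b) genotype tuples."""
    rows = []
    for i, g in enumerate(genos):
        a, b = (None, None) if g is None else g
        rows.append((f"s{i + 1}", population, locus, "1", a, b))
    return make_genotypes(rows)


def two_pop_genotypes(genos_by_pop, locus="L1"):
    rows = []
    for pop, genos in genos_by_pop.items():
        for i, (a, b) in enumerate(genos):
            rows.append((f"{pop}_s{i + 1}", pop, locus, "1", a, b))
    return make_genotypes(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(20121130)


@pytest.fixture
def six_seq_dataset(tmp_path):
    """Six aligned sequences, three identical pairs, two populations."""
    seqs = {
        "s1": "ACGTACGTAC", "s2": "ACGTACGTAC",      # H1
        "s3": "ACGTACGTAT", "s4": "ACGTACGTAT",      # H2
        "s5": "TCGTACGTAT", "s6": "TCGTACGTAT",      # H3
    }
    fasta = tmp_path / "six.fasta"
    fasta.write_text("".join(f">{k}\n{v}\n" for k, v in seqs.items()))
    meta = tmp_path / "six.tsv"
    meta.write_text("sample_id\tpopulation\tgroup\n" + "".join(
        f"{k}\t{'A' if i < 3 else 'B'}\t{'ancient' if i < 3 else 'modern'}\n"
        for i, k in enumerate(seqs)))
    return fasta, meta


def haplotype_dataset_from_counts(counts_by_pop, haplotypes):
    length = len(next(iter(haplotypes.values())))
    return HaplotypeDataset(length, dict(haplotypes),
                            {p: dict(c) for p, c in counts_by_pop.items()})
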