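"""Readers, writers and in-memory containers for the pipeline's inputs.

Three substrates flow through the package:

* aligned mtDNA sequences with per-sample metadata, collapsed to a
  :class:`HaplotypeDataset` (haplotype counts per population);
* diploid genotype calls per sample x locus x PCR run, held in a
  :class:`GenotypeDataset` (long format; Genepop and tab-delimited dialects);
* per-sample metadata (:class:`SampleRecord`), optionally carrying a qPCR
  cycle-threshold (Ct) value used as a DNA-preservation proxy.

Alleles are opaque text labels ordered lexicographically when normalising
unordered pairs; microsatellite allele labels are their fragment size in bp,
which the dropout/stutter screen relies on.  Genepop's ``0000``/``000000``
code maps to an explicit missing genotype.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._util import AdnapopError, ParseError, norm_pair

MISSING = None  # in-memory missing-allele marker

LONG_TABLE_COLUMNS = ["sample_id", "population", "locus", "run_id",
                      "allele_a", "allele_b"]


@dataclass(frozen=True)
class SampleRecord:
    """Per-sample metadata row.

    ``group`` distinguishes e.g. ancient vs modern cohorts (or regions);
    ``age_class`` is a categorical per-millennium bin; ``ct_value`` is the
    qPCR cycle threshold (> 0) and ``mass_mg`` the bone mass in mg.
    """

    sample_id: str
    population: str
    group: str | None = None
    age_class: str | None = None
    ct_value: float | None = None
    mass_mg: float | None = None

    def __post_init__(self):
        if self.ct_value is not None and not self.ct_value > 0:
            raise ValueError(
                f"sample {self.sample_id}: ct_value must be > 0, got {self.ct_value}")


@dataclass
class HaplotypeDataset:
    """Aligned sequences collapsed to haplotypes with per-population counts."""

    alignment_length: int
    haplotypes: dict[str, str]                 # haplotype_id -> sequence
    counts: dict[str, dict[str, int]]          # population -> haplotype_id -> count
    assignments: dict[str, str] | None = None  # sample_id -> haplotype_id

    def __post_init__(self):
        for hid, seq in self.haplotypes.items():
            if len(seq) != self.alignment_length:
                raise ValueError(
                    f"haplotype {hid} has length {len(seq)}, expected "
                    f"{self.alignment_length}")
        for pop, cts in self.counts.items():
            for hid, c in cts.items():
                if hid not in self.haplotypes:
                    raise ValueError(f"unknown haplotype {hid} in population {pop}")
                if c < 0:
                    raise ValueError("haplotype counts must be >= 0")

    @property
    def populations(self) -> list[str]:
        return list(self.counts)

    @property
    def haplotype_ids(self) -> list[str]:
        return list(self.haplotypes)

    def n(self, population: str | None = None) -> int:
        """Sample size of one population, or pooled over all populations."""
        if population is not None:
            return sum(self.counts[population].values())
        return sum(self.n(p) for p in self.counts)

    def count_vector(self, population: str | None = None) -> np.ndarray:
        """Counts aligned to :attr:`haplotype_ids` (pooled if no population)."""
        ids = self.haplotype_ids
        if population is not None:
            src = self.counts[population]
            return np.array([src.get(h, 0) for h in ids], dtype=int)
        return np.sum([self.count_vector(p) for p in self.populations], axis=0)

    def count_matrix(self) -> np.ndarray:
        """Populations x haplotypes count matrix (rows follow .populations)."""
        return np.vstack([self.count_vector(p) for p in self.populations])


class GenotypeDataset:
    """Long-format diploid genotype calls: one row per sample x locus x run.

    Missing genotypes are held explicitly (both alleles ``None``); a partial
    call (one allele missing) is treated as a missing genotype.  Allele pairs
    are stored unordered with ``allele_a <= allele_b`` lexicographically.
    """

    def __init__(self, records: pd.DataFrame):
        df = records.copy()
        missing_cols = [c for c in LONG_TABLE_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValueError(f"genotype records missing columns: {missing_cols}")
        df = df[LONG_TABLE_COLUMNS].reset_index(drop=True)
        for c in ("sample_id", "population", "locus", "run_id"):
            if df[c].isna().any():
                raise ValueError(f"column {c} may not contain missing values")
            df[c] = df[c].astype(str)

        def _norm(row):
            a, b = row["allele_a"], row["allele_b"]
            if pd.isna(a) or pd.isna(b):
                return pd.Series({"allele_a": None, "allele_b": None})
            a, b = norm_pair(a, b)
            return pd.Series({"allele_a": a, "allele_b": b})

        df[["allele_a", "allele_b"]] = df.apply(_norm, axis=1)
        dup = df.duplicated(subset=["sample_id", "locus", "run_id"])
        if dup.any():
            first = df.loc[dup.idxmax(), ["sample_id", "locus", "run_id"]]
            raise ValueError(
                "duplicate (sample, locus, run) record: "
                f"{tuple(first)} appears more than once")
        self.records = df

    # -- basic views ------------------------------------------------------
    @property
    def loci(self) -> list[str]:
        return list(dict.fromkeys(self.records["locus"]))

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.records["population"]))

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.records["sample_id"]))

    @property
    def run_ids(self) -> list[str]:
        return list(dict.fromkeys(self.records["run_id"]))

    def has_replicates(self) -> bool:
        return self.records.duplicated(subset=["sample_id", "locus"]).any()

    def require_single_run(self, context: str = "this statistic"):
        if self.has_replicates():
            raise AdnapopError(
                f"{context} requires one genotype per sample x locus; "
                "collapse replicate runs first (genotyping_qc.consensus_dataset)")

    def subset(self, locus: str | None = None,
               populations: Iterable[str] | None = None) -> "GenotypeDataset":
        df = self.records
        if locus is not None:
            df = df[df["locus"] == locus]
        if populations is not None:
            df = df[df["population"].isin(list(populations))]
        return GenotypeDataset(df)

    def genotypes(self, locus: str, population: str | None = None,
                  drop_missing: bool = True) -> list[tuple[str, str] | None]:
        """Genotype tuples at a locus (single-run data)."""
        self.require_single_run("genotype extraction")
        df = self.records[self.records["locus"] == locus]
        if population is not None:
            df = df[df["population"] == population]
        out = []
        for _, row in df.iterrows():
            if row["allele_a"] is None:
                if not drop_missing:
                    out.append(None)
            else:
                out.append((row["allele_a"], row["allele_b"]))
        return out

    def allele_counts(self, locus: str,
                      population: str | None = None) -> dict[str, int]:
        counts: dict[str, int] = {}
        for a, b in self.genotypes(locus, population):
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
        return counts

    def runs_by_sample(self, locus: str) -> dict[str, list[tuple[str, str] | None]]:
        """Replicate run calls per sample at a locus, in run_id order."""
        df = self.records[self.records["locus"] == locus]
        df = df.sort_values("run_id", kind="stable")
        out: dict[str, list] = {}
        for _, row in df.iterrows():
            g = None if row["allele_a"] is None else (row["allele_a"], row["allele_b"])
            out.setdefault(row["sample_id"], []).append(g)
        return out

    def population_of(self) -> dict[str, str]:
        return dict(zip(self.records["sample_id"], self.records["population"]))

    def __eq__(self, other):
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        a = self.records.sort_values(["sample_id", "locus", "run_id"]).reset_index(drop=True)
        b = other.records.sort_values(["sample_id", "locus", "run_id"]).reset_index(drop=True)
        return a.equals(b)

    def __len__(self):
        return len(self.records)


# ---------------------------------------------------------------------------
# FASTA + metadata
# ---------------------------------------------------------------------------

def read_fasta_with_metadata(seq_path, meta_path) -> tuple[HaplotypeDataset, list[SampleRecord]]:
    """Load an aligned FASTA plus a tab-delimited metadata table.

    The metadata table needs ``sample_id`` and ``population`` columns;
    ``group``, ``age_class``, ``ct_value`` and ``mass_mg`` are optional.
    Sequences are collapsed to unique haplotypes (exact string identity,
    upper-cased) and tallied per population.
    """
    seqs = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(seq_path), "fasta")]
    if not seqs:
        raise ParseError(f"no sequences found in {seq_path}")
    length = len(seqs[0][1])
    for sid, s in seqs:
        if len(s) != length:
            raise ParseError(
                f"ragged alignment: sequence {sid} has length {len(s)}, "
                f"expected {length}")

    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str, "population": str})
    if "sample_id" not in meta.columns or "population" not in meta.columns:
        raise ParseError(f"metadata {meta_path} needs sample_id and population columns")
    records = []
    for _, row in meta.iterrows():
        records.append(SampleRecord(
            sample_id=str(row["sample_id"]),
            population=str(row["population"]),
            group=str(row["group"]) if "group" in meta.columns and pd.notna(row.get("group")) else None,
            age_class=str(row["age_class"]) if "age_class" in meta.columns and pd.notna(row.get("age_class")) else None,
            ct_value=float(row["ct_value"]) if "ct_value" in meta.columns and pd.notna(row.get("ct_value")) else None,
            mass_mg=float(row["mass_mg"]) if "mass_mg" in meta.columns and pd.notna(row.get("mass_mg")) else None,
        ))
    by_id = {r.sample_id: r for r in records}
    if len(by_id) != len(records):
        raise ParseError("duplicate sample_id in metadata")
    unknown = [sid for sid, _ in seqs if sid not in by_id]
    if unknown:
        raise ParseError(f"FASTA ids missing from metadata: {unknown[:5]}")

    hap_of_seq: dict[str, str] = {}
    haplotypes: dict[str, str] = {}
    counts: dict[str, dict[str, int]] = {}
    assignments: dict[str, str] = {}
    for sid, s in seqs:
        hid = hap_of_seq.get(s)
        if hid is None:
            hid = f"H{len(haplotypes) + 1}"
            hap_of_seq[s] = hid
            haplotypes[hid] = s
        pop = by_id[sid].population
        counts.setdefault(pop, {})
        counts[pop][hid] = counts[pop].get(hid, 0) + 1
        assignments[sid] = hid
    dataset = HaplotypeDataset(length, haplotypes, counts, assignments)
    return dataset, records


def write_fasta_with_metadata(dataset: HaplotypeDataset, records: list[SampleRecord],
                              seq_path, meta_path):
    """Inverse of :func:`read_fasta_with_metadata` (requires assignments)."""
    if dataset.assignments is None:
        raise AdnapopError("dataset has no per-sample haplotype assignments")
    with open(seq_path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.sample_id}\n{dataset.haplotypes[dataset.assignments[rec.sample_id]]}\n")
    rows = [{"sample_id": r.sample_id, "population": r.population,
             "group": r.group, "age_class": r.age_class,
             "ct_value": r.ct_value, "mass_mg": r.mass_mg} for r in records]
    pd.DataFrame(rows).to_csv(meta_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genotype dialects
# ---------------------------------------------------------------------------

def read_genotypes(path, dialect: str = "long_table") -> GenotypeDataset:
    """Read genotypes from ``genepop`` or ``long_table`` (TSV) dialects."""
    if dialect == "genepop":
        return _read_genepop(path)
    if dialect == "long_table":
        return _read_long_table(path)
    raise ValueError(f"unknown genotype dialect: {dialect!r}")


def write_genotypes(dataset: GenotypeDataset, path, dialect: str = "long_table"):
    if dialect == "genepop":
        return _write_genepop(dataset, path)
    if dialect == "long_table":
        return _write_long_table(dataset, path)
    raise ValueError(f"unknown genotype dialect: {dialect!r}")


def _read_long_table(path) -> GenotypeDataset:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = [c for c in LONG_TABLE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: long table missing columns {missing_cols}")
    df = df.replace({".": None})
    try:
        return GenotypeDataset(df)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def _write_long_table(dataset: GenotypeDataset, path):
    df = dataset.records.copy()
    df[["allele_a", "allele_b"]] = df[["allele_a", "allele_b"]].fillna(".")
    df.to_csv(path, sep="\t", index=False)


_GENEPOP_CODE = re.compile(r"^\d+$")


def _read_genepop(path) -> GenotypeDataset:
    """Genepop dialect: title line, locus names, then POP-separated samples.

    Two- and three-digit allele codes are supported; ``00``/``000`` is the
    missing-allele code and any genotype containing it is held as missing.
    Populations are labelled ``pop1`` .. ``popK`` in file order (the format
    itself carries no population names).
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = lines[i].strip()
        if chunk:
            loci.extend(name.strip() for name in chunk.split(",") if name.strip())
        i += 1
    if not loci:
        raise ParseError(f"{path}: no locus names before first POP", line=i)
    rows = []
    pop_idx = 0
    while i < len(lines):
        if lines[i].strip().lower() == "pop":
            pop_idx += 1
            i += 1
            continue
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if "," not in line:
            raise ParseError(f"{path}: sample line lacks comma separator", line=i + 1)
        sample_id, geno_part = line.split(",", 1)
        codes = geno_part.split()
        if len(codes) != len(loci):
            raise ParseError(
                f"{path}: expected {len(loci)} genotype codes, got {len(codes)}",
                line=i + 1)
        for locus, code in zip(loci, codes):
            if not _GENEPOP_CODE.match(code) or len(code) not in (4, 6):
                raise ParseError(
                    f"{path}: malformed allele code {code!r} at locus {locus}",
                    line=i + 1)
            w = len(code) // 2
            a_raw, b_raw = code[:w], code[w:]
            if int(a_raw) == 0 or int(b_raw) == 0:
                a = b = None
            else:
                a, b = str(int(a_raw)), str(int(b_raw))
            rows.append({"sample_id": sample_id.strip(),
                         "population": f"pop{pop_idx}",
                         "locus": locus, "run_id": "1",
                         "allele_a": a, "allele_b": b})
        i += 1
    if pop_idx == 0:
        raise ParseError(f"{path}: no POP sections found")
    return GenotypeDataset(pd.DataFrame(rows))


def _write_genepop(dataset: GenotypeDataset, path, title: str = "adnapop export"):
    """Write a Genepop file.  Requires numeric allele labels (1..999) and a
    single run per sample x locus; population labels are not representable
    in the format and regenerate as ``pop1`` .. ``popK`` on re-read."""
    dataset.require_single_run("Genepop export")
    loci = dataset.loci
    labels = [lab for col in ("allele_a", "allele_b")
              for lab in dataset.records[col].dropna()]
    try:
        max_allele = max((int(x) for x in labels), default=1)
    except ValueError as exc:
        raise AdnapopError("Genepop export needs numeric allele labels") from exc
    if max_allele > 999:
        raise AdnapopError("Genepop allele codes are limited to 999")
    width = 2 if max_allele <= 99 else 3
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in loci:
            fh.write(locus + "\n")
        for pop in dataset.populations:
            fh.write("POP\n")
            sub = dataset.records[dataset.records["population"] == pop]
            for sample in dict.fromkeys(sub["sample_id"]):
                srows = sub[sub["sample_id"] == sample].set_index("locus")
                codes = []
                for locus in loci:
                    if locus in srows.index and srows.loc[locus, "allele_a"] is not None:
                        a = int(srows.loc[locus, "allele_a"])
                        b = int(srows.loc[locus, "allele_b"])
                        codes.append(f"{a:0{width}d}{b:0{width}d}")
                    else:
                        codes.append("0" * (2 * width))
                fh.write(f"{sample} , " + " ".join(codes) + "\n")


def cli_entry(argv) -> int:
    """Run the command-line interface on an argv list; returns an exit status."""
    from .cli import main
    try:
        main(args=list(argv), standalone_mode=False)
    except SystemExit as exc:  # click's --help and friends
        return int(exc.code or 0)
    except Exception as exc:  # noqa: BLE001 - CLI boundary
        import click
        if isinstance(exc, click.exceptions.ClickException):
            exc.show()
            return exc.exit_code
        raise
    return 0
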