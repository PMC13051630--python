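"""Genotype containers, I/O, MAF filtering, F1 genotype estimation, parental distances.

Genotypes are coded numerically: -1 homozygous reference, 0 heterozygous,
1 homozygous alternate. The F1 genotype rule is the parental mean with the
half-dose fractions (+-0.5, from one heterozygous parent) rounded outward to
the nearest homozygote, so estimated F1 matrices stay on the {-1, 0, 1} code.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

VALID_CODES = frozenset((-1, 0, 1))


@dataclass
class GenotypeMatrix:
    """Accessions x loci matrix of numeric genotype codes in {-1, 0, 1}."""

    accession_ids: list[str]
    locus_ids: list[str]
    values: np.ndarray  # shape (n_accessions, n_loci)

    def __post_init__(self) -> None:
        self.accession_ids = [str(a) for a in self.accession_ids]
        self.locus_ids = [str(m) for m in self.locus_ids]
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D array")
        n, p = self.values.shape
        if n != len(self.accession_ids) or p != len(self.locus_ids):
            raise ValueError("genotype shape does not match accession/locus labels")
        if len(set(self.accession_ids)) != n:
            raise ValueError("duplicate accession ids")
        if len(set(self.locus_ids)) != p:
            raise ValueError("duplicate locus ids")
        bad = ~np.isin(self.values, (-1, 0, 1))
        if bad.any():
            raise ValueError(
                f"{bad.sum()} genotype entries outside the {{-1, 0, 1}} code"
            )
        self.values = self.values.astype(np.int8)

    # -- basic queries ------------------------------------------------------

    @property
    def n_accessions(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]

    @property
    def allele_freqs(self) -> np.ndarray:
        """Alternate-allele frequency per locus: (2*count(1) + count(0)) / 2n."""
        return (self.values.astype(float) + 1.0).mean(axis=0) / 2.0

    def index_of(self, accession: str) -> int:
        try:
            return self.accession_ids.index(accession)
        except ValueError:
            raise KeyError(f"accession {accession!r} not in genotype matrix") from None

    def subset_accessions(self, ids: list[str]) -> "GenotypeMatrix":
        rows = [self.index_of(a) for a in ids]
        return GenotypeMatrix(list(ids), list(self.locus_ids), self.values[rows])

    def subset_loci(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return GenotypeMatrix(
            list(self.accession_ids),
            [self.locus_ids[j] for j in idx],
            self.values[:, idx],
        )

    @classmethod
    def concat(cls, first: "GenotypeMatrix", *rest: "GenotypeMatrix") -> "GenotypeMatrix":
        """Stack accession sets sharing an identical locus panel."""
        acc = list(first.accession_ids)
        mats = [first.values]
        for g in rest:
            if g.locus_ids != first.locus_ids:
                raise ValueError("cannot concatenate genotype matrices with different loci")
            acc.extend(g.accession_ids)
            mats.append(g.values)
        return cls(acc, list(first.locus_ids), np.vstack(mats))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.accession_ids, columns=self.locus_ids)

    # -- I/O ----------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "accession"
        df.to_csv(path, sep="\t")

    def to_vcf(self, path: str | Path, seed: int | None = None) -> None:
        """Write a minimal VCF 4.2 with unphased diploid GT calls.

        Locus ids of the form ``chrom:pos`` keep their coordinates; anything
        else is placed on contig "1" at consecutive positions.
        """
        code_to_gt = {-1: "0/0", 0: "0/1", 1: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=crosspred\n")
            if seed is not None:
                fh.write(f"##crosspred_seed={seed}\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.accession_ids)
                + "\n"
            )
            for j, locus in enumerate(self.locus_ids):
                if ":" in locus and locus.rsplit(":", 1)[1].isdigit():
                    chrom, pos = locus.rsplit(":", 1)
                else:
                    chrom, pos = "1", str(j + 1)
                gts = "\t".join(code_to_gt[int(v)] for v in self.values[:, j])
                fh.write(f"{chrom}\t{pos}\t{locus}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def _read_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy()
    if not np.isin(values, (-1, 0, 1)).all():
        raise ValueError(f"TSV {path} contains codes outside {{-1, 0, 1}}")
    return GenotypeMatrix(list(df.index), list(df.columns), values)


def _read_vcf(path: str | Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    columns: list[np.ndarray] = []
    locus_ids: list[str] = []
    n_dropped = 0
    for var in vcf:
        if (not var.is_snp) or len(var.ALT) != 1:
            n_dropped += 1
            continue
        gt = np.asarray(var.gt_types)  # 0 hom-ref, 1 het, 2 hom-alt, 3 missing
        if (gt == 3).any():
            n_dropped += 1
            continue
        columns.append(gt.astype(np.int8) - 1)
        locus_ids.append(f"{var.CHROM}:{var.POS}")
    if n_dropped:
        log.info("dropped %d VCF sites (non-biallelic-SNP or missing calls)", n_dropped)
    if not columns:
        raise ValueError(f"no usable biallelic SNP sites in {path}")
    return GenotypeMatrix(samples, locus_ids, np.column_stack(columns))


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read genotypes from a VCF (GT field) or a numeric-coded TSV.

    VCF calls map as 0/0 -> -1, 0/1 or 1/0 -> 0, 1/1 -> 1; sites that are not
    biallelic SNPs or that carry missing calls are dropped panel-wide with a
    logged count. TSV input must already be complete and numeric.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "vcf" if path.suffix.lower() in {".vcf", ".gz", ".bcf"} else "tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def filter_maf(g: GenotypeMatrix, threshold: float = 0.05) -> GenotypeMatrix:
    """Retain loci whose minor allele frequency strictly exceeds ``threshold``."""
    if not (0.0 <= threshold < 0.5):
        raise ValueError("MAF threshold must be in [0, 0.5)")
    freq = g.allele_freqs
    maf = np.minimum(freq, 1.0 - freq)
    keep = maf > threshold
    if not keep.any():
        raise ValueError(f"MAF filter at {threshold} would remove every locus")
    if (~keep).any():
        log.info("MAF filter %.3g removed %d of %d loci", threshold, (~keep).sum(), g.n_loci)
    return g.subset_loci(keep)


@dataclass
class CrossTable:
    """F1 pedigree: one row per F1 with mother and father accession ids."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = {"f1_id", "mother_id", "father_id"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"cross table needs columns {sorted(required)}")
        if self.table["f1_id"].duplicated().any():
            raise ValueError("duplicate f1_id in cross table")
        if (self.table["mother_id"] == self.table["father_id"]).any():
            raise ValueError("self-cross in cross table")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def f1_ids(self) -> list[str]:
        return list(self.table["f1_id"])

    @property
    def parent_ids(self) -> list[str]:
        return sorted(set(self.table["mother_id"]) | set(self.table["father_id"]))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CrossTable":
        return cls(pd.read_csv(path, dtype=str))


def estimate_f1_genotypes(g: GenotypeMatrix, crosses: CrossTable) -> GenotypeMatrix:
    """Estimate F1 genotypes as the parental mean, with half-doses snapped to +-1.

    gF1 = (gP1 + gP2) / 2 per locus; the fractional values -0.5 and 0.5 that a
    single heterozygous parent produces are adjusted to -1 and 1. Segregation at
    heterozygous loci is deliberately not modelled.
    """
    for pid in crosses.parent_ids:
        g.index_of(pid)  # raises KeyError if a parent is ungenotyped
    mothers = g.values[[g.index_of(m) for m in crosses.table["mother_id"]]].astype(float)
    fathers = g.values[[g.index_of(f) for f in crosses.table["father_id"]]].astype(float)
    mean = (mothers + fathers) / 2.0
    est = np.where(mean == 0.5, 1.0, np.where(mean == -0.5, -1.0, mean))
    return GenotypeMatrix(crosses.f1_ids, list(g.locus_ids), est.astype(np.int8))


def parental_distance(g: GenotypeMatrix, crosses: CrossTable) -> pd.DataFrame:
    """Euclidean distance between the two parents of each F1 on genotype codes.

    Returns a DataFrame with columns f1_id, mother_id, father_id, distance.
    """
    mothers = g.values[[g.index_of(m) for m in crosses.table["mother_id"]]].astype(float)
    fathers = g.values[[g.index_of(f) for f in crosses.table["father_id"]]].astype(float)
    dist = np.sqrt(((mothers - fathers) ** 2).sum(axis=1))
    return pd.DataFrame(
        {
            "f1_id": crosses.f1_ids,
            "mother_id": list(crosses.table["mother_id"]),
            "father_id": list(crosses.table["father_id"]),
            "distance": dist,
        }
    )
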