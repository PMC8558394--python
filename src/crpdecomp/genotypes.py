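"""Genotype-matrix container and plain-text I/O (VCF and TSV dosage dialects).

Dosages are stored samples x variants as float arrays with values in
{0, 1, 2, NaN}; NaN marks a missing diploid genotype. Variant metadata lives in
a DataFrame with columns ``chrom, pos, ref, alt, id``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InputError

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "id"]
NUCLEOTIDES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class GenotypeMatrix:
    sample_ids: np.ndarray            # (n_samples,) str
    variants: pd.DataFrame            # VARIANT_COLUMNS
    dosages: np.ndarray               # (n_samples, n_variants) float

    def __post_init__(self):
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if list(self.variants.columns) != VARIANT_COLUMNS:
            self.variants = self.variants[VARIANT_COLUMNS]
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise InputError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        bad = ~self.variants["ref"].isin(NUCLEOTIDES) | ~self.variants["alt"].isin(NUCLEOTIDES)
        if bad.any():
            raise InputError("ref/alt alleles must be single nucleotides")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per variant, ignoring missing genotypes."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def missingness(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def take_variants(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.sample_ids,
            self.variants.iloc[index].reset_index(drop=True),
            self.dosages[:, index],
        )

    def take_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.sample_ids[index], self.variants.copy(), self.dosages[index]
        )

    # -- I/O ----------------------------------------------------------------

    def to_vcf(self, path) -> None:
        """Write a minimal diploid-GT VCF (unphased; missing as ./.)."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(map(str, self.sample_ids)) + "\n")
            gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
            for j, rec in self.variants.iterrows():
                col = self.dosages[:, j]
                gts = "\t".join(
                    "./." if np.isnan(d) else gt_map[float(d)] for d in col
                )
                fh.write(f"{rec.chrom}\t{rec.pos}\t{rec.id}\t{rec.ref}\t{rec.alt}"
                         f"\t.\t.\t.\tGT\t{gts}\n")

    @classmethod
    def from_vcf(cls, path) -> "GenotypeMatrix":
        """Read a diploid-GT VCF written by :meth:`to_vcf` (plain text)."""
        samples, rows, dosage_cols = [], [], []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("##") or not line:
                    continue
                if line.startswith("#CHROM"):
                    samples = line.split("\t")[9:]
                    continue
                parts = line.split("\t")
                chrom, pos, vid, ref, alt = parts[0], int(parts[1]), parts[2], parts[3], parts[4]
                rows.append((chrom, pos, ref, alt, vid))
                col = np.empty(len(parts) - 9)
                for i, gt in enumerate(parts[9:]):
                    gt = gt.split(":")[0]
                    if "." in gt:
                        col[i] = np.nan
                    else:
                        col[i] = sum(int(a) for a in gt.replace("|", "/").split("/"))
                dosage_cols.append(col)
        if not rows:
            raise InputError(f"no variant records in {path}")
        variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
        return cls(np.array(samples, dtype=object), variants,
                   np.column_stack(dosage_cols))

    def to_dosage_tsv(self, path) -> None:
        """TSV dialect: variant metadata columns then one column per sample."""
        df = self.variants.copy()
        for i, sid in enumerate(self.sample_ids):
            df[str(sid)] = self.dosages[i]
        df.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_dosage_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", na_values="NA")
        missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
        if missing:
            raise InputError(f"dosage TSV missing columns {missing}")
        samples = [c for c in df.columns if c not in VARIANT_COLUMNS]
        return cls(
            np.array(samples, dtype=object),
            df[VARIANT_COLUMNS].copy(),
            df[samples].to_numpy(dtype=float).T,
        )


def concat_samples(matrices: list, variants: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Stack sample sets that share an identical variant frame."""
    if variants is None:
        variants = matrices[0].variants
    return GenotypeMatrix(
        np.concatenate([m.sample_ids for m in matrices]),
        variants.reset_index(drop=True),
        np.vstack([m.dosages for m in matrices]),
    )
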