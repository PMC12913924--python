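"""Genotype dosage container and genotype file IO.

The central in-memory object is :class:`GenotypeMatrix`: a samples x SNPs
matrix of effect-allele dosages (0/1/2, ``NaN`` for missing calls) plus a SNP
metadata table (id, chromosome, 1-based position, effect and other allele).
Two on-disk dialects are supported: plain-text VCF (dosage = ALT allele
count) and a tab-delimited dosage matrix with a sidecar SNP table.
"""

from __future__ import annotations

import io
import os
import warnings

import numpy as np
import pandas as pd

SNP_COLUMNS = ["id", "chrom", "pos", "effect_allele", "other_allele"]


class GenotypeMatrix:
    """Samples x SNPs effect-allele dosage matrix with a missingness mask.

    Parameters
    ----------
    dosages : ndarray, shape (n_samples, n_snps)
        Float matrix of dosages in {0, 1, 2}; ``NaN`` marks missing calls.
    samples : sequence of str
        Unique sample identifiers, one per row.
    snps : DataFrame
        One row per SNP with columns ``id, chrom, pos, effect_allele,
        other_allele``; positions are 1-based.
    """

    def __init__(self, dosages: np.ndarray, samples, snps: pd.DataFrame):
        dosages = np.asarray(dosages, dtype=float)
        if dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x SNPs)")
        samples = np.asarray(samples, dtype=object)
        if len(samples) != dosages.shape[0]:
            raise ValueError("sample count does not match dosage rows")
        if len(set(samples)) != len(samples):
            raise ValueError("sample ids must be unique")
        snps = snps.reset_index(drop=True)
        missing_cols = [c for c in SNP_COLUMNS if c not in snps.columns]
        if missing_cols:
            raise ValueError(f"snp table lacks columns: {missing_cols}")
        if len(snps) != dosages.shape[1]:
            raise ValueError("snp count does not match dosage columns")
        self.dosages = dosages
        self.samples = samples
        self.snps = snps

    # ------------------------------------------------------------------ #
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.copy(), self.samples.copy(), self.snps.copy())

    def sample_index(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message only
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None

    def take_samples(self, ids) -> "GenotypeMatrix":
        idx = self.sample_index(ids)
        return GenotypeMatrix(self.dosages[idx], self.samples[idx], self.snps)

    def take_snps(self, mask_or_ids) -> "GenotypeMatrix":
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            idx = np.flatnonzero(arr)
        elif np.issubdtype(arr.dtype, np.integer):
            idx = arr
        else:
            lookup = {s: i for i, s in enumerate(self.snps["id"])}
            idx = np.array([lookup[s] for s in arr], dtype=int)
        return GenotypeMatrix(
            self.dosages[:, idx], self.samples, self.snps.iloc[idx].reset_index(drop=True)
        )

    # -------------------------- marginal summaries -------------------- #
    def snp_call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosages), axis=0)

    def sample_missing_rate(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosages), axis=1)

    def effect_allele_freq(self) -> np.ndarray:
        """Effect-allele frequency from non-missing calls (NaN if none)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.effect_allele_freq()
        return np.minimum(p, 1.0 - p)

    def genotype_counts(self) -> np.ndarray:
        """Per-SNP (n_hom_other, n_het, n_hom_effect) counts, shape (m, 3)."""
        d = self.dosages
        return np.stack(
            [np.nansum(d == k, axis=0) for k in (0.0, 1.0, 2.0)], axis=1
        ).astype(int)

    # ------------------------------ VCF -------------------------------- #
    def write_vcf(self, path, header_lines=()) -> None:
        """Write a minimal uncompressed VCF (GT field only, ALT = effect allele)."""
        d = self.dosages
        gt_codes = np.full(d.shape, "./.", dtype=object)
        gt_codes[d == 0] = "0/0"
        gt_codes[d == 1] = "0/1"
        gt_codes[d == 2] = "1/1"
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=igeprs\n")
            for line in header_lines:
                fh.write(f"##{line}\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            chroms = pd.unique(self.snps["chrom"])
            for c in chroms:
                fh.write(f"##contig=<ID={c}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(map(str, self.samples))
                + "\n"
            )
            for j, row in enumerate(self.snps.itertuples(index=False)):
                fields = [
                    str(row.chrom),
                    str(int(row.pos)),
                    str(row.id),
                    str(row.other_allele),
                    str(row.effect_allele),
                    ".",
                    "PASS",
                    ".",
                    "GT",
                ]
                fh.write("\t".join(fields) + "\t" + "\t".join(gt_codes[:, j]) + "\n")

    @classmethod
    def read_vcf(cls, path) -> "GenotypeMatrix":
        """Read a VCF; biallelic records only (others skipped with a warning)."""
        from cyvcf2 import VCF

        vcf = VCF(os.fspath(path), gts012=True)
        samples = list(vcf.samples)
        rows, meta = [], []
        n_skipped = 0
        for variant in vcf:
            if len(variant.ALT) != 1:
                n_skipped += 1
                continue
            gt = np.asarray(variant.gt_types, dtype=float)  # 0,1,2; 3 = unknown
            gt[gt == 3] = np.nan
            rows.append(gt)
            meta.append(
                (
                    variant.ID or f"{variant.CHROM}:{variant.POS}",
                    variant.CHROM,
                    variant.POS,
                    variant.ALT[0],
                    variant.REF,
                )
            )
        vcf.close()
        if n_skipped:
            warnings.warn(f"skipped {n_skipped} non-biallelic VCF records")
        if not rows:
            raise ValueError(f"no biallelic records parsed from {path}")
        snps = pd.DataFrame(meta, columns=SNP_COLUMNS)
        return cls(np.array(rows).T, samples, snps)

    # --------------------------- dosage TSV ---------------------------- #
    def write_dosage_tsv(self, path, header_lines=()) -> None:
        """Write dosages as TSV (rows = samples) plus a ``.snps.tsv`` sidecar."""
        path = os.fspath(path)
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            df = pd.DataFrame(self.dosages, index=self.samples, columns=self.snps["id"])
            df.index.name = "sample"
            buf = io.StringIO()
            df.to_csv(buf, sep="\t", na_rep="NA", float_format="%.0f")
            fh.write(buf.getvalue())
        self.snps.to_csv(path + ".snps.tsv", sep="\t", index=False)

    @classmethod
    def read_dosage_tsv(cls, path) -> "GenotypeMatrix":
        path = os.fspath(path)
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0, na_values=["NA"])
        sidecar = path + ".snps.tsv"
        if os.path.exists(sidecar):
            snps = pd.read_csv(sidecar, sep="\t")
        else:
            snps = pd.DataFrame(
                {
                    "id": df.columns,
                    "chrom": "1",
                    "pos": np.arange(1, df.shape[1] + 1),
                    "effect_allele": "A",
                    "other_allele": "B",
                }
            )
        bad = df.values[~np.isnan(df.values)]
        if not np.isin(bad, [0.0, 1.0, 2.0]).all():
            raise ValueError(f"dosage file {path} contains values outside {{0,1,2,NA}}")
        return cls(df.values.astype(float), list(df.index.astype(str)), snps)


def pairwise_r2(dosages: np.ndarray, j: int, idx: np.ndarray) -> np.ndarray:
    """Squared dosage correlation (composite LD) of SNP ``j`` with SNPs ``idx``.

    Pairwise-complete: each pair uses the samples non-missing in both SNPs.
    Pairs with fewer than 2 shared calls or a constant SNP give r2 = 0.
    """
    idx = np.asarray(idx)
    x = dosages[:, j]
    out = np.zeros(len(idx))
    x_ok = ~np.isnan(x)
    Y = dosages[:, idx]
    y_nan = np.isnan(Y)
    clean = ~y_nan[x_ok].any(axis=0)

    if clean.any():  # vectorized path: candidates complete where x is complete
        Yc = Y[x_ok][:, clean]
        xs = x[x_ok]
        n = len(xs)
        if n >= 2:
            xc = xs - xs.mean()
            Ycc = Yc - Yc.mean(axis=0)
            cov = xc @ Ycc / n
            vx = xc @ xc / n
            vy = np.einsum("ij,ij->j", Ycc, Ycc) / n
            with np.errstate(invalid="ignore", divide="ignore"):
                r2 = np.where((vx > 0) & (vy > 0), cov**2 / (vx * vy), 0.0)
            out[clean] = r2

    for k in np.flatnonzero(~clean):  # pairwise-complete fallback
        y = Y[:, k]
        ok = x_ok & ~np.isnan(y)
        if ok.sum() < 2:
            continue
        xs, ys = x[ok], y[ok]
        vx, vy = xs.var(), ys.var()
        if vx <= 0 or vy <= 0:
            continue
        c = np.mean((xs - xs.mean()) * (ys - ys.mean()))
        out[k] = (c * c) / (vx * vy)
    return out


def read_genotypes(path, fmt: str | None = None) -> GenotypeMatrix:
    """Read genotypes from ``vcf`` or ``dosage_tsv`` (inferred from suffix)."""
    path = os.fspath(path)
    if fmt is None:
        fmt = "vcf" if path.endswith(".vcf") or path.endswith(".vcf.gz") else "dosage_tsv"
    if fmt == "vcf":
        return GenotypeMatrix.read_vcf(path)
    if fmt == "dosage_tsv":
        return GenotypeMatrix.read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")
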