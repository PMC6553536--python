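"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel either as VCF (biallelic SNPs with GT and optional AD
fields) or as a plain delimited dosage matrix (individuals x markers);
kernels as square CSV with id headers; trial records, population metadata
and reports as ordinary CSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, KernelMatrix

__all__ = ["write_vcf", "read_vcf", "write_dosage", "read_dosage",
           "write_kernel", "read_kernel"]

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(G: GenotypeMatrix, path, ad_table: pd.DataFrame = None) -> None:
    """Write biallelic SNP records with GT (and AD when depths are given).

    ``ad_table`` (columns ``individual, marker, ref_depth, total_depth``)
    fills the AD field for the listed calls; others are written as missing.
    Integer dosages only — write before imputation or round explicitly.
    """
    ad = {}
    if ad_table is not None:
        for row in ad_table.itertuples(index=False):
            ad[(row.individual, row.marker)] = (int(row.ref_depth),
                                                int(row.total_depth - row.ref_depth))
    fmt = "GT:AD" if ad_table is not None else "GT"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if ad_table is not None:
            fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                     'Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, G.individual_ids)) + "\n")
        for j in range(G.n_markers):
            cells = []
            for i in range(G.n_individuals):
                if G.missing[i, j]:
                    gt = "./."
                else:
                    d = int(round(G.dosage[i, j]))
                    gt = _GT.get(d, "./.")
                if ad_table is not None:
                    pair = ad.get((G.individual_ids[i], G.marker_ids[j]))
                    gt += ":" + (f"{pair[0]},{pair[1]}" if pair else ".,.")
                cells.append(gt)
            fh.write(f"{G.chrom[j]}\t{int(G.pos[j])}\t{G.marker_ids[j]}"
                     f"\tA\tT\t.\tPASS\t.\t{fmt}\t" + "\t".join(cells) + "\n")


def read_vcf(path):
    """Read a biallelic-SNP VCF into (GenotypeMatrix, AllelicDepth DataFrame).

    Multi-allelic records are rejected.  The depth table lists every call
    with an AD field, flagging heterozygous genotypes; it is empty when the
    file carries no AD.
    """
    ind_ids = None
    dosage_rows, miss_rows, chroms, poss, mids = [], [], [], [], []
    ad_rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                ind_ids = line.split("\t")[9:]
                continue
            parts = line.split("\t")
            chrom, pos, mid, ref, alt = parts[0], parts[1], parts[2], parts[3], parts[4]
            if "," in alt:
                raise ValueError(f"multi-allelic record at {chrom}:{pos}")
            fmt = parts[8].split(":")
            gt_i = fmt.index("GT")
            ad_i = fmt.index("AD") if "AD" in fmt else None
            drow, mrow = [], []
            for sample, cell in zip(ind_ids, parts[9:]):
                fields = cell.split(":")
                gt = fields[gt_i].replace("|", "/")
                if "." in gt:
                    drow.append(0.0)
                    mrow.append(True)
                    dose = None
                else:
                    dose = sum(int(x) for x in gt.split("/"))
                    drow.append(float(dose))
                    mrow.append(False)
                if ad_i is not None and len(fields) > ad_i and fields[ad_i] != ".,.":
                    try:
                        r, a = (int(x) for x in fields[ad_i].split(","))
                    except ValueError:
                        continue
                    ad_rows.append((sample, mid, r, r + a, dose == 1))
            dosage_rows.append(drow)
            miss_rows.append(mrow)
            chroms.append(chrom)
            poss.append(int(pos))
            mids.append(mid)
    G = GenotypeMatrix(
        dosage=np.array(dosage_rows, dtype=float).T,
        missing=np.array(miss_rows, dtype=bool).T,
        individual_ids=np.array(ind_ids),
        marker_ids=np.array(mids),
        chrom=np.array(chroms),
        pos=np.array(poss),
    )
    ad = pd.DataFrame(ad_rows, columns=["individual", "marker", "ref_depth",
                                        "total_depth", "is_het"])
    return G, ad


def write_dosage(G: GenotypeMatrix, path, sep: str = "\t") -> None:
    """Delimited dosage matrix: rows = individuals, columns = markers."""
    df = pd.DataFrame(np.where(G.missing, np.nan, G.dosage),
                      index=G.individual_ids, columns=G.marker_ids)
    df.to_csv(path, sep=sep)


def read_dosage(path, sep: str = "\t") -> GenotypeMatrix:
    df = pd.read_csv(path, sep=sep, index_col=0)
    vals = df.to_numpy(dtype=float)
    return GenotypeMatrix(dosage=np.nan_to_num(vals),
                          missing=np.isnan(vals),
                          individual_ids=df.index.to_numpy(),
                          marker_ids=df.columns.to_numpy())


def write_kernel(K: KernelMatrix, path) -> None:
    pd.DataFrame(K.values, index=K.ids, columns=K.ids).to_csv(path)


def read_kernel(path, kind: str = "GRM") -> KernelMatrix:
    df = pd.read_csv(path, index_col=0)
    return KernelMatrix(values=df.to_numpy(dtype=float),
                        ids=df.index.to_numpy(), kind=kind)
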