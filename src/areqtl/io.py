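"""Readers and writers for the pipeline's on-disk formats.

Expression and dosage matrices travel as TSV (rows x samples with a header
row); genotypes also round-trip through VCF 4.2 (GT field, 1-based
positions, read back via cyvcf2); sequences are FASTA via Biopython; gene
sets are GMT (see :func:`areqtl.enrichment.read_gmt`); ground truth is JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GenotypeMatrix, GroundTruth, InputError


def read_expression_tsv(path, detection_path=None) -> ExpressionMatrix:
    vals = pd.read_csv(path, sep="\t", index_col=0)
    det = None
    if detection_path is not None:
        det = pd.read_csv(detection_path, sep="\t", index_col=0).astype(bool)
    return ExpressionMatrix(vals, det)


def write_expression_tsv(x: ExpressionMatrix, path, detection_path=None) -> None:
    x.values.to_csv(path, sep="\t")
    if detection_path is not None:
        if x.detection is None:
            raise InputError("no detection flags to write")
        x.detection.astype(int).to_csv(detection_path, sep="\t")


def read_samples_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_samples_tsv(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t")


def read_regions_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"probe", "chrom", "start", "end"}
    if not need <= set(df.columns):
        raise InputError(f"regions TSV needs columns {sorted(need)}")
    return df


def read_dosage_tsv(path, meta_path=None) -> GenotypeMatrix:
    dos = pd.read_csv(path, sep="\t", index_col=0)
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    else:
        meta = pd.DataFrame({"chrom": "chr0", "pos": np.arange(1, len(dos) + 1),
                             "ref": "A", "alt": "G", "snp_class": "unknown"},
                            index=dos.index)
    return GenotypeMatrix(dos, meta)


def write_dosage_tsv(g: GenotypeMatrix, path, meta_path=None) -> None:
    g.dosage.to_csv(path, sep="\t")
    if meta_path is not None:
        g.meta.to_csv(meta_path, sep="\t")


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=areqtl
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write genotypes as VCF 4.2 with a GT field; dosage 1 is counted on
    the ALT allele, missing calls become ./."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    samples = list(g.samples)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        contigs = pd.unique(g.meta["chrom"])
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        order = g.meta.sort_values(["chrom", "pos"]).index
        for snp in order:
            m = g.meta.loc[snp]
            row = g.dosage.loc[snp]
            gts = "\t".join(gt_map.get(v, "./.") if not np.isnan(v) else "./."
                            for v in row.to_numpy(dtype=float))
            fh.write(f"{m['chrom']}\t{int(m['pos'])}\t{snp}\t{m['ref']}\t"
                     f"{m['alt']}\t.\t.\t.\tGT\t{gts}\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix; GT is parsed to ALT-allele dosage
    and then re-oriented so dosage counts the minor allele (frequency ties
    broken by allele lexicographic order)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    ids, rows, meta_rows = [], [], []
    for var in vcf:
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = var.gt_types.astype(float)
        dos = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], np.nan)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        rows.append(dos)
        alt = var.ALT[0] if var.ALT else "N"
        meta_rows.append((var.CHROM, var.POS, var.REF, alt, "unknown"))
    dosage = pd.DataFrame(rows, index=pd.Index(ids, name="snp"), columns=samples)
    meta = pd.DataFrame(meta_rows, columns=["chrom", "pos", "ref", "alt",
                                            "snp_class"], index=dosage.index)
    arr = dosage.to_numpy()
    freq = np.nanmean(arr, axis=1) / 2
    flip = (freq > 0.5) | ((freq == 0.5)
                           & (meta["alt"].to_numpy() < meta["ref"].to_numpy()))
    arr[flip] = 2 - arr[flip]
    meta.loc[flip, ["ref", "alt"]] = meta.loc[flip, ["alt", "ref"]].to_numpy()
    return GenotypeMatrix(pd.DataFrame(arr, index=dosage.index, columns=samples),
                          meta)


def write_fasta(seqs: dict[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    seqio_write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    from Bio.SeqIO import parse

    return {rec.id: str(rec.seq).upper() for rec in parse(str(path), "fasta")}


def read_snp_table(path) -> pd.DataFrame:
    """SNP list TSV: seq_id, offset (0-based), ref, alt."""
    df = pd.read_csv(path, sep="\t")
    need = {"seq_id", "offset", "ref", "alt"}
    if not need <= set(df.columns):
        raise InputError(f"SNP TSV needs columns {sorted(need)}")
    return df


def write_truth_json(truth: GroundTruth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1))


def read_truth_json(path) -> GroundTruth:
    return GroundTruth.from_dict(json.loads(Path(path).read_text()))
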