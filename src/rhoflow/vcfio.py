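"""VCF input/output for haplotype samples.

Samples are written as VCF v4.2 with a single contig "1" of length L,
1-based positions (internal coordinates are 0-based), fixed REF/ALT letters
A/T (the simulator tracks ancestral/derived state only), and phased diploid
genotypes pairing adjacent haplotypes.  Reading uses cyvcf2 and therefore
also accepts third-party VCFs with biallelic SNVs and phased genotypes;
unphased or multi-allelic records are rejected with the offending record
named.
"""

from __future__ import annotations

import warnings

import numpy as np

from .wf import SampleSet

__all__ = ["write_vcf", "read_vcf"]

_HEADER_PREFIX = "rhoflow"


def write_vcf(sample: SampleSet, path) -> None:
    """Write a SampleSet as a phased diploid VCF v4.2."""
    if sample.n_hap % 2:
        raise ValueError("haplotype count must be even (diploid samples)")
    n_dip = sample.n_hap // 2
    names = [f"ind{i}" for i in range(n_dip)]
    meta = {
        "population": sample.population,
        "generation_model": sample.generation_model,
        "generation_actual": sample.generation_actual,
        "replicate_id": sample.replicate_id,
        **sample.metadata,
    }
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID=1,length={sample.L}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for key, val in meta.items():
            fh.write(f"##{_HEADER_PREFIX}_{key}={val}\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(names)
            + "\n"
        )
        H = sample.H
        for j, pos in enumerate(sample.positions):
            gts = "\t".join(
                f"{H[2 * i, j]}|{H[2 * i + 1, j]}" for i in range(n_dip)
            )
            fh.write(f"1\t{pos + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path) -> SampleSet:
    """Read a phased diploid single-contig VCF into a SampleSet.

    Inverse of :func:`write_vcf` on files it produced; multi-allelic or
    unphased records are rejected with their record number.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    L = 0
    meta: dict = {}
    for line in vcf.raw_header.splitlines():
        if line.startswith("##contig"):
            for field in line.strip("<>").split(","):
                if field.startswith("length"):
                    L = int(field.split("=")[1].rstrip(">"))
        elif line.startswith(f"##{_HEADER_PREFIX}_"):
            key, _, val = line[2 + len(_HEADER_PREFIX) + 1 :].partition("=")
            meta[key] = val
    n_dip = len(vcf.samples)
    positions, columns = [], []
    for k, rec in enumerate(vcf, start=1):
        if len(rec.ALT) != 1:
            raise ValueError(f"record {k} (POS {rec.POS}): not biallelic")
        gts = rec.genotypes  # [a0, a1, phased] per sample
        col = np.empty(2 * n_dip, dtype=np.uint8)
        for i, g in enumerate(gts):
            if len(g) < 3 or not g[2]:
                raise ValueError(
                    f"record {k} (POS {rec.POS}), sample {vcf.samples[i]}: unphased genotype"
                )
            if g[0] < 0 or g[1] < 0:
                raise ValueError(
                    f"record {k} (POS {rec.POS}), sample {vcf.samples[i]}: missing genotype"
                )
            col[2 * i] = g[0]
            col[2 * i + 1] = g[1]
        positions.append(rec.POS - 1)
        columns.append(col)
    if not positions:
        warnings.warn(f"{path}: no variant records; returning empty sample")
        H = np.empty((2 * n_dip, 0), dtype=np.uint8)
        pos_arr = np.empty(0, dtype=np.int64)
    else:
        H = np.stack(columns, axis=1)
        pos_arr = np.asarray(positions, dtype=np.int64)
    keep_meta = {
        k: v
        for k, v in meta.items()
        if k not in ("population", "generation_model", "generation_actual", "replicate_id")
    }
    return SampleSet(
        positions=pos_arr,
        H=H,
        population=meta.get("population", "p1"),
        L=L or (int(pos_arr[-1]) + 1 if len(pos_arr) else 0),
        generation_model=int(meta.get("generation_model", 0)),
        generation_actual=float(meta.get("generation_actual", 0.0)),
        replicate_id=int(meta.get("replicate_id", 0)),
        metadata=keep_meta,
    )
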