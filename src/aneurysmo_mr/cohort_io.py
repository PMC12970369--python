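"""On-disk form of a synthetic cohort.

A cohort directory holds ``cohort.vcf`` (one DS-dosage FORMAT field per
sample), ``samples.tsv`` (covariates, lipids, AAA status keyed by sample
ID) and ``dx.tsv`` (long-format diagnosis codes: sample_id, system,
code, ISO-8601 date).  The VCF is written directly (dosage-only records
are line-trivial); reading goes through cyvcf2 when available, with a
plain-text fallback.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .simulate import CohortTable

_VCF_HEADER = """##fileformat=VCFv4.2
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">
"""


def write_cohort(cohort: CohortTable, outdir) -> None:
    os.makedirs(outdir, exist_ok=True)
    samples = cohort.samples
    vm = cohort.variants
    ids = samples["sample_id"].tolist()

    with open(os.path.join(outdir, "cohort.vcf"), "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in pd.unique(vm["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ids) + "\n")
        dos = cohort.dosages
        for j in range(len(vm)):
            row = vm.iloc[j]
            ds = "\t".join(f"{d:.3f}" for d in dos[:, j])
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['variant_id']}\t"
                     f"{row['other_allele']}\t{row['effect_allele']}\t.\t.\t.\tDS\t"
                     f"{ds}\n")

    samples.to_csv(os.path.join(outdir, "samples.tsv"), sep="\t",
                   index=False, float_format="%.10g")
    cohort.dx.to_csv(os.path.join(outdir, "dx.tsv"), sep="\t", index=False)


def read_cohort(outdir) -> CohortTable:
    samples = pd.read_csv(os.path.join(outdir, "samples.tsv"), sep="\t",
                          dtype={"sample_id": str})
    dx = pd.read_csv(os.path.join(outdir, "dx.tsv"), sep="\t",
                     dtype={"sample_id": str, "system": str, "code": str,
                            "date": str})
    vcf_path = os.path.join(outdir, "cohort.vcf")
    rows, dosages = [], []
    try:
        from cyvcf2 import VCF
        vcf = VCF(vcf_path)
        sample_order = list(vcf.samples)
        for v in vcf:
            rows.append((str(v.CHROM), int(v.POS), v.ID, v.ALT[0], v.REF))
            dosages.append(np.asarray(v.format("DS"), dtype=np.float32).ravel())
    except ImportError:  # pragma: no cover - cyvcf2 expected to be present
        with open(vcf_path) as fh:
            sample_order = None
            for line in fh:
                if line.startswith("##"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if line.startswith("#CHROM"):
                    sample_order = parts[9:]
                    continue
                rows.append((parts[0], int(parts[1]), parts[2],
                             parts[4], parts[3]))
                dosages.append(np.asarray(parts[9:], dtype=np.float32))
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "variant_id",
                                           "effect_allele", "other_allele"])
    dos = np.vstack(dosages).T if dosages else np.zeros((len(samples), 0),
                                                        dtype=np.float32)
    if sample_order != samples["sample_id"].tolist():
        order = {s: i for i, s in enumerate(sample_order)}
        dos = dos[[order[s] for s in samples["sample_id"]], :]
    return CohortTable(samples=samples, dosages=dos, variants=variants, dx=dx)
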