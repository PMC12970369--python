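"""Drug-target gene regions (GRCh38-like coordinates, 1-based inclusive).

PCSK9, HMGCR, NPC1L1 and LDLR act primarily on LDL-C; LPL, APOC3 and
APOA5 act primarily on TRL-C.  APOC3 and APOA5 sit ~40 kb apart on
chromosome 11, so with the default 200 kb cis flank their windows
overlap and a variant may instrument both.  The LPA locus is carried for
the lipoprotein(a) exclusion step, not as a drug target.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class GeneRegion:
    gene: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    pathway: str  # "LDL" | "TRL" | ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene}: start > end")

    def contains(self, chrom: str, pos: int, flank: int = 0) -> bool:
        return (str(chrom) == self.chrom
                and self.start - flank <= pos <= self.end + flank)


DRUG_TARGET_REGIONS = [
    GeneRegion("PCSK9", "1", 55_039_447, 55_064_852, "LDL"),
    GeneRegion("HMGCR", "5", 75_336_329, 75_362_104, "LDL"),
    GeneRegion("NPC1L1", "7", 44_552_134, 44_580_929, "LDL"),
    GeneRegion("LPL", "8", 19_939_253, 19_967_259, "TRL"),
    GeneRegion("APOA5", "11", 116_790_106, 116_792_420, "TRL"),
    GeneRegion("APOC3", "11", 116_829_907, 116_833_072, "TRL"),
    GeneRegion("LDLR", "19", 11_089_362, 11_133_820, "LDL"),
]

LPA_REGION = GeneRegion("LPA", "6", 160_531_482, 160_664_275, "")

PATHWAY_GROUPS = {
    "LDL": ["LDLR", "PCSK9", "NPC1L1", "HMGCR"],
    "TRL": ["APOC3", "LPL", "APOA5"],
}


def read_gene_regions(path) -> list:
    """Read a BED-like TSV (chrom, start, end, gene, pathway); a leading
    ``#coords=1-based-inclusive`` pragma line is tolerated and assumed."""
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, start, end, gene, pathway = line.split("\t")[:5]
            regions.append(GeneRegion(gene, chrom, int(start), int(end), pathway))
    if not regions:
        raise ValueError(f"no gene regions found in {path}")
    return regions


def write_gene_regions(regions, path) -> None:
    with open(path, "w") as fh:
        fh.write("#coords=1-based-inclusive\n")
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene}\t{r.pathway}\n")
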