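"""Registry of the 20 candidate-gene markers used throughout the pipeline.

Five historical dyslexia candidate genes (DYX1C1, DCDC2, KIAA0319, ROBO1,
GRIN2B) are covered by 19 SNPs plus the READ1 intron-2 microdeletion of
DCDC2 (a presence/absence marker).  Minor-allele frequencies are the
published estimates in unrelated subjects (probands + typical readers) and
serve as the synthetic generator's defaults.  rs2143340 sits in the TTRAP
region adjacent to KIAA0319 and is grouped with that gene for the per-gene
multiple-testing thresholds (0.05 / number of markers in the gene).
"""

from __future__ import annotations

from dataclasses import dataclass

GENES = ("DYX1C1", "DCDC2", "KIAA0319", "ROBO1", "GRIN2B")

# Five mediator endophenotypes, in canonical model order:
# multisensory warning effect, illusion slope (log), illusion threshold
# (sqrt), rapid auditory processing, rapid naming RT.
MEDIATORS = ("WE", "RTLI_b", "RTLI_t", "RAP", "RAN_rt")


@dataclass(frozen=True)
class VariantInfo:
    """Metadata for one biallelic marker."""

    marker: str
    gene: str
    major: str
    minor: str
    maf: float  # minor-allele frequency in unrelated subjects
    is_deletion: bool = False

    def __post_init__(self) -> None:
        if self.gene not in GENES:
            raise ValueError(f"unknown gene {self.gene!r} for marker {self.marker}")
        if not 0.0 <= self.maf <= 0.5 + 1e-9:
            raise ValueError(f"MAF {self.maf} out of range for marker {self.marker}")


#: Default marker panel: (marker id, gene, major allele, minor allele, MAF).
DEFAULT_VARIANTS: tuple[VariantInfo, ...] = (
    VariantInfo("rs3743205", "DYX1C1", "G", "A", 0.073),
    VariantInfo("rs57809907", "DYX1C1", "G", "T", 0.109),
    VariantInfo("rs189983504", "DYX1C1", "C", "G", 0.101),
    VariantInfo("rs793842", "DCDC2", "C", "T", 0.416),
    VariantInfo("READ1", "DCDC2", "ins", "del", 0.078, is_deletion=True),
    VariantInfo("rs793862", "DCDC2", "G", "A", 0.242),
    VariantInfo("rs4504469", "KIAA0319", "C", "T", 0.366),
    VariantInfo("rs2038137", "KIAA0319", "G", "T", 0.358),
    VariantInfo("rs9461045", "KIAA0319", "C", "T", 0.208),
    VariantInfo("rs2143340", "KIAA0319", "A", "G", 0.161),
    VariantInfo("rs333491", "ROBO1", "A", "G", 0.455),
    VariantInfo("rs6803202", "ROBO1", "T", "C", 0.494),
    VariantInfo("rs9853895", "ROBO1", "C", "T", 0.413),
    VariantInfo("rs7644521", "ROBO1", "T", "C", 0.164),
    VariantInfo("rs5796555", "GRIN2B", "-", "A", 0.306),
    VariantInfo("rs1012586", "GRIN2B", "G", "C", 0.305),
    VariantInfo("rs2268119", "GRIN2B", "A", "T", 0.232),
    VariantInfo("rs2216128", "GRIN2B", "A", "G", 0.216),
    VariantInfo("rs11609779", "GRIN2B", "C", "T", 0.183),
    VariantInfo("rs2192973", "GRIN2B", "G", "A", 0.225),
)

MARKER_IDS: tuple[str, ...] = tuple(v.marker for v in DEFAULT_VARIANTS)


def hwe_alpha(gene: str, variants=DEFAULT_VARIANTS) -> float:
    """Per-gene Bonferroni threshold for the HWE test: 0.05 / markers in gene."""
    k = sum(1 for v in variants if v.gene == gene)
    if k == 0:
        raise ValueError(f"gene {gene!r} has no markers in the panel")
    return 0.05 / k
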