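"""Static genome annotation used for CNV labelling and simulation.

Chromosome lengths and approximate centromere midpoints for GRCh38
(default) and GRCh37. Positions are 1-based; the p arm spans
``[1, centromere]`` and the q arm ``(centromere, length]``. Arm-level
CNV labels only need megabase-scale accuracy, so cytoband-midpoint
centromeres are sufficient here.
"""

from __future__ import annotations

# chrom -> (length, centromere midpoint), GRCh38
CHROMOSOMES_GRCH38: dict[str, tuple[int, int]] = {
    "1": (248_956_422, 123_400_000),
    "2": (242_193_529, 93_900_000),
    "3": (198_295_559, 90_900_000),
    "4": (190_214_555, 50_000_000),
    "5": (181_538_259, 48_800_000),
    "6": (170_805_979, 59_800_000),
    "7": (159_345_973, 60_100_000),
    "8": (145_138_636, 45_200_000),
    "9": (138_394_717, 43_000_000),
    "10": (133_797_422, 39_800_000),
    "11": (135_086_622, 53_400_000),
    "12": (133_275_309, 35_500_000),
    "13": (114_364_328, 17_700_000),
    "14": (107_043_718, 17_200_000),
    "15": (101_991_189, 19_000_000),
    "16": (90_338_345, 36_800_000),
    "17": (83_257_441, 25_100_000),
    "18": (80_373_285, 18_500_000),
    "19": (58_617_616, 26_200_000),
    "20": (64_444_167, 28_100_000),
    "21": (46_709_983, 12_000_000),
    "22": (50_818_468, 15_000_000),
    "X": (156_040_895, 60_600_000),
}

CHROMOSOMES_GRCH37: dict[str, tuple[int, int]] = {
    "1": (249_250_621, 125_000_000),
    "2": (243_199_373, 93_300_000),
    "3": (198_022_430, 91_000_000),
    "4": (191_154_276, 50_400_000),
    "5": (180_915_260, 48_400_000),
    "6": (171_115_067, 61_000_000),
    "7": (159_138_663, 59_900_000),
    "8": (146_364_022, 45_600_000),
    "9": (141_213_431, 49_000_000),
    "10": (135_534_747, 40_200_000),
    "11": (135_006_516, 53_700_000),
    "12": (133_851_895, 35_800_000),
    "13": (115_169_878, 17_900_000),
    "14": (107_349_540, 17_600_000),
    "15": (102_531_392, 19_000_000),
    "16": (90_354_753, 36_600_000),
    "17": (81_195_210, 24_000_000),
    "18": (78_077_248, 17_200_000),
    "19": (59_128_983, 26_500_000),
    "20": (63_025_520, 27_500_000),
    "21": (48_129_895, 13_200_000),
    "22": (51_304_566, 14_700_000),
    "X": (155_270_560, 60_600_000),
}

BUILDS = {"GRCh38": CHROMOSOMES_GRCH38, "GRCh37": CHROMOSOMES_GRCH37}


def arm_table(build: str = "GRCh38") -> dict[str, tuple[int, int]]:
    """Return ``chrom -> (length, centromere)`` for the given build."""
    try:
        return BUILDS[build]
    except KeyError:  # pragma: no cover - trivial guard
        raise ValueError(f"unknown genome build: {build!r}") from None


def normalize_chrom(chrom: str) -> str:
    """Strip a leading 'chr' prefix; keeps X/Y as-is."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def arm_of(chrom: str, start: int, end: int, build: str = "GRCh38",
           arm_fraction: float = 0.9) -> str | None:
    """Assign a segment to 'p' or 'q' when >= ``arm_fraction`` of its
    length lies in one arm, else ``None`` (whole-chromosome scale)."""
    chrom = normalize_chrom(chrom)
    table = arm_table(build)
    if chrom not in table:
        raise KeyError(f"chromosome {chrom!r} missing from arm table ({build})")
    length, cen = table[chrom]
    seg_len = end - start + 1
    p_overlap = max(0, min(end, cen) - start + 1)
    q_overlap = max(0, end - max(start, cen + 1) + 1)
    if p_overlap >= arm_fraction * seg_len:
        return "p"
    if q_overlap >= arm_fraction * seg_len:
        return "q"
    return None


# Representative panel-gene loci (GRCh38) used by the cohort simulator to
# give synthetic small variants plausible coordinates. One locus per gene
# is enough: the analysis only uses gene symbols and CN context.
GENE_LOCI: dict[str, tuple[str, int]] = {
    "NOTCH1": ("9", 136_500_000),   # 9q34.3 — outside the 9p CNV regions
    "PHF6": ("X", 134_373_000),
    "FBXW7": ("4", 152_320_000),
    "PTEN": ("10", 87_900_000),
    "BCL11B": ("14", 99_170_000),
    "USP7": ("16", 8_990_000),
    "KMT2D": ("12", 49_000_000),
    "TP53": ("17", 7_670_000),
    "JAK1": ("1", 64_800_000),
    "PIK3CA": ("3", 179_200_000),
    "PIK3R1": ("5", 68_200_000),
    "NOTCH3": ("19", 15_200_000),
    "DNM2": ("19", 10_800_000),
    "SUZ12": ("17", 31_900_000),
    "SETD1B": ("12", 121_800_000),
}

# Genomic extents used for simulated CNV event labels (GRCh38, 1-based).
CNV_REGIONS: dict[str, tuple[str, int, int]] = {
    "del_in_9p": ("9", 200_000, 39_000_000),
    "LOH_in_9p": ("9", 200_000, 39_000_000),
    "dup_in_9p": ("9", 200_000, 39_000_000),
    "dup20": ("20", 100_000, 64_000_000),
    "del_in_6q": ("6", 62_000_000, 169_000_000),
}
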