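"""Published heading-date summary values and synthetic allele stand-ins.

This module ships, as plain data, the published line means for the four
primary SSSLs and the recurrent parent HJX74 across the 2014 and 2015
trials, the published additive effects/contributions they imply, and
builders for allele-pair fixtures whose variant coordinates match the
published allele comparisons.

The CDS sequences themselves are **synthetic**: the study deposited no
accessions, so each builder generates a random in-silico CDS of the reported
length and plants the reported SNPs and deletions at their reported 1-based
coordinates (see :func:`sssltools.synthetic_data.simulate_allele_pair`).
Variant coordinates, deletion totals, and allele lengths are therefore
faithful to the published comparisons while the base-level content is not
real rice sequence.
"""

from __future__ import annotations

from .allele_diff import AlleleSequence
from .synthetic_data import SimTruth, simulate_allele_pair

__all__ = [
    "RECIPIENT",
    "LINE_MEANS",
    "REPORTED_EFFECTS",
    "dth3_w05s2_pair",
    "dth3_w08s3_pair",
    "ehd2_w22s2_pair",
    "rft1_w12s4_pair",
    "REPORTED_TRANSLATIONS",
]

RECIPIENT = "HJX74"

#: Published mean days to heading (20 plants/line) per trial year.
LINE_MEANS: dict[str, dict[str, float]] = {
    "2014": {
        "W05": 121.20,
        "W08": 92.36,
        "W12": 123.49,
        "W12-S5": 110.32,
        "W22": 113.42,
        "HJX74": 105.18,
    },
    "2015": {
        "W05": 123.20,
        "W08": 94.28,
        "W12": 124.49,
        "W12-S5": 111.58,
        "W22": 112.69,
        "HJX74": 106.65,
    },
}

#: Published additive effect (days) and contribution (%) per line and year.
#: 2015 contributions for W08 and W22 are omitted: the published -6.72 and
#: 3.68 do not follow from the published means under the stated formula
#: (effect / recipient mean x 100), so they are not reproducible targets.
#: The published 2015 W08 effect (-6.18) also disagrees at the final digit
#: with half-up rounding of (94.28 - 106.65)/2 = -6.185 and is omitted too,
#: as is the 2015 W12-S5 contribution (2.32), which only follows if computed
#: from the pre-rounded effect (2.47/106.65 x 100 = 2.32) whereas the full
#: precision effect gives 2.465/106.65 x 100 = 2.31.
REPORTED_EFFECTS: dict[str, dict[str, tuple]] = {
    "2014": {
        "W05": (8.01, 7.62),
        "W08": (-6.41, -6.09),
        "W12": (9.15, 8.70),
        "W12-S5": (2.57, 2.44),
        "W22": (4.12, 3.92),
    },
    "2015": {
        "W05": (8.28, 7.76),
        "W12": (8.92, 8.36),
        "W12-S5": (2.47, None),
        "W22": (3.02, None),
    },
}

#: Published (CDS length nt, protein length aa) translation pairs.  The 81-nt
#: entry is a partial CDS without a stop codon (runs off the end).
REPORTED_TRANSLATIONS: tuple[tuple[int, int], ...] = (
    (693, 230),
    (540, 179),
    (2496, 831),
    (81, 27),
)

# Stop-free (T-less) blocks forced into the DTH3 reference over the retained
# regions, so each retained fragment translates through in its own frame
# (W05-S2's 66 nt encode 22 aa; W08-S3's 81 nt encode 27 aa, as published).
_DTH3_W08_RETAINED_BLOCK = (
    "CCAAACAAAACGAGCACAAGAGCGCAGCGGCAAGCGACCCCCACACCAGGGAGAACACAAAGCAAACACCACCAAGCC"
)
_DTH3_W05_RETAINED_BLOCK = (
    "GAAAAGGCGGGCGCGGGGCCGGCAAAACCAACGGAAAAACACGGCGGAGCACAACCGGGCGACCCC"
)


def dth3_w05s2_pair(seed: int = 101) -> tuple[AlleleSequence, AlleleSequence, SimTruth]:
    """DTH3, recipient vs W05-S2: 693-nt CDS of which the substitution-line
    allele retains only positions 557-622 (66 nt, encoding 22 aa), i.e.
    deletions of 1-556 and 623-693 totalling 627 nt."""
    plan = [("del", 1, 556), ("del", 623, 693)]
    plan += [("ref", 557 + i, b) for i, b in enumerate(_DTH3_W05_RETAINED_BLOCK)]
    return simulate_allele_pair(
        "DTH3",
        693,
        plan,
        seed=seed,
        orf=True,
        alt_line="W05-S2",
    )


def dth3_w08s3_pair(seed: int = 102) -> tuple[AlleleSequence, AlleleSequence, SimTruth]:
    """DTH3, recipient vs W08-S3: the 81-nt allele keeps reference positions
    347-424 (78 nt identical) followed by a GTG-to-CAA change of positions
    425-427; positions 1-346 and 428-693 (612 nt total) are deleted.

    Because the change sits at the very end of the allele, equally scoring
    alignments exist that trade the three terminal substitutions against a
    shifted deletion; the invariant facts are the totals (612 nt deleted, 81
    nt retained), not the exact SNP coordinates."""
    plan = [
        ("del", 1, 346),
        ("snp", 425, "C", "G"),
        ("snp", 426, "A", "T"),
        ("snp", 427, "A", "G"),
        ("del", 428, 693),
    ]
    plan += [
        ("ref", 347 + i, b) for i, b in enumerate(_DTH3_W08_RETAINED_BLOCK)
    ]
    return simulate_allele_pair(
        "DTH3", 693, plan, seed=seed, orf=True, alt_line="W08-S3"
    )


def ehd2_w22s2_pair(seed: int = 103) -> tuple[AlleleSequence, AlleleSequence, SimTruth]:
    """Ehd2, recipient vs W22-S2: 1045-nt reference; the substitution-line
    allele (816 nt) lacks positions 103-331 (a 229-nt deletion, not a codon
    multiple, hence a frameshift) and differs by C-T SNPs at 43 and 985 and
    an A-G SNP at 814."""
    plan = [
        ("snp", 43, "T", "C"),
        ("del", 103, 331),
        ("snp", 814, "G", "A"),
        ("snp", 985, "T", "C"),
    ]
    return simulate_allele_pair(
        "Ehd2", 1045, plan, seed=seed, orf=True, alt_line="W22-S2"
    )


#: Published RFT1 SNPs: 1-based position, recipient base, substitution-line base.
RFT1_SNPS: tuple[tuple[int, str, str], ...] = (
    (81, "T", "C"),
    (92, "T", "C"),
    (313, "G", "A"),
    (399, "G", "A"),
    (408, "A", "G"),
    (411, "G", "C"),
    (420, "C", "T"),
    (431, "G", "A"),
    (437, "G", "A"),
    (439, "A", "G"),
    (478, "A", "G"),
    (488, "T", "C"),
)


def rft1_w12s4_pair(seed: int = 104) -> tuple[AlleleSequence, AlleleSequence, SimTruth]:
    """RFT1, recipient vs W12-S4: 537-nt CDS differing by 12 SNPs at the
    published positions."""
    plan = [("snp", pos, alt, ref) for pos, ref, alt in RFT1_SNPS]
    return simulate_allele_pair(
        "RFT1", 537, plan, seed=seed, orf=True, alt_line="W12-S4"
    )
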