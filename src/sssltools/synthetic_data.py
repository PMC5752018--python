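"""Synthetic SSSL libraries, phenotypes, and allele pairs with known truth.

The generators emulate the experimental design the analysis assumes: a
recurrent parent scored alongside substitution lines, each line carrying one
contiguous marker-delimited homozygous donor segment; per-plant days to
heading Normal around the line mean with 20 plants per line; a homozygous
substitution carrying a QTL of additive effect *a* shifting the line mean by
2a; and allele CDS pairs differing by planted SNPs and contiguous indels at
known 1-based coordinates.

Everything is a pure function of the configuration (including its seed), so
two runs with the same config produce identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .allele_diff import AlleleSequence, Variant
from .genetic_map import (
    GeneticMap,
    Marker,
    SubstitutedSegment,
    format_segment_notation,
    segment_to_interval,
)
from .phenotype_stats import PhenotypeTable

__all__ = [
    "QTLSpec",
    "SimConfig",
    "SimTruth",
    "simulate_library",
    "simulate_phenotypes",
    "simulate_allele_pair",
]

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class QTLSpec:
    """A planted QTL: chromosome, cM position, additive effect in days."""

    chromosome: int
    position: float
    additive_effect: float


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the simulated SSSL experiment.

    Defaults mirror the field trial the analysis targets: 20 scored plants
    per line, a recipient mean of 105.18 days, and residual SD of 3 days
    (per-plant SDs implied by reported line standard errors are roughly 2-4
    days at n = 20).
    """

    seed: int = 0
    n_chromosomes: int = 3
    markers_per_chromosome: int = 15
    chromosome_length: float = 120.0  # cM
    n_lines: int = 12
    plants_per_line: int = 20
    recipient_id: str = "HJX74"
    recipient_mean: float = 105.18  # days
    residual_sd: float = 3.0  # days
    qtls: tuple[QTLSpec, ...] = ()
    epistasis: Optional[tuple[int, int]] = None  # (masking qtl idx, masked qtl idx)
    year: str = "Y1"

    def __post_init__(self) -> None:
        if self.markers_per_chromosome < 3:
            raise ValueError("need at least 3 markers per chromosome to place segments")
        for q in self.qtls:
            if not 0 <= q.position <= self.chromosome_length:
                raise ValueError(f"QTL position {q.position} outside chromosome")
        if self.epistasis is not None:
            i, j = self.epistasis
            if not (0 <= i < len(self.qtls) and 0 <= j < len(self.qtls) and i != j):
                raise ValueError("epistasis indices must name two distinct planted QTLs")


@dataclass
class SimTruth:
    """Ground truth emitted next to the simulated data."""

    qtls: tuple[QTLSpec, ...]
    segments: dict[str, SubstitutedSegment]
    carriers: dict[str, tuple[int, ...]]  # line -> indices into qtls
    expected_line_means: dict[str, float] = field(default_factory=dict)
    planted_variants: dict[str, tuple[Variant, ...]] = field(default_factory=dict)


def _rng(cfg_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg_seed, stream]))


def simulate_library(cfg: SimConfig) -> tuple[GeneticMap, pd.DataFrame, SimTruth]:
    """Simulate a genetic map and one substituted segment per line.

    Markers are laid down at sorted uniform positions; each line receives a
    contiguous run of inner markers with the neighbouring markers as flanks
    (or a chromosome end).  Returns the map, a segments table
    (line_id, donor, chromosome, segment_notation), and the truth record with
    carrier status for every planted QTL.
    """
    rng = _rng(cfg.seed, 0)
    markers = []
    for chrom in range(1, cfg.n_chromosomes + 1):
        pos = np.sort(rng.uniform(0, cfg.chromosome_length, cfg.markers_per_chromosome))
        for i, p in enumerate(pos):
            markers.append(Marker(f"M{chrom:02d}_{i:02d}", chrom, round(float(p), 2)))
    gmap = GeneticMap(markers)

    segments: dict[str, SubstitutedSegment] = {}
    rows = []
    for li in range(cfg.n_lines):
        line = f"L{li:03d}"
        chrom = int(rng.integers(1, cfg.n_chromosomes + 1))
        names = [m.name for m in gmap.markers_on(chrom)]
        i = int(rng.integers(0, len(names) - 1))
        j = int(rng.integers(i, len(names)))
        seg = SubstitutedSegment(
            chromosome=chrom,
            inner_markers=tuple(names[i : j + 1]),
            left_flank=names[i - 1] if i > 0 else None,
            right_flank=names[j + 1] if j + 1 < len(names) else None,
            terminal_label="Short arm" if i == 0 else None,
        )
        segments[line] = seg
        rows.append(
            {
                "line_id": line,
                "donor": "DONOR",
                "chromosome": chrom,
                "segment_notation": format_segment_notation(seg),
            }
        )

    carriers = {}
    for line, seg in segments.items():
        iv = segment_to_interval(seg, gmap)
        carried = tuple(
            qi
            for qi, q in enumerate(cfg.qtls)
            if q.chromosome == seg.chromosome and iv.contains(q.position)
        )
        carriers[line] = carried

    truth = SimTruth(qtls=tuple(cfg.qtls), segments=segments, carriers=carriers)
    return gmap, pd.DataFrame(rows), truth


def expected_line_mean(cfg: SimConfig, carried: Sequence[int]) -> float:
    """Noise-free line mean: recipient mean plus 2a per carried QTL, with a
    masked QTL contributing nothing when its masking QTL is also carried."""
    carried = set(carried)
    if cfg.epistasis is not None:
        masking, masked = cfg.epistasis
        if masking in carried:
            carried = carried - {masked}
    return cfg.recipient_mean + sum(2.0 * cfg.qtls[qi].additive_effect for qi in carried)


def simulate_phenotypes(cfg: SimConfig, truth: SimTruth) -> PhenotypeTable:
    """Per-plant phenotypes for every line plus the recipient.

    plant value = expected line mean + Normal(0, residual_sd).
    """
    rng = _rng(cfg.seed, 1)
    records = []
    lines = [cfg.recipient_id] + sorted(truth.segments)
    for line in lines:
        carried = truth.carriers.get(line, ())
        mu = expected_line_mean(cfg, carried)
        truth.expected_line_means[line] = mu
        noise = rng.normal(0.0, cfg.residual_sd, cfg.plants_per_line) if cfg.residual_sd > 0 else np.zeros(cfg.plants_per_line)
        for pi, eps in enumerate(noise):
            records.append((line, cfg.year, f"{line}_p{pi:02d}", mu + float(eps)))
    return PhenotypeTable.from_records(records)


def _random_cds(rng: np.random.Generator, length: int, orf: bool) -> list[str]:
    """Random DNA; with ``orf`` true, an ATG start and no premature in-frame
    stop.  When the length is a codon multiple the last codon is a TAA stop;
    otherwise the sequence is stop-free (an open reading frame running off the
    end, as for a partial CDS)."""
    seq = list(rng.choice(_BASES, size=length))
    if orf:
        if length < 6:
            raise ValueError("ORF sequences need length >= 6")
        seq[:3] = "ATG"
        ends_in_stop = length % 3 == 0
        if ends_in_stop:
            seq[-3:] = "TAA"
        limit = length - 3 if ends_in_stop else 3 * (length // 3)
        for c in range(3, limit, 3):
            while "".join(seq[c : c + 3]) in _STOPS:
                seq[c : c + 3] = rng.choice(_BASES, size=3)
    return seq


def simulate_allele_pair(
    gene: str,
    length: int,
    plan: Sequence[tuple],
    seed: int = 0,
    orf: bool = True,
    ref_line: str = "HJX74",
    alt_line: str = "SSSL",
) -> tuple[AlleleSequence, AlleleSequence, SimTruth]:
    """Generate a reference CDS and an alternate carrying planted variants.

    ``plan`` entries (1-based inclusive coordinates on the reference):

    - ``("snp", pos, alt_base)`` or ``("snp", pos, alt_base, ref_base)`` to
      also force the reference base (alt_base of "" draws a random non-ref
      base);
    - ``("del", start, end)`` — delete reference positions start..end;
    - ``("ins", after_pos, inserted_seq)`` — insert after reference position
      ``after_pos`` (0 = before the first base);
    - ``("ref", pos, base)`` — force a reference base without a variant
      (both alleles), e.g. to control an indel's boundary context.

    Planted variants must not overlap.  Bases flanking each indel are pinned
    so the indel cannot shift under left-normalization; if a pin would have to
    rewrite a base claimed by another planted variant, the plan is rejected.
    Recovery by :func:`sssltools.allele_diff.compare_alleles` is then
    coordinate-exact provided neighbouring variants are separated by enough
    matching bases (roughly a dozen at the default alignment penalties) that
    no merged representation of two nearby variants can outscore the planted
    one.
    """
    rng = _rng(seed, 2)
    seq = _random_cds(rng, length, orf)

    def other_base(*exclude: str) -> str:
        choices = [b for b in "ACGT" if b not in exclude]
        return str(rng.choice(choices))

    # validate the plan and collect claimed reference spans
    spans: list[tuple[int, int]] = []
    variants: list[tuple] = []
    for entry in plan:
        kind = entry[0]
        if kind == "snp":
            pos = entry[1]
            if not 1 <= pos <= length:
                raise ValueError(f"SNP position {pos} outside sequence")
            spans.append((pos, pos, "snp"))
            variants.append(entry)
        elif kind == "del":
            start, end = entry[1], entry[2]
            if not 1 <= start <= end <= length:
                raise ValueError(f"deletion {start}-{end} outside sequence")
            spans.append((start, end, "del"))
            variants.append(entry)
        elif kind == "ins":
            after, ins = entry[1], str(entry[2]).upper()
            if not 0 <= after <= length:
                raise ValueError(f"insertion anchor {after} outside sequence")
            if not ins or set(ins) - set("ACGT"):
                raise ValueError(f"invalid inserted sequence {entry[2]!r}")
            spans.append((after, after, "ins"))  # occupies no reference base
            variants.append((kind, after, ins))
        elif kind == "ref":
            pos, base = entry[1], str(entry[2]).upper()
            if not 1 <= pos <= length or base not in "ACGT":
                raise ValueError(f"bad ref-base directive {entry!r}")
            seq[pos - 1] = base
        else:
            raise ValueError(f"unknown plan entry kind {kind!r}")
    spans_sorted = sorted(spans)
    for (s1, e1, _k1), (s2, e2, _k2) in zip(spans_sorted, spans_sorted[1:]):
        if s2 <= e1:
            raise ValueError(f"planted variants overlap: {(s1, e1)} and {(s2, e2)}")

    # insertions consume no reference base, so they claim none
    claimed = {p for s, e, k in spans if k != "ins" for p in range(s, e + 1)}

    # force requested SNP reference bases before computing indel contexts
    for entry in variants:
        if entry[0] == "snp" and len(entry) == 4:
            seq[entry[1] - 1] = entry[3].upper()

    def pin(pos: int, *must_differ_from: str) -> None:
        """Ensure the reference base at 1-based ``pos`` differs from the given
        bases, rewriting it unless it is claimed by a planted variant.
        Replacement prefers C (a C can never create a stop codon in any
        reading frame, so pinning cannot truncate an ORF)."""
        if seq[pos - 1] not in must_differ_from:
            return
        if pos in claimed:
            raise ValueError(
                f"cannot pin indel context at position {pos}: claimed by another variant"
            )
        seq[pos - 1] = next(b for b in "CGAT" if b not in must_differ_from)

    for entry in variants:
        if entry[0] == "del":
            start, end = entry[1], entry[2]
            if start > 1:
                pin(start - 1, seq[end - 1])  # blocks a left shift
            if end < length:
                pin(end + 1, seq[start - 1])  # blocks a right shift
        elif entry[0] == "ins":
            after, ins = entry[1], entry[2]
            if after >= 1:
                pin(after, ins[-1])
            if after < length:
                pin(after + 1, ins[0])

    # reference is now final; record truth and build right-to-left edits
    edits: list[tuple] = []
    truth_variants: list[Variant] = []
    for entry in sorted(variants, key=lambda e: e[1], reverse=True):
        kind = entry[0]
        if kind == "snp":
            pos = entry[1]
            ref_b = seq[pos - 1]
            alt_b = entry[2].upper() if entry[2] else other_base(ref_b)
            if alt_b == ref_b:
                raise ValueError(f"SNP at {pos}: alt equals ref base {ref_b}")
            edits.append((pos - 1, pos, alt_b))
            truth_variants.append(Variant("snp", pos, pos, ref_b, alt_b))
        elif kind == "del":
            start, end = entry[1], entry[2]
            deleted = "".join(seq[start - 1 : end])
            edits.append((start - 1, end, ""))
            truth_variants.append(Variant("deletion", start, end, deleted, ""))
        else:  # ins
            after, ins = entry[1], entry[2]
            edits.append((after, after, ins))
            truth_variants.append(Variant("insertion", after, after, "", ins))

    alt_seq = list(seq)
    for start0, end0, repl in edits:  # already right-to-left
        alt_seq[start0:end0] = list(repl)

    ref = AlleleSequence(gene=gene, line_id=ref_line, seq="".join(seq))
    alt = AlleleSequence(gene=gene, line_id=alt_line, seq="".join(alt_seq))
    truth = SimTruth(
        qtls=(),
        segments={},
        carriers={},
        planted_variants={gene: tuple(sorted(truth_variants, key=lambda v: v.ref_start))},
    )
    return ref, alt, truth
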