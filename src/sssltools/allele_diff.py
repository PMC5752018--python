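"""Pairwise CDS allele comparison: alignment, variants, protein consequences.

Compares the coding sequence of a gene cloned from a substitution line
against the recurrent parent's allele: global affine-gap alignment, variant
extraction (SNPs and maximally merged, left-normalized indels with 1-based
inclusive reference coordinates), translation-level consequences (frameshift,
premature stop, substitutions), physicochemical protein profiles, and simple
primer quality checks.

Alignment and protein arithmetic are delegated to Biopython
(:class:`Bio.Align.PairwiseAligner`, ``Bio.SeqUtils``); variant extraction,
consequence classification and primer checks are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp, ProtParamData
from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from scipy.optimize import brentq

__all__ = [
    "AlleleSequence",
    "AlignParams",
    "PairAlignment",
    "Variant",
    "VariantReport",
    "ProteinConsequence",
    "ProteinProfile",
    "PrimerParams",
    "PrimerReport",
    "align_pair",
    "call_variants",
    "compare_alleles",
    "translate_cds",
    "protein_consequence",
    "protein_properties",
    "check_primer",
]

_DNA = set("ACGT")
_DNA_N = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _validate_dna(seq: str, allow_n: bool = False, what: str = "sequence") -> str:
    s = seq.upper().replace("U", "T")
    alphabet = _DNA_N if allow_n else _DNA
    bad = set(s) - alphabet
    if bad:
        raise ValueError(f"non-ACGT symbol(s) {sorted(bad)} in {what}")
    if not s:
        raise ValueError(f"empty {what}")
    return s


@dataclass(frozen=True)
class AlleleSequence:
    """A CDS allele of one gene from one line; coordinates are 1-based inclusive."""

    gene: str
    line_id: str
    seq: str
    allow_n: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "seq", _validate_dna(self.seq, self.allow_n, f"{self.gene}/{self.line_id}")
        )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AlignParams:
    """Affine-gap global alignment scores.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend`` (the opening
    residue carries the open score).  Ties are broken deterministically by
    taking Biopython's first reported optimal alignment; indel coordinates are
    subsequently left-normalized, so tie placement does not leak into variant
    coordinates in unambiguous contexts.
    """

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -8.0
    gap_extend: float = -1.0


@dataclass(frozen=True)
class PairAlignment:
    ref: AlleleSequence
    alt: AlleleSequence
    aligned_ref: str
    aligned_alt: str
    score: float

    @property
    def identity(self) -> float:
        """Matching columns over alignment length."""
        matches = sum(a == b and a != "-" for a, b in zip(self.aligned_ref, self.aligned_alt))
        return matches / len(self.aligned_ref)


def align_pair(
    ref: AlleleSequence, alt: AlleleSequence, params: AlignParams = AlignParams()
) -> PairAlignment:
    """Global pairwise alignment of two allele CDSs with affine gap penalties."""
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=params.match,
        mismatch_score=params.mismatch,
        open_gap_score=params.gap_open,
        extend_gap_score=params.gap_extend,
    )
    aln = aligner.align(ref.seq, alt.seq)[0]
    return PairAlignment(
        ref=ref, alt=alt, aligned_ref=str(aln[0]), aligned_alt=str(aln[1]), score=float(aln.score)
    )


@dataclass(frozen=True)
class Variant:
    """One difference on the reference, 1-based inclusive coordinates.

    For insertions ``ref_start == ref_end`` is the reference base *after
    which* the insertion occurs (0 for an insertion before the first base)
    and ``ref_allele`` is empty; for deletions ``alt_allele`` is empty.
    """

    kind: str  # "snp" | "insertion" | "deletion"
    ref_start: int
    ref_end: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.kind == "snp":
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError("SNP alleles must be single bases")
            if self.ref_start != self.ref_end:
                raise ValueError("SNP must span one position")
        elif self.kind == "deletion":
            if self.alt_allele or not self.ref_allele:
                raise ValueError("deletion must have ref allele only")
            if len(self.ref_allele) != self.ref_end - self.ref_start + 1:
                raise ValueError("deletion length inconsistent with coordinates")
        elif self.kind == "insertion":
            if self.ref_allele or not self.alt_allele:
                raise ValueError("insertion must have alt allele only")
            if self.ref_start != self.ref_end:
                raise ValueError("insertion anchors at a single reference position")
        else:
            raise ValueError(f"unknown variant kind {self.kind!r}")

    @property
    def length(self) -> int:
        return max(len(self.ref_allele), len(self.alt_allele))


@dataclass(frozen=True)
class VariantReport:
    gene: str
    ref_line: str
    alt_line: str
    variants: tuple[Variant, ...]
    alignment_identity: float

    @property
    def snps(self) -> tuple[Variant, ...]:
        return tuple(v for v in self.variants if v.kind == "snp")

    @property
    def n_snps(self) -> int:
        return sum(v.kind == "snp" for v in self.variants)

    @property
    def n_insertions(self) -> int:
        return sum(v.kind == "insertion" for v in self.variants)

    @property
    def n_deletions(self) -> int:
        return sum(v.kind == "deletion" for v in self.variants)

    @property
    def total_deleted_nt(self) -> int:
        return sum(v.length for v in self.variants if v.kind == "deletion")

    @property
    def total_inserted_nt(self) -> int:
        return sum(v.length for v in self.variants if v.kind == "insertion")


def _left_normalize(kind: str, start: int, allele: str, ref: str) -> tuple[int, str]:
    """Shift an indel left while the base before it equals its last base
    (VCF-style normalization on the reference).  ``start`` is the 1-based
    first deleted base (deletion) or the anchor base (insertion)."""
    allele = allele
    if kind == "deletion":
        while start > 1 and ref[start - 2] == allele[-1]:
            allele = ref[start - 2] + allele[:-1]
            start -= 1
    else:  # insertion anchored after position `start`
        while start > 0 and ref[start - 1] == allele[-1]:
            allele = ref[start - 1] + allele[:-1]
            start -= 1
    return start, allele


def call_variants(alignment: PairAlignment) -> VariantReport:
    """Extract SNPs and maximally merged indels from a pairwise alignment.

    Adjacent gap columns on the same side are merged into a single indel;
    adjacent mismatch columns stay separate SNPs (matching how substitution
    runs are conventionally counted).  Indels are left-normalized so their
    coordinates are reproducible in repeat contexts.
    """
    ra, aa = alignment.aligned_ref, alignment.aligned_alt
    ref = alignment.ref.seq
    variants: list[Variant] = []
    ref_pos = 0  # 1-based position of the last consumed reference base
    i = 0
    n = len(ra)
    while i < n:
        if ra[i] != "-" and aa[i] != "-":
            ref_pos += 1
            if ra[i] != aa[i]:
                variants.append(
                    Variant("snp", ref_pos, ref_pos, ra[i], aa[i])
                )
            i += 1
        elif aa[i] == "-":  # deletion from the reference
            start = ref_pos + 1
            deleted = []
            while i < n and aa[i] == "-":
                deleted.append(ra[i])
                ref_pos += 1
                i += 1
            s, allele = _left_normalize("deletion", start, "".join(deleted), ref)
            variants.append(Variant("deletion", s, s + len(allele) - 1, allele, ""))
        else:  # insertion relative to the reference
            inserted = []
            while i < n and ra[i] == "-":
                inserted.append(aa[i])
                i += 1
            s, allele = _left_normalize("insertion", ref_pos, "".join(inserted), ref)
            variants.append(Variant("insertion", s, s, "", allele))
    variants.sort(key=lambda v: (v.ref_start, v.kind))
    return VariantReport(
        gene=alignment.ref.gene,
        ref_line=alignment.ref.line_id,
        alt_line=alignment.alt.line_id,
        variants=tuple(variants),
        alignment_identity=alignment.identity,
    )


def compare_alleles(
    ref: AlleleSequence, alt: AlleleSequence, params: AlignParams = AlignParams()
) -> VariantReport:
    """Align two alleles and call variants in one step."""
    return call_variants(align_pair(ref, alt, params))


def translate_cds(seq: AlleleSequence | str) -> str:
    """Translate a CDS with the standard genetic code.

    Translation starts at position 1 and stops at the first stop codon (the
    stop is not counted in the protein length).  A trailing partial codon is
    dropped with a warning; a missing stop codon also warns.
    """
    dna = seq.seq if isinstance(seq, AlleleSequence) else _validate_dna(str(seq))
    if len(dna) < 3:
        raise ValueError("CDS shorter than one codon")
    trailing = len(dna) % 3
    if trailing:
        warnings.warn(
            f"CDS length {len(dna)} is not a multiple of 3; dropping {trailing} trailing nt",
            stacklevel=2,
        )
        dna = dna[: len(dna) - trailing]
    full = str(Seq(dna).translate())
    protein = full.split("*")[0]
    if "*" not in full:
        warnings.warn("CDS has no stop codon; translated to the end", stacklevel=2)
    return protein


@dataclass(frozen=True)
class ProteinConsequence:
    ref_protein_length: int
    alt_protein_length: int
    n_substitutions: int
    frameshift: bool
    frameshift_codon: Optional[int]  # first affected codon (1-based, ref frame)
    premature_stop: bool
    stop_position_aa: Optional[int]  # alt protein length when stop is premature
    identical: bool


def protein_consequence(
    ref: AlleleSequence, alt: AlleleSequence, params: AlignParams = AlignParams()
) -> ProteinConsequence:
    """Classify the protein-level consequence of the differences between two
    allele CDSs.

    A frameshift is called when the net indel length upstream of the reference
    stop codon is not a multiple of 3; a premature stop when the alt protein
    terminates before the reference protein does.  Substitutions are counted
    over the aligned equal-length portion of the two proteins.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ref_prot = translate_cds(ref)
        alt_prot = translate_cds(alt)
    if ref_prot == alt_prot:
        return ProteinConsequence(
            ref_protein_length=len(ref_prot),
            alt_protein_length=len(alt_prot),
            n_substitutions=0,
            frameshift=False,
            frameshift_codon=None,
            premature_stop=False,
            stop_position_aa=None,
            identical=True,
        )

    report = compare_alleles(ref, alt, params)
    coding_end_nt = 3 * (len(ref_prot) + 1)  # includes the ref stop codon
    net = 0
    first_indel_nt: Optional[int] = None
    for v in report.variants:
        if v.kind == "insertion" and v.ref_start < coding_end_nt:
            net += v.length
            first_indel_nt = first_indel_nt or max(v.ref_start, 1)
        elif v.kind == "deletion" and v.ref_start <= coding_end_nt:
            net -= v.length
            first_indel_nt = first_indel_nt or v.ref_start
    frameshift = net % 3 != 0
    frameshift_codon = (first_indel_nt + 2) // 3 if frameshift and first_indel_nt else None

    premature = len(alt_prot) < len(ref_prot)
    m = min(len(ref_prot), len(alt_prot))
    n_sub = sum(a != b for a, b in zip(ref_prot[:m], alt_prot[:m]))
    return ProteinConsequence(
        ref_protein_length=len(ref_prot),
        alt_protein_length=len(alt_prot),
        n_substitutions=n_sub,
        frameshift=frameshift,
        frameshift_codon=frameshift_codon,
        premature_stop=premature,
        stop_position_aa=len(alt_prot) if premature else None,
        identical=False,
    )


@dataclass(frozen=True)
class ProteinProfile:
    """ProtParam/ProtScale-style physicochemical summary of a protein."""

    length: int
    molecular_weight: float  # Da, average isotopic masses
    theoretical_pi: float
    gravy: float
    aa_composition: dict[str, float]
    hydropathy_profile: tuple[float, ...]
    window: int


def protein_properties(protein: str, window: int = 9) -> ProteinProfile:
    """Physicochemical profile: average-mass MW, theoretical pI, GRAVY, amino
    acid composition, and a centered Kyte-Doolittle hydropathy profile.

    The pI is the root of the Henderson-Hasselbalch net-charge function
    (Bjellqvist pKa set, as in ProtParam), located by bisection to 1e-6 pH.
    """
    protein = protein.upper()
    bad = set(protein) - set("ACDEFGHIKLMNPQRSTVWY")
    if bad:
        raise ValueError(f"unknown residue(s) {sorted(bad)}")
    if not protein:
        raise ValueError("empty protein")
    pa = ProteinAnalysis(protein)
    ip = IsoelectricPoint(protein)
    pi = float(brentq(ip.charge_at_pH, 0.0, 14.0, xtol=1e-6))
    if len(protein) >= window:
        profile = tuple(float(v) for v in pa.protein_scale(ProtParamData.kd, window))
    else:
        profile = ()
    comp = {aa: protein.count(aa) / len(protein) for aa in sorted(set(protein))}
    return ProteinProfile(
        length=len(protein),
        molecular_weight=float(pa.molecular_weight()),
        theoretical_pi=pi,
        gravy=float(pa.gravy()),
        aa_composition=comp,
        hydropathy_profile=profile,
        window=window,
    )


@dataclass(frozen=True)
class PrimerParams:
    """Primer acceptance windows (targets follow common SSR-primer practice:
    18-25 nt, ~50% GC, Tm ~55 C)."""

    min_length: int = 18
    max_length: int = 25
    gc_target: float = 50.0
    gc_tolerance: float = 10.0  # percentage points
    tm_target: float = 55.0
    tm_tolerance: float = 3.0  # degrees C
    tm_method: str = "wallace"  # or "nearest_neighbor"
    min_hairpin_stem: int = 6  # self-complementary run length that flags
    min_hairpin_loop: int = 3


@dataclass(frozen=True)
class PrimerReport:
    seq: str
    length: int
    gc_percent: float
    tm: float
    max_self_complementary_run: int
    passed: bool
    failures: tuple[str, ...]


def _max_self_complementary_run(seq: str, min_loop: int) -> int:
    """Longest stem of a perfect hairpin: the longest substring whose reverse
    complement also occurs, separated by a loop of at least ``min_loop`` nt."""
    n = len(seq)
    rc = seq.translate(_COMPLEMENT)[::-1]
    best = 0
    for L in range(n // 2, 0, -1):
        if L <= best:
            break
        for i in range(n - L + 1):
            stem = seq[i : i + L]
            # search for the reverse complement downstream of the loop
            j = seq.find(stem.translate(_COMPLEMENT)[::-1], i + L + min_loop)
            if j != -1:
                best = L
                break
    return best


def check_primer(seq: str, params: PrimerParams = PrimerParams()) -> PrimerReport:
    """Quality-check one primer: length, GC content, melting temperature, and
    hairpin/self-dimer potential.

    Tm uses the Wallace rule (2(A+T) + 4(G+C)) by default; a
    nearest-neighbor estimate (Biopython ``Tm_NN``) is available via
    ``params.tm_method``.
    """
    s = _validate_dna(seq, what="primer")
    gc = 100.0 * sum(b in "GC" for b in s) / len(s)
    if params.tm_method == "wallace":
        tm = float(MeltingTemp.Tm_Wallace(s))
    elif params.tm_method == "nearest_neighbor":
        tm = float(MeltingTemp.Tm_NN(s))
    else:
        raise ValueError(f"unknown tm_method {params.tm_method!r}")
    run = _max_self_complementary_run(s, params.min_hairpin_loop)

    failures = []
    if not params.min_length <= len(s) <= params.max_length:
        failures.append(
            f"length {len(s)} outside [{params.min_length}, {params.max_length}]"
        )
    if abs(gc - params.gc_target) > params.gc_tolerance:
        failures.append(
            f"GC {gc:.1f}% outside {params.gc_target}+/-{params.gc_tolerance}%"
        )
    if abs(tm - params.tm_target) > params.tm_tolerance:
        failures.append(
            f"Tm {tm:.1f}C outside {params.tm_target}+/-{params.tm_tolerance}C"
        )
    if run >= params.min_hairpin_stem:
        failures.append(
            f"self-complementary run of {run} nt (hairpin/self-dimer risk)"
        )
    return PrimerReport(
        seq=s,
        length=len(s),
        gc_percent=gc,
        tm=tm,
        max_self_complementary_run=run,
        passed=not failures,
        failures=tuple(failures),
    )
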