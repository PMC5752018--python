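"""Substitution mapping, allelic-effect estimation, and epistasis calls.

Substitution mapping delimits a QTL using presence/absence calls across
substitution lines whose donor segments overlap: the QTL must lie inside
every phenotype-positive line's segment (intersection) and outside every
phenotype-negative line's segment (subtraction).  When the subtraction splits
the candidate region, each disjoint piece is reported as its own QTL.

For a homozygous substitution the line mean differs from the recipient mean
by twice the additive effect, so

    additive effect (days)    = (line mean - recipient mean) / 2
    additive contribution (%) = additive effect / recipient mean * 100
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .genetic_map import (
    CMInterval,
    GeneticMap,
    SubstitutedSegment,
    format_segment_notation,
    intersect,
    segment_to_interval,
    subtract,
)
from .phenotype_stats import PhenotypeTable

__all__ = [
    "QTLInterval",
    "QTLEffect",
    "EpistasisRelation",
    "EpistasisCall",
    "InconsistentCallsError",
    "round_report",
    "additive_effect",
    "additive_contribution",
    "name_qtl",
    "map_qtl",
    "classify_epistasis",
]


class InconsistentCallsError(ValueError):
    """Raised when presence calls admit no QTL location (empty candidate region)."""


def round_report(x: float, decimals: int = 2) -> float:
    """Round half-up at ``decimals`` for report output.

    The value is first snapped to 15 significant digits so that one-ulp
    binary-float noise from differencing decimal inputs (e.g. 123.49 - 105.18
    evaluating a hair below 18.31) does not flip a decimal tie.  Computation
    keeps full precision; this is applied only when rendering tables.
    """
    return float(Decimal(f"{x:.15g}").quantize(Decimal(str(10.0**-decimals)), rounding=ROUND_HALF_UP))


def additive_effect(line_mean: float, recipient_mean: float) -> float:
    """Additive effect in trait units: (line mean - recipient mean) / 2."""
    if line_mean <= 0 or recipient_mean <= 0:
        raise ValueError("means must be positive")
    return (line_mean - recipient_mean) / 2.0


def additive_contribution(effect: float, recipient_mean: float) -> float:
    """Additive effect as a percentage of the recipient mean."""
    if recipient_mean <= 0:
        raise ValueError("recipient mean must be positive")
    return effect / recipient_mean * 100.0


def name_qtl(trait_code: str, chromosome: int, index_on_chromosome: Optional[int] = None) -> str:
    """QTL name: ``q`` + trait code + chromosome, with an index suffix when
    several QTLs for the trait share a chromosome (qHD-6-1, qHD-6-2)."""
    if not trait_code:
        raise ValueError("trait code must be non-empty")
    name = f"q{trait_code}-{chromosome}"
    if index_on_chromosome is not None:
        name += f"-{index_on_chromosome}"
    return name


@dataclass(frozen=True)
class QTLInterval:
    name: str
    chromosome: int
    interval: CMInterval
    delimiting_notation: Optional[str]

    @property
    def length(self) -> float:
        return self.interval.length


@dataclass(frozen=True)
class QTLEffect:
    qtl_name: str
    line_id: str
    year: str
    additive_effect: float
    additive_contribution: float


def _interval_notation(interval: CMInterval, gmap: GeneticMap) -> Optional[str]:
    """Render a cM interval as hyphen notation: markers inside it as inner
    markers, nearest outside markers as flanks.  None when no marker falls
    inside the interval."""
    markers = gmap.markers_on(interval.chromosome)
    inner = [m.name for m in markers if interval.contains(m.position)]
    if not inner:
        return None
    left = [m.name for m in markers if m.position < interval.start]
    right = [m.name for m in markers if m.position > interval.end]
    seg = SubstitutedSegment(
        chromosome=interval.chromosome,
        inner_markers=tuple(inner),
        left_flank=left[-1] if left else None,
        right_flank=right[0] if right else None,
    )
    return format_segment_notation(seg)


def map_qtl(
    segments: Mapping[str, SubstitutedSegment],
    calls: Mapping[str, bool],
    gmap: GeneticMap,
    trait_code: str = "HD",
) -> list[QTLInterval]:
    """Delimit QTL interval(s) on one chromosome from presence calls.

    The candidate region is the intersection of all positive lines' segment
    intervals; the interval of every negative line overlapping the candidate
    is then subtracted.  Disjoint remaining pieces are reported as separate
    QTLs, named with ascending positional suffixes.

    Raises :class:`InconsistentCallsError` when the positives do not overlap
    or the negatives cover the whole candidate region.
    """
    lines = sorted(segments)
    unknown = [l for l in lines if l not in calls]
    if unknown:
        raise ValueError(f"no presence call for line(s) {unknown}")
    chroms = {segments[l].chromosome for l in lines}
    if len(chroms) != 1:
        raise ValueError(f"segments span several chromosomes: {sorted(chroms)}")
    chromosome = chroms.pop()

    positives = [l for l in lines if calls[l]]
    if not positives:
        raise ValueError("no phenotype-positive line; nothing to map")
    intervals = {l: segment_to_interval(segments[l], gmap) for l in lines}

    candidate = intervals[positives[0]]
    for l in positives[1:]:
        candidate = intersect(candidate, intervals[l])
        if candidate is None:
            raise InconsistentCallsError(
                f"positive lines {positives} have no common overlap"
            )

    pieces = [candidate]
    for l in lines:
        if calls[l]:
            continue
        neg = intervals[l]
        pieces = [q for p in pieces for q in subtract(p, neg)]
    if not pieces:
        raise InconsistentCallsError(
            "negative-line segments cover the entire candidate region"
        )
    pieces.sort(key=lambda p: p.start)

    out = []
    for i, piece in enumerate(pieces, start=1):
        idx = i if len(pieces) > 1 else None
        out.append(
            QTLInterval(
                name=name_qtl(trait_code, chromosome, idx),
                chromosome=chromosome,
                interval=piece,
                delimiting_notation=_interval_notation(piece, gmap),
            )
        )
    return out


class EpistasisRelation(str, Enum):
    A_OVER_B = "a_over_b"
    B_OVER_A = "b_over_a"
    ADDITIVE = "additive"
    UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class EpistasisCall:
    qtl_a: str
    qtl_b: str
    relation: EpistasisRelation
    p_a_vs_ab: float
    p_b_vs_ab: float
    p_additivity: float


def _welch_p(x: np.ndarray, y: np.ndarray) -> float:
    return float(stats.ttest_ind(x, y, equal_var=False).pvalue)


def classify_epistasis(
    pheno: PhenotypeTable,
    line_ab: str,
    line_a: str,
    line_b: str,
    recipient: str,
    alpha: float = 0.01,
    year: Optional[str] = None,
    qtl_a: str = "A",
    qtl_b: str = "B",
) -> EpistasisCall:
    """Classify the joint action of two QTLs from line means.

    ``line_ab`` carries both QTLs, ``line_a``/``line_b`` one each.  Welch
    two-sample contrasts at ``alpha`` decide the relation:

    - ``a_over_b``: the AB line phenocopies the A line (fail to reject) while
      differing from the B line (reject) — QTL A masks QTL B;
    - ``b_over_a``: the symmetric pattern;
    - ``additive``: AB differs from both single lines and the interaction
      contrast AB - A - B + recipient is not rejected;
    - ``undetermined`` otherwise.
    """
    xs = {}
    for name in (line_ab, line_a, line_b, recipient):
        v = pheno.values(name, year)
        if v.size < 2:
            raise ValueError(f"line {name!r} missing or has <2 plants")
        xs[name] = v
    ab, a, b, r = xs[line_ab], xs[line_a], xs[line_b], xs[recipient]

    p_a = _welch_p(a, ab)
    p_b = _welch_p(b, ab)

    # Welch-Satterthwaite t test of the interaction contrast AB - A - B + R = 0
    parts = [ab, a, b, r]
    variances = [np.var(x, ddof=1) / len(x) for x in parts]
    se2 = sum(variances)
    contrast = np.mean(ab) - np.mean(a) - np.mean(b) + np.mean(r)
    if se2 == 0:
        p_add = 1.0 if contrast == 0 else 0.0
    else:
        t = contrast / np.sqrt(se2)
        df = se2**2 / sum(v**2 / (len(x) - 1) for v, x in zip(variances, parts))
        p_add = float(2 * stats.t.sf(abs(t), df))

    if p_a > alpha and p_b <= alpha:
        relation = EpistasisRelation.A_OVER_B
    elif p_b > alpha and p_a <= alpha:
        relation = EpistasisRelation.B_OVER_A
    elif p_a <= alpha and p_b <= alpha and p_add > alpha:
        relation = EpistasisRelation.ADDITIVE
    else:
        relation = EpistasisRelation.UNDETERMINED
    return EpistasisCall(
        qtl_a=qtl_a,
        qtl_b=qtl_b,
        relation=relation,
        p_a_vs_ab=p_a,
        p_b_vs_ab=p_b,
        p_additivity=p_add,
    )
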