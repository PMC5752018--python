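"""Genetic maps, substituted segments, and interval algebra in centimorgans.

A single-segment substitution line (SSSL) carries one contiguous, homozygous
donor chromosome segment in an otherwise uniform recurrent-parent background.
The segment is described by the markers known to lie on donor DNA (the *inner*
markers) plus, when available, the nearest markers on either side known to
still carry recipient DNA (the *flanks*).  The conventional text rendering
joins inner markers with a single hyphen and separates flanks with a double
hyphen / em-dash, e.g. ``RM596—RM271-RM269-RM258-RM304—PSM167``.  A segment
reaching a chromosome end may be anchored by a terminal label such as
``Short arm`` instead of a flanking marker.

Because the true recombination breakpoint lies somewhere between the outermost
inner marker and its flank, the expected segment length under a uniform
breakpoint position is the inner-marker span plus half of each inner-to-flank
gap.  That midpoint convention is the default here; the conservative
flank-to-flank span is available via ``convention="flank_to_flank"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "Marker",
    "GeneticMap",
    "SubstitutedSegment",
    "CMInterval",
    "SegmentNotationError",
    "parse_segment_notation",
    "format_segment_notation",
    "estimate_segment_length",
    "segment_to_interval",
    "intersect",
    "subtract",
]

#: Em-dash as printed in segment tables; ``--`` is accepted on input.
EM_DASH = "—"

_OUTER_SEP = re.compile(r"—|–|--")
_TERMINAL_LABEL = re.compile(r"^(short|long)\s+arm$", re.IGNORECASE)


class SegmentNotationError(ValueError):
    """Raised for malformed segment notation strings."""


@dataclass(frozen=True)
class Marker:
    """A mapped marker locus (e.g. an SSR such as RM569)."""

    name: str
    chromosome: int
    position: float  # cM from the top of the chromosome (short arm = 0)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("marker name must be non-empty")
        if not 1 <= int(self.chromosome) <= 24:
            raise ValueError(f"implausible chromosome {self.chromosome!r}")
        if self.position < 0:
            raise ValueError(f"negative cM position for {self.name}: {self.position}")


class GeneticMap:
    """Ordered markers with cM positions, grouped by chromosome.

    Marker order within a chromosome is taken from the input order and must be
    consistent with non-decreasing positions (ties are allowed).
    """

    def __init__(self, markers: Iterable[Marker]):
        self._by_name: dict[str, Marker] = {}
        self._by_chrom: dict[int, list[Marker]] = {}
        for m in markers:
            if m.name in self._by_name:
                raise ValueError(f"duplicate marker name {m.name!r}")
            self._by_name[m.name] = m
            self._by_chrom.setdefault(m.chromosome, []).append(m)
        for chrom, ms in self._by_chrom.items():
            pos = [m.position for m in ms]
            if any(b < a for a, b in zip(pos, pos[1:])):
                raise ValueError(
                    f"marker positions on chromosome {chrom} are not non-decreasing"
                )

    def __len__(self) -> int:
        return len(self._by_name)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def marker(self, name: str) -> Marker:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown marker {name!r}") from None

    def position(self, name: str) -> float:
        return self.marker(name).position

    def chromosomes(self) -> list[int]:
        return sorted(self._by_chrom)

    def markers_on(self, chromosome: int) -> list[Marker]:
        return list(self._by_chrom.get(chromosome, []))

    def chromosome_span(self, chromosome: int) -> tuple[float, float]:
        ms = self._by_chrom.get(chromosome)
        if not ms:
            raise KeyError(f"no markers on chromosome {chromosome}")
        return ms[0].position, ms[-1].position


@dataclass(frozen=True)
class SubstitutedSegment:
    """A donor chromosome segment delimited by markers.

    ``inner_markers`` are on donor DNA; ``left_flank``/``right_flank`` are the
    nearest markers known to be recipient DNA.  ``terminal_label`` records a
    chromosome-end anchor ("Short arm") in place of the left flank; it is
    modelled as a flank pinned at position 0 cM.
    """

    chromosome: int
    inner_markers: tuple[str, ...]
    left_flank: Optional[str] = None
    right_flank: Optional[str] = None
    terminal_label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.inner_markers:
            raise SegmentNotationError("segment must contain at least one inner marker")
        object.__setattr__(self, "inner_markers", tuple(self.inner_markers))
        if self.terminal_label is not None and self.left_flank is not None:
            raise SegmentNotationError(
                "terminal label and left flank are mutually exclusive"
            )
        names = list(self.inner_markers)
        for fl in (self.left_flank, self.right_flank):
            if fl is not None:
                if fl in self.inner_markers:
                    raise SegmentNotationError(f"flank {fl!r} duplicates an inner marker")
                names.append(fl)
        if len(set(names)) != len(names):
            raise SegmentNotationError(f"duplicate marker names in segment: {names}")

    @property
    def all_markers(self) -> tuple[str, ...]:
        out = []
        if self.left_flank:
            out.append(self.left_flank)
        out.extend(self.inner_markers)
        if self.right_flank:
            out.append(self.right_flank)
        return tuple(out)


def _is_terminal_label(token: str) -> bool:
    return bool(_TERMINAL_LABEL.match(token.strip()))


def parse_segment_notation(text: str, chromosome: int) -> SubstitutedSegment:
    """Parse hyphen notation into a :class:`SubstitutedSegment`.

    Tokens between the double-hyphen (or em-dash) separators that are joined
    by single hyphens are the inner markers; tokens outside the double hyphens
    are flanks.  ``Short arm`` / ``Long arm`` tokens at the start are terminal
    labels whether they are attached with a single or a double hyphen.

    With exactly two double-hyphen-separated parts the inner part is the one
    containing a single-hyphen join (or a leading terminal label); two bare
    single-marker parts are rejected as ambiguous.
    """
    if not text or not text.strip():
        raise SegmentNotationError("empty segment notation")
    parts = [p.strip() for p in _OUTER_SEP.split(text.strip())]
    if any(not p for p in parts):
        raise SegmentNotationError(f"malformed separators in {text!r}")

    def split_inner(part: str) -> list[str]:
        return [t.strip() for t in part.split("-") if t.strip()]

    left: Optional[str] = None
    right: Optional[str] = None
    if len(parts) == 1:
        inner = split_inner(parts[0])
    elif len(parts) == 3:
        left, inner, right = parts[0], split_inner(parts[1]), parts[2]
    elif len(parts) == 2:
        t0, t1 = split_inner(parts[0]), split_inner(parts[1])
        if len(t0) == 1 and _is_terminal_label(t0[0]):
            left, inner = parts[0], t1  # "Short arm—inner[-inner...]"
        elif len(t0) > 1 or _is_terminal_label(t0[0]):
            if len(t1) > 1:
                raise SegmentNotationError(f"ambiguous two-part notation {text!r}")
            inner, right = t0, parts[1]
        else:
            # single-token first part: left flank + inner ("A—B", "F—M1-M2")
            left, inner = parts[0], t1
    else:
        raise SegmentNotationError(f"too many double-hyphen separators in {text!r}")

    terminal = None
    if left is not None and _is_terminal_label(left):
        terminal, left = left, None
    if inner and _is_terminal_label(inner[0]):
        if terminal is not None:
            raise SegmentNotationError(f"two terminal labels in {text!r}")
        terminal = inner[0]
        inner = inner[1:]
    if right is not None and _is_terminal_label(right):
        raise SegmentNotationError(
            f"terminal label in right-flank position is not supported: {text!r}"
        )
    if not inner:
        raise SegmentNotationError(f"no inner markers in {text!r}")
    return SubstitutedSegment(
        chromosome=chromosome,
        inner_markers=tuple(inner),
        left_flank=left,
        right_flank=right,
        terminal_label=terminal,
    )


def format_segment_notation(seg: SubstitutedSegment) -> str:
    """Render a segment in canonical hyphen notation (em-dash separators)."""
    inner = "-".join(seg.inner_markers)
    left = seg.terminal_label or seg.left_flank
    pieces = []
    if left:
        pieces.append(left)
    pieces.append(inner)
    if seg.right_flank:
        pieces.append(seg.right_flank)
    return EM_DASH.join(pieces)


@dataclass(frozen=True)
class CMInterval:
    """A closed interval [start, end] on one chromosome, in cM."""

    chromosome: int
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"interval end {self.end} < start {self.start}")

    @property
    def length(self) -> float:
        return self.end - self.start

    def contains(self, position: float) -> bool:
        return self.start <= position <= self.end

    def overlaps(self, other: "CMInterval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start <= other.end
            and other.start <= self.end
        )


def _inner_positions(seg: SubstitutedSegment, gmap: GeneticMap) -> list[float]:
    pos = []
    for name in seg.inner_markers:
        m = gmap.marker(name)
        if m.chromosome != seg.chromosome:
            raise ValueError(
                f"marker {name!r} is on chromosome {m.chromosome}, segment on {seg.chromosome}"
            )
        pos.append(m.position)
    if any(b < a for a, b in zip(pos, pos[1:])):
        raise ValueError(f"inner markers out of map order: {seg.inner_markers}")
    return pos


def _flank_gaps(seg: SubstitutedSegment, gmap: GeneticMap) -> tuple[float, float]:
    """(left gap, right gap) from the outermost inner markers to their anchors.

    A terminal label anchors the left side at 0 cM; a missing flank with no
    label contributes a zero gap.
    """
    pos = _inner_positions(seg, gmap)
    lo, hi = pos[0], pos[-1]
    if seg.left_flank is not None:
        left_anchor = gmap.position(seg.left_flank)
    elif seg.terminal_label is not None:
        left_anchor = 0.0
    else:
        left_anchor = lo
    if seg.right_flank is not None:
        right_anchor = gmap.position(seg.right_flank)
    else:
        right_anchor = hi
    lgap = lo - left_anchor
    rgap = right_anchor - hi
    if lgap < 0 or rgap < 0:
        raise ValueError(
            f"flank inside inner span for segment {format_segment_notation(seg)}"
        )
    return lgap, rgap


def estimate_segment_length(
    seg: SubstitutedSegment, gmap: GeneticMap, convention: str = "midpoint"
) -> float:
    """Estimated substituted-segment length in cM.

    ``midpoint`` (default): inner span plus half of each inner-to-flank gap,
    the expected length when each breakpoint is uniform between the outermost
    inner marker and its flank.  ``flank_to_flank``: inner span plus the full
    gaps (an upper bound).
    """
    pos = _inner_positions(seg, gmap)
    span = pos[-1] - pos[0]
    lgap, rgap = _flank_gaps(seg, gmap)
    if convention == "midpoint":
        return span + 0.5 * (lgap + rgap)
    if convention == "flank_to_flank":
        return span + lgap + rgap
    raise ValueError(f"unknown length convention {convention!r}")


def segment_to_interval(seg: SubstitutedSegment, gmap: GeneticMap) -> CMInterval:
    """Midpoint-convention cM interval covered by a substituted segment."""
    pos = _inner_positions(seg, gmap)
    lgap, rgap = _flank_gaps(seg, gmap)
    return CMInterval(
        chromosome=seg.chromosome,
        start=pos[0] - 0.5 * lgap,
        end=pos[-1] + 0.5 * rgap,
    )


def intersect(a: CMInterval, b: CMInterval) -> Optional[CMInterval]:
    """Intersection of two same-chromosome intervals, or None when disjoint."""
    if a.chromosome != b.chromosome:
        raise ValueError(f"chromosome mismatch: {a.chromosome} vs {b.chromosome}")
    start, end = max(a.start, b.start), min(a.end, b.end)
    if end < start:
        return None
    return CMInterval(a.chromosome, start, end)


def subtract(a: CMInterval, b: CMInterval) -> list[CMInterval]:
    """``a`` minus ``b``: the 0-2 pieces of ``a`` not covered by ``b``.

    Zero-length leftovers are dropped unless ``a`` itself had zero length and
    is untouched by ``b``.
    """
    if a.chromosome != b.chromosome:
        raise ValueError(f"chromosome mismatch: {a.chromosome} vs {b.chromosome}")
    if b.end < a.start or b.start > a.end:
        return [a]
    pieces = []
    if b.start > a.start:
        pieces.append(CMInterval(a.chromosome, a.start, b.start))
    if b.end < a.end:
        pieces.append(CMInterval(a.chromosome, b.end, a.end))
    return [p for p in pieces if p.length > 0]
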