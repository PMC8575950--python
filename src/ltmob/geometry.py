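"""Headful-packaging geometry on circular bacterial chromosomes.

A temperate pac-type phage that packages DNA in situ from its integrated
prophage fills successive capsids ("headfuls", ~43-46 kb) processively along
the chromosome, starting at the prophage attachment site (attB) and walking
in the packaging direction.  Everything here is coordinate arithmetic on the
circle: directed distances, headful windows, the maximal lateral-transduction
(LT) reach of a prophage, the union coverage achievable by a poly-lysogen,
and the assignment of chromosomal loci to the headful(s) that would carry
them.

Coordinates are 0-based half-open, positions taken modulo the genome length
L; packaging direction is +1 (increasing coordinate) or -1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class CircularInterval:
    """Half-open interval [start, start+length) modulo ``genome_length``."""

    start: int
    length: int
    genome_length: int

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise GeometryError("genome_length must be positive")
        if not 0 <= self.start < self.genome_length:
            raise GeometryError(
                f"start {self.start} outside [0, {self.genome_length})"
            )
        if not 0 < self.length <= self.genome_length:
            raise GeometryError(
                f"length {self.length} outside (0, {self.genome_length}]"
            )

    @property
    def end(self) -> int:
        """Exclusive end, possibly >= genome_length for wrapped intervals."""
        return self.start + self.length

    @property
    def wraps(self) -> bool:
        return self.end > self.genome_length

    def contains(self, position: int) -> bool:
        return (position - self.start) % self.genome_length < self.length

    def contains_interval(self, other: "CircularInterval") -> bool:
        """True if every base of ``other`` lies inside this interval."""
        if other.genome_length != self.genome_length:
            raise GeometryError("intervals on different genomes")
        offset = (other.start - self.start) % self.genome_length
        return offset + other.length <= self.length

    def overlaps(self, other: "CircularInterval") -> bool:
        if other.genome_length != self.genome_length:
            raise GeometryError("intervals on different genomes")
        return (
            (other.start - self.start) % self.genome_length < self.length
            or (self.start - other.start) % self.genome_length < other.length
        )

    def segments(self) -> list[tuple[int, int]]:
        """Linear [start, end) pieces on [0, L); two pieces if wrapped."""
        if self.wraps:
            return [
                (self.start, self.genome_length),
                (0, self.end - self.genome_length),
            ]
        return [(self.start, self.end)]


@dataclass(frozen=True)
class AttBSite:
    """Chromosomal phage attachment site with its packaging direction."""

    site_id: str
    position: int
    direction: int  # +1 packaging towards increasing coordinates, -1 decreasing
    occupied_by: Optional[str] = None

    def __post_init__(self) -> None:
        if self.direction not in (+1, -1):
            raise GeometryError(f"direction must be +1 or -1, got {self.direction}")
        if self.position < 0:
            raise GeometryError("position must be non-negative")


@dataclass(frozen=True)
class ProphageModel:
    """Headful-packaging parameters of a pac-type prophage.

    ``headful_size`` is the capsid capacity in bp; ``n_max`` the maximum
    number of processive headfuls observed for the phage;
    ``hf1_phage_carryover`` the span of phage DNA that occupies the start of
    the first headful during LT (the first capsid packages the remainder of
    the prophage before reaching chromosomal DNA); ``pac_offset`` optionally
    shifts the packaging origin away from the attB position.
    """

    phage_id: str
    headful_size: int
    n_max: int
    prophage_length: int = 0
    pac_offset: int = 0
    hf1_phage_carryover: int = 0

    def __post_init__(self) -> None:
        if self.headful_size <= 0:
            raise GeometryError("headful_size must be positive")
        if self.n_max < 1:
            raise GeometryError("n_max must be >= 1")
        if not 0 <= self.hf1_phage_carryover < self.headful_size:
            raise GeometryError("hf1_phage_carryover must be in [0, headful_size)")


#: Default models for the two experimentally characterised LT phages:
#: the staphylococcal phage 80α (~45 kb capsid, packaging demonstrated over
#: seven processive headfuls) and the Salmonella phage P22 (~43 kb capsid,
#: demonstrated over twelve headfuls).
PHAGE_80ALPHA = ProphageModel("80alpha", headful_size=45_000, n_max=7)
PHAGE_P22 = ProphageModel("P22", headful_size=43_000, n_max=12)


@dataclass(frozen=True)
class GenomicLocus:
    locus_id: str
    span: CircularInterval
    locus_class: str = "locus"


@dataclass
class CoverageSummary:
    covered_bp: int
    genome_length: int
    per_site_reach: dict[str, CircularInterval] = field(default_factory=dict)

    @property
    def fraction(self) -> float:
        return self.covered_bp / self.genome_length


def directed_distance(from_pos: int, to_pos: int, direction: int, genome_length: int) -> int:
    """Bases walked from ``from_pos`` to ``to_pos`` moving in ``direction``."""
    if direction not in (+1, -1):
        raise GeometryError("direction must be +1 or -1")
    for p in (from_pos, to_pos):
        if not 0 <= p < genome_length:
            raise GeometryError(f"position {p} outside [0, {genome_length})")
    if direction == +1:
        return (to_pos - from_pos) % genome_length
    return (from_pos - to_pos) % genome_length


def _packaging_origin(site: AttBSite, model: ProphageModel, genome_length: int) -> int:
    return (site.position + site.direction * model.pac_offset) % genome_length


def headful_index(
    site: AttBSite, locus_pos: int, model: ProphageModel, genome_length: int
) -> Optional[int]:
    """1-based headful that would package ``locus_pos``; None if out of reach.

    The distance is measured from the attachment site along the packaging
    direction, so a locus 35 kb downstream of the attB with a 45 kb headful
    falls in HF1.
    """
    origin = _packaging_origin(site, model, genome_length)
    dist = directed_distance(origin, locus_pos, site.direction, genome_length)
    n = dist // model.headful_size + 1
    return int(n) if n <= model.n_max else None


def headful_windows(
    site: AttBSite, model: ProphageModel, genome_length: int
) -> list[CircularInterval]:
    """Consecutive, disjoint headful windows HF1..HFn along the packaging direction.

    Window k holds the positions whose directed distance from the site lies
    in [(k-1)·H, k·H).  If the nominal reach n_max·H exceeds the genome, the
    tiling is truncated at one full circle (with a warning).
    """
    origin = _packaging_origin(site, model, genome_length)
    h = model.headful_size
    limit = model.n_max * h
    if limit > genome_length:
        warnings.warn(
            f"reach {limit} bp exceeds genome length {genome_length}; truncating",
            stacklevel=2,
        )
        limit = genome_length
    windows: list[CircularInterval] = []
    offset = 0
    while offset < limit:
        length = min(h, limit - offset)
        if site.direction == +1:
            start = (origin + offset) % genome_length
        else:
            start = (origin - offset - length + 1) % genome_length
        windows.append(CircularInterval(start, length, genome_length))
        offset += length
    return windows


def lt_reach_span(model: ProphageModel) -> int:
    """Maximal chromosomal span (bp) a single prophage can move by LT: n_max × H."""
    return model.n_max * model.headful_size


def reach_interval(
    site: AttBSite, model: ProphageModel, genome_length: int
) -> CircularInterval:
    """The full LT reach of a prophage at ``site`` as one circular interval."""
    origin = _packaging_origin(site, model, genome_length)
    length = min(lt_reach_span(model), genome_length)
    if site.direction == +1:
        start = origin
    else:
        start = (origin - length + 1) % genome_length
    return CircularInterval(start, length, genome_length)


def _union_size(intervals: Sequence[CircularInterval], genome_length: int) -> int:
    segments: list[tuple[int, int]] = []
    for iv in intervals:
        segments.extend(iv.segments())
    segments.sort()
    covered = 0
    cur_start = cur_end = None
    for s, e in segments:
        if cur_end is None or s > cur_end:
            if cur_end is not None:
                covered += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        covered += cur_end - cur_start
    return min(covered, genome_length)


def polylysogen_coverage(
    genome_length: int,
    sites: Sequence[AttBSite],
    models: Mapping[str, ProphageModel],
) -> CoverageSummary:
    """Union LT coverage of the chromosome from several integrated prophages.

    ``models`` maps site_id to the prophage model integrated there, allowing
    per-site headful counts.  The covered fraction bounds the share of the
    chromosome mobilisable in a single induction event of a poly-lysogen.
    """
    seen: set[str] = set()
    for site in sites:
        if site.site_id in seen:
            raise GeometryError(f"duplicate attB site id {site.site_id!r}")
        seen.add(site.site_id)
    reaches: dict[str, CircularInterval] = {}
    for site in sites:
        try:
            model = models[site.site_id]
        except KeyError:
            raise GeometryError(f"no prophage model for site {site.site_id!r}") from None
        reaches[site.site_id] = reach_interval(site, model, genome_length)
    covered = _union_size(list(reaches.values()), genome_length) if reaches else 0
    return CoverageSummary(covered, genome_length, reaches)


def locus_headful_range(
    site: AttBSite,
    locus: GenomicLocus,
    model: ProphageModel,
    genome_length: int,
) -> Optional[tuple[int, int]]:
    """Range of headful indices that jointly package a locus, or None.

    Both edges of the locus span are mapped (a locus straddling a headful
    boundary reports e.g. (5, 6)); if only part of the locus lies within the
    prophage reach the range is truncated, and a fully unreachable locus
    yields None.
    """
    origin = _packaging_origin(site, model, genome_length)
    span = locus.span
    if span.genome_length != genome_length:
        raise GeometryError("locus on a different genome")
    d_start = directed_distance(origin, span.start, site.direction, genome_length)
    last = (span.start + span.length - 1) % genome_length
    d_last = directed_distance(origin, last, site.direction, genome_length)
    if site.direction == +1:
        d_near, d_far = d_start, d_last
    else:
        d_near, d_far = d_last, d_start
    reach = min(lt_reach_span(model), genome_length)
    if d_near <= d_far:
        dist_segments = [(d_near, d_far)]
    else:  # the packaging origin lies inside the locus
        dist_segments = [(0, d_far), (d_near, genome_length - 1)]
    h = model.headful_size
    indices: list[int] = []
    for lo, hi in dist_segments:
        hi = min(hi, reach - 1)
        if lo > hi:
            continue
        indices.append(lo // h + 1)
        indices.append(hi // h + 1)
    if not indices:
        return None
    return (min(indices), min(max(indices), model.n_max))


def format_headful_range(rng: Optional[tuple[int, int]]) -> str:
    """Render a headful range the way compatibility tables print it."""
    if rng is None:
        return "—"
    lo, hi = rng
    return f"HF {lo}" if lo == hi else f"HF {lo}-{hi}"


def locus_compatibility_table(
    loci: Sequence[GenomicLocus],
    sites: Sequence[AttBSite],
    models: Mapping[str, ProphageModel],
    genome_length: int,
) -> dict[str, dict[str, Optional[tuple[int, int]]]]:
    """locus_id → site_id → headful range (or None when out of reach)."""
    table: dict[str, dict[str, Optional[tuple[int, int]]]] = {}
    for locus in loci:
        row: dict[str, Optional[tuple[int, int]]] = {}
        for site in sites:
            model = models[site.site_id]
            row[site.site_id] = locus_headful_range(site, locus, model, genome_length)
        table[locus.locus_id] = row
    return table


def windows_to_bed(
    sites: Sequence[AttBSite],
    models: Mapping[str, ProphageModel],
    genome_length: int,
    chrom: str = "chromosome",
) -> str:
    """BED-like text of all headful windows; wrapped windows split in two lines."""
    lines = []
    for site in sites:
        model = models[site.site_id]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            wins = headful_windows(site, model, genome_length)
        for k, win in enumerate(wins, start=1):
            for s, e in win.segments():
                lines.append(f"{chrom}\t{s}\t{e}\t{site.site_id}:HF{k}")
    return "\n".join(lines) + "\n"
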