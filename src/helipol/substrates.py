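"""Fork-DNA substrate geometry and region-to-orientation mapping.

A fork substrate is a duplex with two single-strand arms.  A hexameric
3'->5' helicase encircles the 3'-arm strand (the translocating strand) and
excludes the other.  Cleavage-probe footprinting quantifies where the
C-terminal face of the hexamer sits on the labelled strand, so each
substrate carries a :class:`RegionMap` that assigns base intervals of the
single-strand window to the two binding orientations:

* ``N@duplex`` — N-terminal face of the hexamer nearest the duplex junction
  (junction-proximal cleavage by the C-terminal probe);
* ``C@duplex`` — C-terminal face nearest the junction (junction-distal
  cleavage).

Coordinates are 1-based inclusive, counted from the strand end named in
``coordinate_origin``; the origin differs between substrates (the Cy3
substrates are read from the 5' duplex end, the Cy5 5'-long-arm substrate
from the 3' end), so it is recorded per map rather than assumed globally.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional


class LabelledStrand(str, Enum):
    """Which fork strand carries the fluorescent label."""

    ENCIRCLED_3ARM = "encircled_3arm"
    EXCLUDED_5ARM = "excluded_5arm"


class LabelEnd(str, Enum):
    """Which end of the labelled strand carries the dye (always at the duplex)."""

    DUPLEX_5PRIME = "duplex_5prime"
    DUPLEX_3PRIME = "duplex_3prime"


class Origin(str, Enum):
    FROM_5PRIME = "from_5prime"
    FROM_3PRIME = "from_3prime"


class SubstrateError(ValueError):
    """Raised for geometrically impossible substrate definitions."""


@dataclass(frozen=True)
class ForkSubstrate:
    """Geometry and labelling of a fork or tailed DNA substrate.

    Lengths are in nucleotides / base pairs.  ``arm3_len`` is the
    single-strand 3'-arm of the encircled strand; ``arm5_len`` the 5'-arm
    of the excluded strand.  ``block_pos`` (biotin/streptavidin roadblock)
    and ``reporter_pos`` (FAM site) are measured in nt from the duplex
    junction along the strand that carries them.
    """

    name: str
    duplex_len: int
    arm3_len: int
    arm5_len: int
    labelled_strand: LabelledStrand = LabelledStrand.ENCIRCLED_3ARM
    label_end: LabelEnd = LabelEnd.DUPLEX_5PRIME
    block_pos: Optional[int] = None
    reporter_pos: Optional[int] = None

    @property
    def labelled_arm_len(self) -> int:
        if self.labelled_strand is LabelledStrand.ENCIRCLED_3ARM:
            return self.arm3_len
        return self.arm5_len

    @property
    def labelled_strand_len(self) -> int:
        """Total length of the labelled strand (duplex + its arm)."""
        return self.duplex_len + self.labelled_arm_len


@dataclass(frozen=True)
class RegionMap:
    """Assignment of labelled-strand base intervals to binding orientations.

    ``n_region`` collects cleavage attributed to the N@duplex orientation,
    ``c_region`` to C@duplex.  Intervals are 1-based inclusive ``(lo, hi)``
    pairs in the coordinate system of ``coordinate_origin``.
    """

    coordinate_origin: Origin
    n_region: tuple[int, int]
    c_region: tuple[int, int]
    strand_len: int

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("n_region", self.n_region), ("c_region", self.c_region)):
            if not (1 <= lo <= hi <= self.strand_len):
                raise SubstrateError(
                    f"{name} [{lo},{hi}] outside labelled strand of length {self.strand_len}"
                )
        n_lo, n_hi = self.n_region
        c_lo, c_hi = self.c_region
        if not (n_hi < c_lo or c_hi < n_lo):
            raise SubstrateError("n_region and c_region overlap")

    def region_slice(self, which: str) -> slice:
        """0-based slice into a per-base intensity vector for 'N' or 'C'."""
        lo, hi = self.n_region if which == "N" else self.c_region
        return slice(lo - 1, hi)


def make_substrate(
    name: str,
    duplex_len: int,
    arm3_len: int,
    arm5_len: int,
    labelled_strand: LabelledStrand | str = LabelledStrand.ENCIRCLED_3ARM,
    label_end: LabelEnd | str | None = None,
    block_pos: Optional[int] = None,
    reporter_pos: Optional[int] = None,
) -> ForkSubstrate:
    """Validate and construct a :class:`ForkSubstrate`.

    The dye sits at the duplex end of the labelled strand, so an encircled
    (3'-arm) labelled strand is labelled at its 5' end and an excluded
    (5'-arm) strand at its 3' end; a mismatching ``label_end`` is rejected.
    """
    labelled_strand = LabelledStrand(labelled_strand)
    if label_end is None:
        label_end = (
            LabelEnd.DUPLEX_5PRIME
            if labelled_strand is LabelledStrand.ENCIRCLED_3ARM
            else LabelEnd.DUPLEX_3PRIME
        )
    label_end = LabelEnd(label_end)

    for field, value in (("duplex_len", duplex_len), ("arm3_len", arm3_len), ("arm5_len", arm5_len)):
        if value < 0:
            raise SubstrateError(f"{field} must be non-negative, got {value}")
    if duplex_len == 0:
        raise SubstrateError("duplex_len must be positive for a fork/tailed substrate")

    expected = (
        LabelEnd.DUPLEX_5PRIME
        if labelled_strand is LabelledStrand.ENCIRCLED_3ARM
        else LabelEnd.DUPLEX_3PRIME
    )
    if label_end is not expected:
        raise SubstrateError(
            f"label_end {label_end.value} inconsistent with labelled_strand "
            f"{labelled_strand.value}: the duplex-end label of the "
            f"{'encircled' if expected is LabelEnd.DUPLEX_5PRIME else 'excluded'} "
            f"strand is its {'5' if expected is LabelEnd.DUPLEX_5PRIME else '3'}' end"
        )

    sub = ForkSubstrate(
        name=name,
        duplex_len=duplex_len,
        arm3_len=arm3_len,
        arm5_len=arm5_len,
        labelled_strand=labelled_strand,
        label_end=label_end,
        block_pos=block_pos,
        reporter_pos=reporter_pos,
    )
    strand_len = sub.labelled_strand_len
    for field, value in (("block_pos", block_pos), ("reporter_pos", reporter_pos)):
        if value is not None and not (0 <= value <= strand_len):
            raise SubstrateError(f"{field}={value} outside the labelled strand (len {strand_len})")
    return sub


# The four fork substrates used throughout: 20 bp duplex, arms as named.
PRESETS: dict[str, ForkSubstrate] = {
    "equal_arm": make_substrate("equal_arm", duplex_len=20, arm3_len=30, arm5_len=30),
    "fork_3long": make_substrate("fork_3long", duplex_len=20, arm3_len=30, arm5_len=8),
    "fork_3long_0nt": make_substrate("fork_3long_0nt", duplex_len=20, arm3_len=30, arm5_len=0),
    "fork_5long": make_substrate(
        "fork_5long",
        duplex_len=20,
        arm3_len=8,
        arm5_len=30,
        labelled_strand=LabelledStrand.EXCLUDED_5ARM,
    ),
}


def get_preset(name: str) -> ForkSubstrate:
    try:
        return PRESETS[name]
    except KeyError:
        raise SubstrateError(
            f"unknown substrate preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def default_region_map(substrate: ForkSubstrate) -> RegionMap:
    """Default orientation regions for a substrate.

    For the 50-nt labelled strands (20 bp duplex + 30 nt arm) the fixed
    intervals are bases 20-35 (N@duplex) and 36-50 (C@duplex), counted from
    the labelled (duplex) end: from the 5' end when the encircled strand is
    labelled, from the 3' end when the excluded strand is.  Shorter strands
    fall back to splitting the single-strand window at its midpoint.
    """
    origin = (
        Origin.FROM_5PRIME
        if substrate.labelled_strand is LabelledStrand.ENCIRCLED_3ARM
        else Origin.FROM_3PRIME
    )
    strand_len = substrate.labelled_strand_len
    window_lo = substrate.duplex_len  # junction base included, per convention
    window_hi = strand_len
    if window_hi - window_lo + 1 < 2:
        raise SubstrateError(
            f"single-strand window of {substrate.name} shorter than 2 bases"
        )
    if strand_len >= 50:
        n_region, c_region = (20, 35), (36, 50)
    else:
        mid = (window_lo + window_hi) // 2
        n_region, c_region = (window_lo, mid), (mid + 1, window_hi)
    return RegionMap(
        coordinate_origin=origin,
        n_region=n_region,
        c_region=c_region,
        strand_len=strand_len,
    )


def region_map_override(
    base: RegionMap,
    n_region: tuple[int, int] | None = None,
    c_region: tuple[int, int] | None = None,
) -> RegionMap:
    """Return a copy of ``base`` with one or both intervals replaced."""
    kwargs = {}
    if n_region is not None:
        kwargs["n_region"] = tuple(n_region)
    if c_region is not None:
        kwargs["c_region"] = tuple(c_region)
    return replace(base, **kwargs)
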