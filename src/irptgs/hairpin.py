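"""Intron-spliced hairpin RNA (ihpRNA) construct model.

An ihpRNA precursor is an inverted repeat: a first arm (``arm1``, one or more
trigger fragments each in sense or antisense orientation), a spacer intron,
and a second arm that is exactly the reverse complement of the first.  Small
RNAs are produced preferentially near the loop/intron junction, so the key
coordinate here is the *loop distance*: how far an arm-1 position lies from
the intron-proximal end of arm 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from Bio.Seq import Seq

_ALPHABET = set("ACGTN")
_ORIENTATIONS = ("sense", "antisense")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class TriggerFragment:
    """A trigger/target gene fragment cloned into the hairpin."""

    id: str
    source_name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError(f"fragment {self.id!r}: empty sequence")
        bad = set(seq) - _ALPHABET
        if bad:
            raise ValueError(f"fragment {self.id!r}: invalid characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HairpinSpec:
    """Arm-1 layout of a hairpin construct.

    ``arm1`` is an ordered list of ``(fragment_id, orientation)`` pairs,
    promoter-proximal first; the intron follows arm 1.  The construct name is
    determined by the layout, e.g. ``gusS-chsS^chsA-gusA`` where ``^`` marks
    the intron and S/A the fragment orientation.
    """

    arm1: tuple[tuple[str, str], ...]
    intron_length: int = 0

    def __post_init__(self) -> None:
        arm1 = tuple((fid, orient) for fid, orient in self.arm1)
        object.__setattr__(self, "arm1", arm1)
        if not arm1:
            raise ValueError("arm1 must contain at least one fragment")
        for fid, orient in arm1:
            if orient not in _ORIENTATIONS:
                raise ValueError(f"invalid orientation {orient!r} for fragment {fid!r}")
        if self.intron_length < 0:
            raise ValueError("intron_length must be >= 0")

    @property
    def name(self) -> str:
        tag = {"sense": "S", "antisense": "A"}
        fwd = "-".join(f"{fid}{tag[o]}" for fid, o in self.arm1)
        flip = {"sense": "A", "antisense": "S"}
        rev = "-".join(f"{fid}{flip[o]}" for fid, o in reversed(self.arm1))
        return f"{fwd}^{rev}"


@dataclass(frozen=True)
class HairpinConstruct:
    """A realized precursor: arm1 + intron + revcomp(arm1), with coordinates.

    ``fragment_intervals`` maps ``(fragment_id, arm)`` with arm in {1, 2} to
    0-based half-open intervals on the precursor.
    """

    spec: HairpinSpec
    precursor_sequence: str
    fragment_intervals: dict[tuple[str, int], tuple[int, int]] = field(repr=False)

    @property
    def name(self) -> str:
        return self.spec.name

    @property
    def arm_length(self) -> int:
        return (len(self.precursor_sequence) - self.spec.intron_length) // 2

    @property
    def intron_interval(self) -> tuple[int, int]:
        return self.arm_length, self.arm_length + self.spec.intron_length

    def arm1_interval(self, fragment_id: str) -> tuple[int, int]:
        return self.fragment_intervals[(fragment_id, 1)]

    def loop_distance(self, fragment_id: str, pos: int) -> int:
        """Distance (nt) of an arm-1 fragment position from the loop/intron.

        ``pos`` is a 0-based offset within the fragment's arm-1 occurrence.
        The arm-1 position immediately adjacent to the intron has distance 0;
        the promoter-proximal end of arm 1 has distance ``arm_length - 1``.
        Reads mapping to arm 2 share the distance of their arm-1 mirror, so
        distances are always computed in arm-1 coordinates.
        """
        start, end = self.arm1_interval(fragment_id)
        if not 0 <= pos < end - start:
            raise ValueError(
                f"pos {pos} out of range for fragment {fragment_id!r} "
                f"(length {end - start})"
            )
        return self.arm_length - 1 - (start + pos)

    def position_loop_distance(self, precursor_pos: int) -> int:
        """Loop distance for any precursor position, folding arm 2 onto arm 1."""
        n = len(self.precursor_sequence)
        a = self.arm_length
        if not 0 <= precursor_pos < n:
            raise ValueError("position outside precursor")
        i0, i1 = self.intron_interval
        if i0 <= precursor_pos < i1:
            raise ValueError("position inside the intron has no loop distance")
        if precursor_pos >= i1:  # mirror arm-2 position onto arm 1
            precursor_pos = n - 1 - precursor_pos
        return a - 1 - precursor_pos


def build_hairpin(
    spec: HairpinSpec,
    fragments: Sequence[TriggerFragment],
    intron: str = "",
) -> HairpinConstruct:
    """Assemble a hairpin precursor from a spec and fragment sequences.

    Arm 1 concatenates the fragments in spec order (antisense fragments are
    reverse-complemented); arm 2 is the reverse complement of arm 1, so each
    fragment occurs once per arm and the two occurrences mirror each other.
    """
    if len(intron) != spec.intron_length:
        if spec.intron_length == 0 and intron:
            spec = HairpinSpec(spec.arm1, len(intron))
        else:
            raise ValueError(
                f"intron length {len(intron)} != spec.intron_length {spec.intron_length}"
            )
    by_id = {f.id: f for f in fragments}
    parts: list[str] = []
    intervals: dict[tuple[str, int], tuple[int, int]] = {}
    offset = 0
    for fid, orient in spec.arm1:
        if fid not in by_id:
            raise KeyError(f"unknown fragment id {fid!r}")
        seq = by_id[fid].sequence
        if orient == "antisense":
            seq = revcomp(seq)
        intervals[(fid, 1)] = (offset, offset + len(seq))
        parts.append(seq)
        offset += len(seq)
    arm1 = "".join(parts)
    arm_length = len(arm1)
    precursor = arm1 + intron.upper() + revcomp(arm1)
    n = len(precursor)
    # arm-2 interval of a fragment mirrors its arm-1 interval
    for fid, _ in spec.arm1:
        s, e = intervals[(fid, 1)]
        intervals[(fid, 2)] = (n - e, n - s)
    assert arm_length == sum(by_id[f].length for f, _ in spec.arm1)
    return HairpinConstruct(spec=spec, precursor_sequence=precursor, fragment_intervals=intervals)


def loop_distance(construct: HairpinConstruct, fragment_id: str, pos: int) -> int:
    """Functional alias for :meth:`HairpinConstruct.loop_distance`."""
    return construct.loop_distance(fragment_id, pos)


def enumerate_configurations(
    frag_a: TriggerFragment, frag_b: TriggerFragment, intron_length: int = 0
) -> list[HairpinSpec]:
    """The four two-fragment hairpin configurations.

    Two fragment orders x two leading orientations (both fragments sense, or
    both antisense, in arm 1), as used in the four-construct comparison.
    """
    if frag_a.id == frag_b.id:
        raise ValueError("fragments must be distinct")
    specs = []
    for order in ((frag_a.id, frag_b.id), (frag_b.id, frag_a.id)):
        for orient in ("sense", "antisense"):
            specs.append(
                HairpinSpec(tuple((fid, orient) for fid in order), intron_length)
            )
    names = [s.name for s in specs]
    assert len(set(names)) == 4
    return specs
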