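"""Secondary-structure containers and dot-bracket manipulation.

Conventions used throughout the package:

* positions are 1-based over the *concatenated* sequence with the ``&``
  strand separator removed (pair-table convention);
* user-facing sequence and dot-bracket strings keep the ``&`` aligned
  between the two;
* a duplex "end" is formed by both strands: the 5p end comprises the first
  ``n`` nucleotides of the 5p strand together with the last ``n`` of the 3p
  strand, and symmetrically for the 3p end.  Restricting only one partner of
  a base pair would let the other re-pair, so windows always cover both
  strands.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Literal

End = Literal["5p_end", "3p_end"]
ENDS: tuple[End, End] = ("5p_end", "3p_end")

CANONICAL_PAIRS = frozenset({"AU", "UA", "GC", "CG", "GU", "UG"})

__all__ = [
    "SecondaryStructure",
    "DuplexStructure",
    "DotBracketError",
    "parse_dotbracket",
    "render_dotbracket",
    "insert_separator",
    "extract_hairpin_duplex",
    "annotate_loops",
    "classify_difference",
    "ENDS",
    "CANONICAL_PAIRS",
]


class DotBracketError(ValueError):
    """Unbalanced or ill-formed dot-bracket string."""


def parse_dotbracket(db: str) -> dict[int, int]:
    """Parse dot-bracket into a symmetric 1-based pairs map.

    ``&`` separators are ignored for numbering.  Unpaired positions are
    absent from the map.  Raises :class:`DotBracketError` with the offending
    position for unbalanced brackets or foreign characters.
    """
    pairs: dict[int, int] = {}
    stack: list[int] = []
    pos = 0
    for ch in db:
        if ch == "&":
            continue
        pos += 1
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise DotBracketError(f"unmatched ')' at position {pos}")
            i = stack.pop()
            pairs[i] = pos
            pairs[pos] = i
        elif ch != ".":
            raise DotBracketError(f"illegal character {ch!r} at position {pos}")
    if stack:
        raise DotBracketError(f"unmatched '(' at position {stack[-1]}")
    return pairs


def render_dotbracket(pairs: dict[int, int], length: int) -> str:
    """Inverse of :func:`parse_dotbracket` (no separator)."""
    out = ["."] * length
    for i, j in pairs.items():
        if pairs.get(j) != i or i == j:
            raise DotBracketError(f"pairs map is not an involution at {i}<->{j}")
        if not (1 <= i <= length and 1 <= j <= length):
            raise DotBracketError(f"pair {i}<->{j} outside 1..{length}")
        if i < j:
            out[i - 1] = "("
            out[j - 1] = ")"
    return "".join(out)


def insert_separator(plain: str, strand_break: int) -> str:
    """Insert ``&`` after position *strand_break* of a plain string."""
    return plain[:strand_break] + "&" + plain[strand_break:]


@dataclass(kw_only=True)
class SecondaryStructure:
    """A sequence with its dot-bracket fold, free energy and temperature.

    ``sequence`` and ``dotbracket`` may contain one aligned ``&``.
    ``energy`` is in kcal/mol (``None`` for purely combinatorial
    structures that have not been evaluated); ``temperature`` in °C.
    """

    sequence: str
    dotbracket: str
    energy: float | None = None
    temperature: float | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.dotbracket):
            raise ValueError("sequence and dotbracket lengths differ")
        for i, (s, d) in enumerate(zip(self.sequence, self.dotbracket)):
            if (s == "&") != (d == "&"):
                raise ValueError(f"'&' misaligned between sequence and dotbracket at index {i}")
        parse_dotbracket(self.dotbracket)  # validates balance

    @property
    def plain_sequence(self) -> str:
        return self.sequence.replace("&", "")

    @property
    def plain_dotbracket(self) -> str:
        return self.dotbracket.replace("&", "")

    @cached_property
    def pairs(self) -> dict[int, int]:
        return parse_dotbracket(self.dotbracket)

    def partner(self, i: int) -> int | None:
        return self.pairs.get(i)

    def is_paired(self, i: int) -> bool:
        return i in self.pairs

    def __len__(self) -> int:
        return len(self.plain_sequence)

    def pair_bases(self, i: int) -> str:
        j = self.pairs[i]
        s = self.plain_sequence
        return s[i - 1] + s[j - 1]

    def check_canonical(self) -> None:
        for i, j in self.pairs.items():
            if i < j and self.pair_bases(i) not in CANONICAL_PAIRS:
                raise ValueError(f"non-canonical pair {self.pair_bases(i)} at {i}<->{j}")

    def hairpin_loops(self) -> list[range]:
        """Unpaired runs enclosed by a pair with nothing paired inside."""
        loops = []
        for i, j in self.pairs.items():
            if i < j and all(k not in self.pairs for k in range(i + 1, j)):
                loops.append(range(i + 1, j))
        return loops


@dataclass(kw_only=True)
class DuplexStructure(SecondaryStructure):
    """Two-strand structure; ``strand_break`` is the length of the 5p strand."""

    strand_break: int

    def __post_init__(self) -> None:
        super().__post_init__()
        if not (0 < self.strand_break < len(self)):
            raise ValueError("strand_break outside sequence")
        if "&" in self.sequence and self.sequence.index("&") != self.strand_break:
            raise ValueError("'&' position disagrees with strand_break")

    @property
    def len5p(self) -> int:
        return self.strand_break

    @property
    def len3p(self) -> int:
        return len(self) - self.strand_break

    @property
    def seq5p(self) -> str:
        return self.plain_sequence[: self.strand_break]

    @property
    def seq3p(self) -> str:
        return self.plain_sequence[self.strand_break :]

    def end_window(self, end: End, n: int) -> frozenset[int]:
        """Positions forming duplex end *end* at width *n* (both strands).

        Already-unpaired 3' overhang nucleotides are counted inside the
        window: they are terminal nucleotides that happen to be unwound
        already, which is what makes the unwinding cost of an open end zero.
        """
        if n < 0:
            raise ValueError("window width must be >= 0")
        L1, L = self.len5p, len(self)
        if end == "5p_end":
            win = set(range(1, n + 1)) | set(range(L - n + 1, L + 1))
        elif end == "3p_end":
            win = set(range(L1 - n + 1, L1 + 1)) | set(range(L1 + 1, L1 + 1 + n))
        else:
            raise ValueError(f"unknown end {end!r}")
        return frozenset(win)

    def strand_of(self, i: int) -> int:
        return 1 if i <= self.strand_break else 2

    def interstrand_pairs(self) -> list[tuple[int, int]]:
        """Pairs (i, j) with i on the 5p strand and j on the 3p strand."""
        return sorted(
            (i, j)
            for i, j in self.pairs.items()
            if i < j and self.strand_of(i) == 1 and self.strand_of(j) == 2
        )


def extract_hairpin_duplex(record, hairpin_fold: SecondaryStructure) -> DuplexStructure:
    """Project the hairpin MFE fold onto the duplex region.

    Keeps exactly the hairpin pairs whose *both* partners lie inside the
    5p or 3p arm interval, re-indexed to duplex coordinates; arm nucleotides
    paired to the loop or to flanking sequence become unpaired.  The result
    is the "hairpin-derived" duplex structure: how the two arms base-pair
    while still embedded in the precursor.

    The returned structure's energy is ``None`` (evaluate it with the
    folding engine if needed).
    """
    if record.pos5p is None or record.pos3p is None:
        raise ValueError(f"{record.name}: mature positions not located")
    if len(hairpin_fold) != len(record.hairpin_seq):
        raise ValueError(f"{record.name}: hairpin fold does not cover the hairpin sequence")
    (a5, b5), (a3, b3) = record.pos5p, record.pos3p
    region = list(range(a5, b5 + 1)) + list(range(a3, b3 + 1))
    old_to_new = {old: new for new, old in enumerate(region, start=1)}
    pairs: dict[int, int] = {}
    for i, j in hairpin_fold.pairs.items():
        if i < j and i in old_to_new and j in old_to_new:
            ni, nj = old_to_new[i], old_to_new[j]
            pairs[ni] = nj
            pairs[nj] = ni
    strand_break = b5 - a5 + 1
    db = render_dotbracket(pairs, len(region))
    return DuplexStructure(
        sequence=insert_separator(record.seq5p + record.seq3p, strand_break),
        dotbracket=insert_separator(db, strand_break),
        energy=None,
        temperature=hairpin_fold.temperature,
        strand_break=strand_break,
    )


def annotate_loops(duplex: DuplexStructure) -> list[tuple[str, tuple[int, ...]]]:
    """Classify interior unpaired runs of a duplex as mismatches or bulges.

    Walks the ladder of inter-strand pairs from the 5p end inward.  Between
    two consecutive rungs, unpaired nucleotides on both strands form a
    mismatch/internal loop; on one strand only, a bulge.  Unpaired runs at
    strand termini outside the outermost inter-strand pair are 3' overhangs
    (or frayed ends) and are excluded, matching the convention that terminal
    overhangs are not scored as internal features.

    Returns ``(kind, positions)`` tuples with positions in duplex
    coordinates, 5p-strand gap first.
    """
    ladder = duplex.interstrand_pairs()
    features: list[tuple[str, tuple[int, ...]]] = []
    for (i1, j1), (i2, j2) in zip(ladder, ladder[1:]):
        gap_top = [k for k in range(i1 + 1, i2) if not duplex.is_paired(k)]
        gap_bottom = [k for k in range(j2 + 1, j1) if not duplex.is_paired(k)]
        if gap_top and gap_bottom:
            features.append(("mismatch", tuple(gap_top + gap_bottom)))
        elif gap_top or gap_bottom:
            features.append(("bulge", tuple(gap_top + gap_bottom)))
    return features


def _terminal_zone(structure: SecondaryStructure, margin: int) -> set[int]:
    """Positions within *margin* of any strand terminus.

    For single-stranded structures (hairpins) the apical loop run(s) are
    also part of the terminal zone, mirroring how terminal-vs-central calls
    are made on hairpins (the loop is an "end" of the stem).
    """
    zone: set[int] = set()
    seqs = structure.sequence.split("&")
    offset = 0
    for s in seqs:
        L = len(s)
        zone |= set(range(offset + 1, offset + min(margin, L) + 1))
        zone |= set(range(offset + max(1, L - margin + 1), offset + L + 1))
        offset += L
    if len(seqs) == 1:
        for loop in structure.hairpin_loops():
            zone |= set(loop)
    return zone


def classify_difference(
    a: SecondaryStructure,
    b: SecondaryStructure,
    terminal_margin: int = 4,
) -> str:
    """Classify where two folds of the same sequence differ.

    Returns ``identical``, ``terminal``, ``central`` or ``both``.  A
    position "differs" when its pairing partner differs between the two
    structures.  Differing positions inside the terminal zone (within
    ``terminal_margin`` of a strand terminus, or in a hairpin's apical
    loop) count as terminal; all others as central.  Symmetric in its two
    arguments.
    """
    if a.plain_sequence != b.plain_sequence:
        raise ValueError("structures fold different sequences")
    if a.plain_dotbracket == b.plain_dotbracket:
        return "identical"
    diffs = {
        i
        for i in range(1, len(a) + 1)
        if a.pairs.get(i) != b.pairs.get(i)
    }
    zone = _terminal_zone(a, terminal_margin) | _terminal_zone(b, terminal_margin)
    has_terminal = bool(diffs & zone)
    has_central = bool(diffs - zone)
    if has_terminal and has_central:
        return "both"
    return "terminal" if has_terminal else "central"
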