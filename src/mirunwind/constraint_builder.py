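"""Automatic generation of hard-constraint strings for duplex unwinding.

Three constraint regimes drive the unwinding-energy calculations:

``mfe_pinned``
    the duplex is pinned to its unconstrained MFE structure, then the
    terminal window is forced open;
``hairpin_pinned``
    the duplex is pinned to the base pairing its arms adopt inside the
    precursor hairpin's MFE fold, then the window is forced open;
``ends_only``
    only the window is forced open and the rest of the duplex refolds
    freely into the constrained MFE.

In the pinned regimes unpaired reference positions are written as ``x``
(forbidden), not ``.`` (free): a free position would let the engine add new
pairs, and the unwinding energy is defined against the *fixed* reference
structure.  Releasing a pinned pair always releases both partners — an ``x``
on one side of a pair would merely shift the partner's pairing, not unwind
the end.  Window widths run 1–4 nucleotides; overhang nucleotides count as
window members (their ``x`` is an energetic no-op, which is what yields a
zero unwinding cost for an already-open end).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

from .structure_model import DuplexStructure, End, insert_separator, parse_dotbracket

Regime = Literal["mfe_pinned", "hairpin_pinned", "ends_only"]
REGIMES: tuple[Regime, ...] = ("mfe_pinned", "hairpin_pinned", "ends_only")
MAX_WIDTH = 4

__all__ = [
    "ConstraintSet",
    "ConstraintError",
    "REGIMES",
    "MAX_WIDTH",
    "pin_structure",
    "unwind_end",
    "write_constraint_file",
    "read_constraint_file",
    "diff_constraints",
]


class ConstraintError(ValueError):
    pass


@dataclass(frozen=True, kw_only=True)
class ConstraintSet:
    """A hard-constraint string aligned to ``seq5p&seq3p``.

    ``string`` keeps the ``&`` separator (carrying no constraint symbol);
    ``end``/``width`` record which terminal window, if any, is forced open.
    """

    string: str
    regime: Regime
    end: End | None = None
    width: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ConstraintError(f"unknown regime {self.regime!r}")
        bad = set(self.string) - set(".x()&")
        if bad:
            raise ConstraintError(f"illegal constraint characters {sorted(bad)}")
        parse_dotbracket(self.string.replace("x", "."))  # balance check
        if not 0 <= self.width <= MAX_WIDTH:
            raise ConstraintError(f"width {self.width} outside 0..{MAX_WIDTH}")
        if (self.end is None) != (self.width == 0):
            raise ConstraintError("end and width must be set together")

    @property
    def plain(self) -> str:
        return self.string.replace("&", "")

    @property
    def x_positions(self) -> frozenset[int]:
        return frozenset(i for i, c in enumerate(self.plain, start=1) if c == "x")

    @property
    def pinned_pairs(self) -> dict[int, int]:
        return parse_dotbracket(self.string.replace("x", "."))


def pin_structure(duplex: DuplexStructure, regime: Regime = "mfe_pinned") -> ConstraintSet:
    """Transcribe a duplex structure into a fully-pinning constraint.

    Paired positions become matched ``()``, unpaired positions become ``x``,
    so exactly one structure satisfies the constraint: the input itself.
    """
    duplex.check_canonical()  # the engine will not meaningfully enforce a non-canonical pin
    chars = [c if c in "()&" else "x" for c in duplex.dotbracket]
    return ConstraintSet(string="".join(chars), regime=regime)


def unwind_end(
    base: ConstraintSet | None,
    duplex: DuplexStructure,
    end: End,
    n: int,
) -> ConstraintSet:
    """Force open the terminal window ``W(end, n)`` on top of *base*.

    Every window position (on both strands) is set to ``x``.  In pinned
    regimes any pinned pair with at least one partner inside the window is
    released — both partners become ``x``.  With ``base=None`` an
    ``ends_only`` constraint is produced: window ``x``, everything else
    free.
    """
    if not 1 <= n <= MAX_WIDTH:
        raise ConstraintError(f"window width {n} outside 1..{MAX_WIDTH}")
    limit = min(duplex.len5p, duplex.len3p) - 5
    if n > limit:
        raise ConstraintError(
            f"width {n} leaves no foldable core (strands {duplex.len5p}+{duplex.len3p} nt "
            f"support at most {limit})"
        )
    window = duplex.end_window(end, n)
    other = duplex.end_window("3p_end" if end == "5p_end" else "5p_end", MAX_WIDTH)
    if window & other:
        raise ConstraintError(f"window W({end},{n}) collides with the opposite end window")

    if base is None:
        chars = ["."] * len(duplex)
        regime: Regime = "ends_only"
    else:
        chars = list(base.plain)
        regime = base.regime
        pinned = parse_dotbracket(base.string.replace("x", "."))
        for i in window:
            j = pinned.get(i)
            if j is not None:
                chars[j - 1] = "x"
    for i in window:
        chars[i - 1] = "x"
    return ConstraintSet(
        string=insert_separator("".join(chars), duplex.len5p),
        regime=regime,
        end=end,
        width=n,
    )


def write_constraint_file(
    path: str | Path,
    entries: Iterable[tuple[str, str, ConstraintSet]],
) -> None:
    """Write engine-dialect constraint records.

    Each entry ``(name, duplex_sequence, constraint)`` becomes a FASTA-style
    block: header line, ``SEQ5P&SEQ3P`` line, constraint line of equal
    length.
    """
    with Path(path).open("w") as fh:
        for name, seq, cs in entries:
            if len(seq) != len(cs.string):
                raise ConstraintError(f"{name}: constraint and sequence lengths differ")
            fh.write(f">{name}\n{seq}\n{cs.string}\n")


def read_constraint_file(path: str | Path) -> list[tuple[str, str, str]]:
    """Read ``(name, sequence, constraint_string)`` triples."""
    out = []
    lines = [ln.rstrip("\n") for ln in Path(path).open() if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ConstraintError(f"{path}: expected header at line {i + 1}")
        if i + 2 >= len(lines):
            raise ConstraintError(f"{path}: truncated record {lines[i]!r}")
        name, seq, cons = lines[i][1:].split()[0], lines[i + 1], lines[i + 2]
        if len(seq) != len(cons):
            raise ConstraintError(f"{path}: {name}: sequence/constraint length mismatch")
        out.append((name, seq, cons))
        i += 3
    return out


def diff_constraints(
    generated: ConstraintSet, manual: str, name: str = ""
) -> list[tuple[int, str, str]]:
    """Compare a generated constraint against a manually curated string.

    Returns ``(position, generated_char, manual_char)`` mismatches (1-based,
    separator excluded).  Manually curated constraint corpora are treated as
    validation data: differences are reported, never silently overridden.
    """
    manual_plain = manual.replace("&", "")
    if len(manual_plain) != len(generated.plain):
        raise ConstraintError(f"{name}: manual constraint length differs")
    return [
        (i, g, m)
        for i, (g, m) in enumerate(zip(generated.plain, manual_plain), start=1)
        if g != m
    ]
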