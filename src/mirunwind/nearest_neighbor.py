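"""Terminal stack free energies from the nearest-neighbour table.

This is the comparison method for the unwinding-energy approach: instead of
asking how forcing an end open changes whole-duplex stability, it sums the
published stacked-pair free energies (ΔG°37) of the first 1–4 helix steps
counted inward from a duplex end.  The parameters are experimental 37 °C
values — deliberately kept un-rescaled, since the comparison is against a
method that cannot be evaluated at other temperatures.

A stack step is written ``XY/ZW`` for::

    5'-X Y-3'
    3'-Z W-5'

with X:Z and Y:W the two base pairs.  Reading the same step from the other
strand's 5'→3' direction gives ``WZ/YX``; the table treats both spellings as
one key.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .structure_model import DuplexStructure, End

__all__ = ["NNTable", "terminal_nn_energy", "StackLookupError"]

_PAIR_NAMES = {1: "CG", 2: "GC", 3: "GU", 4: "UG", 5: "AU", 6: "UA"}


class StackLookupError(KeyError):
    """A stack step is absent from the nearest-neighbour table."""


def _canonical_key(step: str) -> str:
    """Normalise ``XY/ZW`` and its reverse-strand reading to one key."""
    top, bottom = step.split("/")
    alt = bottom[::-1] + "/" + top[::-1]
    return min(step, alt)


@dataclass(frozen=True)
class NNTable:
    """Stacked-pair free energies (kcal/mol) keyed by ``XY/ZW`` steps."""

    values: Mapping[str, float]
    provenance: str = ""

    def __contains__(self, step: str) -> bool:
        return _canonical_key(step) in self.values

    def __getitem__(self, step: str) -> float:
        try:
            return self.values[_canonical_key(step)]
        except KeyError:
            raise StackLookupError(f"stack step {step!r} not in nearest-neighbour table") from None

    @classmethod
    def from_engine(cls, temperature: float = 37.0) -> "NNTable":
        """Build the table from the engine's Turner 2004 parameter set.

        Covers all Watson-Crick and GU wobble steps.  At the default 37 °C
        these are the published nearest-neighbour database values.
        """
        import RNA  # noqa: PLC0415

        RNA.params_load_RNA_Turner2004()
        md = RNA.md()
        md.temperature = temperature
        P = RNA.param(md)
        values: dict[str, float] = {}
        # stack[t_outer][t_inner_rev]: outer pair (X, Z), inner pair read
        # reversed (W, Y); energies are stored in dcal/mol.
        for t1, outer in _PAIR_NAMES.items():
            for t2, inner_rev in _PAIR_NAMES.items():
                x, z = outer
                w, y = inner_rev
                step = f"{x}{y}/{z}{w}"
                values[_canonical_key(step)] = P.stack[t1][t2] / 100.0
        return cls(
            values=values,
            provenance=f"ViennaRNA {RNA.__version__} Turner 2004 stacking energies at {temperature:g}C",
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NNTable":
        """Read a ``step<TAB>dG37_kcal_mol`` table; ``#`` lines are provenance."""
        values: dict[str, float] = {}
        provenance = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                provenance.append(line.lstrip("# "))
                continue
            step, val = line.split("\t")[:2]
            if step == "step":
                continue
            values[_canonical_key(step)] = float(val)
        return cls(values=values, provenance="; ".join(provenance))

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write(f"# {self.provenance}\n")
            fh.write("step\tdG37_kcal_mol\n")
            for step in sorted(self.values):
                fh.write(f"{step}\t{self.values[step]:.2f}\n")


def terminal_nn_energy(duplex: DuplexStructure, end: End, n: int, table: NNTable) -> float:
    """Sum of the first *n* stack free energies counted inward from *end*.

    Walks the strand whose 5' terminus forms the end (the 5p strand for the
    5p end, the 3p strand for the 3p end): step *k* is the stack between the
    pairs closed by positions *k* and *k*+1 of that strand.  A step exists
    only when both positions are paired to adjacent partners; an unpaired or
    bulged position terminates the walk and the remaining terms contribute
    zero — the table has no parameters for interrupted stacks, and an open
    terminal position mirrors the zero unwinding cost of an already-open
    end.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    seq = duplex.plain_sequence
    start = 1 if end == "5p_end" else duplex.len5p + 1
    total = 0.0
    for k in range(n):
        i = start + k
        j = duplex.partner(i)
        j2 = duplex.partner(i + 1)
        if j is None or j2 is None or j2 != j - 1:
            break
        step = f"{seq[i - 1]}{seq[i]}/{seq[j - 1]}{seq[j2 - 1]}"
        total += table[step]
    return total
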