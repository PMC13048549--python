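"""Deterministic synthetic hairpin/duplex generator with planted structure.

Fixtures emulate the geometry of Dicer products: two ~19–24 nt strands with
a complementary core, 0–3 internal mismatches or bulges, 2-nt 3' overhangs
at both duplex ends, and hairpins built as arm–loop–arm concatenations.
Every fixture records its ground truth (pair map, feature positions, arm
intervals), so parsing, projection and annotation code is testable without
repository downloads; a single integer seed drives one reproducible stream.

Optionally one duplex end is planted "weak" (terminal AU pairs) and the
other "strong" (terminal GC pairs), and a guide arm is labelled concordant
with the weak end in a configurable fraction of duplexes — the
thermodynamic-asymmetry condition the unwinding statistics probe.  These
are idealised constructs, not biological miRNA simulations: no sequence
motifs, no loop realism.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

from .sequence_io import MirnaRecord
from .structure_model import (
    CANONICAL_PAIRS,
    DuplexStructure,
    SecondaryStructure,
    insert_separator,
    render_dotbracket,
)

__all__ = ["FixtureSpec", "PlantedDuplex", "PlantedHairpin", "FixtureSpecError", "make_duplex", "make_hairpin", "make_cohort"]

_PURINES_WEAK = "AU"
_STRONG = "GC"


class FixtureSpecError(ValueError):
    pass


@dataclass(frozen=True, kw_only=True)
class FixtureSpec:
    """Parameters of one synthetic fixture.

    ``strand_length`` counts the 5p strand including its overhang;
    ``gc_fraction`` defaults GC-rich (0.6) so planted helices dominate the
    folding landscape and engine-dependent tests are deterministic in
    practice.  ``weak_end`` plants AU terminal pairs at that end and GC
    pairs at the other.
    """

    seed: int
    strand_length: int = 22
    n_mismatch: int = 0
    n_bulge: int = 0
    overhang: int = 2
    gc_fraction: float = 0.6
    loop_length: int = 6
    weak_end: str | None = None

    def __post_init__(self) -> None:
        if self.strand_length < 12:
            raise FixtureSpecError("strand_length must be >= 12 (unwinding window + core)")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise FixtureSpecError("gc_fraction must be in [0, 1]")
        if self.overhang < 0 or self.loop_length < 3:
            raise FixtureSpecError("overhang must be >= 0 and loop_length >= 3")
        if self.weak_end not in (None, "5p_end", "3p_end"):
            raise FixtureSpecError(f"weak_end must be None/5p_end/3p_end, got {self.weak_end!r}")
        core = self.strand_length - self.overhang
        # features sit >= 2 columns from the core termini, pairwise separated
        slots = max(0, (core - 6) // 2)
        if self.n_mismatch + self.n_bulge > slots:
            raise FixtureSpecError(
                f"{self.n_mismatch} mismatches + {self.n_bulge} bulges do not fit a "
                f"{core}-column core"
            )


@dataclass(frozen=True, kw_only=True)
class PlantedDuplex:
    seq5p: str
    seq3p: str
    structure: DuplexStructure
    mismatches: tuple[tuple[int, ...], ...]  # duplex positions per planted mismatch
    bulges: tuple[tuple[int, ...], ...]      # duplex positions per planted bulge


@dataclass(frozen=True, kw_only=True)
class PlantedHairpin:
    sequence: str
    structure: SecondaryStructure
    pos5p: tuple[int, int]
    pos3p: tuple[int, int]
    duplex: PlantedDuplex


def _random_base(rng: random.Random, gc_fraction: float) -> str:
    if rng.random() < gc_fraction:
        return rng.choice(_STRONG)
    return rng.choice(_PURINES_WEAK)


_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _noncomplementary(rng: random.Random, base: str) -> str:
    choices = [b for b in "ACGU" if base + b not in CANONICAL_PAIRS]
    return rng.choice(choices)


def _feature_columns(rng: random.Random, core: int, count: int) -> list[int]:
    """Distinct interior columns, >= 2 from core termini, >= 2 apart."""
    candidates = list(range(2, core - 2))
    for _ in range(200):
        cols = sorted(rng.sample(candidates, count)) if count else []
        if all(b - a >= 2 for a, b in zip(cols, cols[1:])):
            return cols
    raise FixtureSpecError("could not place non-overlapping features")


def make_duplex(spec: FixtureSpec) -> PlantedDuplex:
    """Construct a duplex with a planted, fully known structure."""
    rng = random.Random(spec.seed)
    core = spec.strand_length - spec.overhang

    top = [_random_base(rng, spec.gc_fraction) for _ in range(core)]
    if spec.weak_end is not None:
        weak_cols = (0, 1) if spec.weak_end == "5p_end" else (core - 2, core - 1)
        strong_cols = (core - 2, core - 1) if spec.weak_end == "5p_end" else (0, 1)
        for c in weak_cols:
            top[c] = rng.choice(_PURINES_WEAK)
        for c in strong_cols:
            top[c] = rng.choice(_STRONG)
    bottom = [_COMPLEMENT[b] for b in top]

    cols = _feature_columns(rng, core, spec.n_mismatch + spec.n_bulge)
    rng.shuffle(cols)
    mismatch_cols = sorted(cols[: spec.n_mismatch])
    bulge_cols = sorted(cols[spec.n_mismatch :])
    for c in mismatch_cols:
        bottom[c] = _noncomplementary(rng, top[c])
    # bulge boundary c: one extra nucleotide between columns c and c+1
    bulge_strand = {c: rng.choice((1, 2)) for c in bulge_cols}
    bulge_base = {c: rng.choice("ACGU") for c in bulge_cols}

    top_seq: list[str] = []
    top_pos: dict[int, int] = {}
    bulge_top_pos: dict[int, int] = {}
    for c in range(core):
        top_seq.append(top[c])
        top_pos[c] = len(top_seq)
        if bulge_strand.get(c) == 1:
            top_seq.append(bulge_base[c])
            bulge_top_pos[c] = len(top_seq)
    for _ in range(spec.overhang):
        top_seq.append(rng.choice("ACGU"))
    len5p = len(top_seq)

    bottom_seq: list[str] = []
    bottom_pos: dict[int, int] = {}
    bulge_bottom_pos: dict[int, int] = {}
    for c in reversed(range(core)):
        if bulge_strand.get(c) == 2:
            bottom_seq.append(bulge_base[c])
            bulge_bottom_pos[c] = len5p + len(bottom_seq)
        bottom_seq.append(bottom[c])
        bottom_pos[c] = len5p + len(bottom_seq)
    for _ in range(spec.overhang):
        bottom_seq.append(rng.choice("ACGU"))

    pairs: dict[int, int] = {}
    for c in range(core):
        if c in mismatch_cols:
            continue
        i, j = top_pos[c], bottom_pos[c]
        pairs[i] = j
        pairs[j] = i

    seq5p, seq3p = "".join(top_seq), "".join(bottom_seq)
    total = len(seq5p) + len(seq3p)
    structure = DuplexStructure(
        sequence=insert_separator(seq5p + seq3p, len5p),
        dotbracket=insert_separator(render_dotbracket(pairs, total), len5p),
        energy=None,
        strand_break=len5p,
    )
    mismatches = tuple((top_pos[c], bottom_pos[c]) for c in mismatch_cols)
    bulges = tuple(
        (bulge_top_pos[c],) if bulge_strand[c] == 1 else (bulge_bottom_pos[c],)
        for c in bulge_cols
    )
    return PlantedDuplex(
        seq5p=seq5p, seq3p=seq3p, structure=structure, mismatches=mismatches, bulges=bulges
    )


def make_hairpin(spec: FixtureSpec) -> PlantedHairpin:
    """Arm–loop–arm hairpin whose stem is the overhang-free duplex of *spec*."""
    duplex = make_duplex(replace(spec, overhang=0))
    rng = random.Random(spec.seed + 1)
    loop = "".join(rng.choice("AC") for _ in range(spec.loop_length))
    len5p = len(duplex.seq5p)
    sequence = duplex.seq5p + loop + duplex.seq3p
    pairs = {}
    for i, j in duplex.structure.pairs.items():
        ni = i if i <= len5p else i + spec.loop_length
        nj = j if j <= len5p else j + spec.loop_length
        pairs[ni] = nj
    structure = SecondaryStructure(
        sequence=sequence,
        dotbracket=render_dotbracket(pairs, len(sequence)),
        energy=None,
    )
    return PlantedHairpin(
        sequence=sequence,
        structure=structure,
        pos5p=(1, len5p),
        pos3p=(len5p + spec.loop_length + 1, len(sequence)),
        duplex=duplex,
    )


@dataclass(frozen=True, kw_only=True)
class CohortEntry:
    record: MirnaRecord
    planted: PlantedHairpin
    weak_end: str


def make_cohort(
    n: int,
    seed: int,
    *,
    strand_length: int = 22,
    overhang: int = 2,
    gc_fraction: float = 0.6,
    loop_length: int = 6,
    max_mismatch: int = 2,
    max_bulge: int = 1,
    guide_consistency: float = 0.78,
) -> list[CohortEntry]:
    """A seeded cohort of annotated miRNA-like records.

    Each entry has a hairpin (arm–loop–arm), a duplex with 2-nt 3'
    overhangs, a randomly weak/strong pair of ends and a guide-arm label
    concordant with the weak end in ``guide_consistency`` of entries —
    mirroring the field's observation that strand choice follows duplex end
    asymmetry for roughly three quarters of miRNAs.

    Note the hairpin embeds the full duplex strands (overhangs fall into
    the loop and the hairpin 3' terminus), so mature arms are exact hairpin
    substrings.
    """
    rng = random.Random(seed)
    out: list[CohortEntry] = []
    attempts = 0
    while len(out) < n and attempts < 20 * n:
        attempts += 1
        sub_seed = rng.randrange(2**31)
        weak_end = rng.choice(("5p_end", "3p_end"))
        spec = FixtureSpec(
            seed=sub_seed,
            strand_length=rng.randint(strand_length - 1, strand_length + 1),
            n_mismatch=rng.randint(0, max_mismatch),
            n_bulge=rng.randint(0, max_bulge),
            overhang=overhang,
            gc_fraction=gc_fraction,
            loop_length=loop_length,
            weak_end=weak_end,
        )
        # hairpin stem = duplex including overhangs, so arms stay substrings
        hp_rng = random.Random(sub_seed + 2)
        duplex = make_duplex(spec)
        loop = "".join(hp_rng.choice("AC") for _ in range(loop_length))
        hairpin_seq = duplex.seq5p + loop + duplex.seq3p
        if hairpin_seq.count(duplex.seq5p) != 1 or hairpin_seq.count(duplex.seq3p) != 1:
            continue  # rare repeated-substring draw; resample
        favoured = "5p" if weak_end == "5p_end" else "3p"
        other = "3p" if favoured == "5p" else "5p"
        guide = favoured if rng.random() < guide_consistency else other
        len5p = len(duplex.seq5p)
        pairs = {}
        for i, j in duplex.structure.pairs.items():
            ni = i if i <= len5p else i + loop_length
            nj = j if j <= len5p else j + loop_length
            pairs[ni] = nj
        planted = PlantedHairpin(
            sequence=hairpin_seq,
            structure=SecondaryStructure(
                sequence=hairpin_seq,
                dotbracket=render_dotbracket(pairs, len(hairpin_seq)),
                energy=None,
            ),
            pos5p=(1, len5p),
            pos3p=(len5p + loop_length + 1, len(hairpin_seq)),
            duplex=duplex,
        )
        record = MirnaRecord(
            name=f"syn-mir-{len(out) + 1:03d}",
            hairpin_seq=hairpin_seq,
            seq5p=duplex.seq5p,
            seq3p=duplex.seq3p,
            pos5p=planted.pos5p,
            pos3p=planted.pos3p,
            guide_arm=guide,
        )
        out.append(CohortEntry(record=record, planted=planted, weak_end=weak_end))
    if len(out) < n:
        raise FixtureSpecError(f"could only generate {len(out)} of {n} cohort entries")
    return out
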