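"""Reading, writing and assembly of miRNA sequence records.

Three plain-text formats flow through the pipeline:

* hairpin FASTA — one single-stranded precursor sequence per record;
* duplex FASTA — a two-strand record whose sequence line joins the 5p and
  3p arms with a single ``&`` (the cofold dialect), 5p arm first;
* an annotation table (TSV) with columns ``name``, ``seq5p``, ``seq3p`` and
  ``guide_arm``, where ``guide_arm`` records which arm accumulates the most
  sequencing reads in the source repository.

All sequences are normalised to uppercase RNA on input (``T`` becomes ``U``,
a common artifact of repository exports of DNA-alphabet sequences).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGU")
GUIDE_ARMS = ("5p", "3p", "unknown")

__all__ = [
    "MirnaRecord",
    "FastaFormatError",
    "AlphabetError",
    "MatureLocationError",
    "read_fasta",
    "write_fasta",
    "split_duplex_record",
    "join_duplex",
    "locate_mature_in_hairpin",
    "read_annotation_table",
    "write_annotation_table",
    "records_from_tables",
    "normalize_rna",
]


class FastaFormatError(ValueError):
    """Malformed FASTA / duplex record."""


class AlphabetError(ValueError):
    """Sequence contains characters outside the RNA alphabet."""


class MatureLocationError(ValueError):
    """A mature arm could not be placed (or placed uniquely) in its hairpin."""


def normalize_rna(seq: str, *, allow_separator: bool = False, name: str = "") -> str:
    """Uppercase, DNA->RNA (T->U) and validate the alphabet.

    ``allow_separator`` permits a single ``&`` strand separator (duplex
    records).  Raises :class:`AlphabetError` naming the record and the
    1-based offending position otherwise.
    """
    out = seq.strip().upper().replace("T", "U")
    allowed = RNA_ALPHABET | ({"&"} if allow_separator else set())
    for i, ch in enumerate(out, start=1):
        if ch not in allowed:
            where = f" in record {name!r}" if name else ""
            raise AlphabetError(f"non-RNA character {ch!r} at position {i}{where}")
    if allow_separator and out.count("&") > 1:
        raise FastaFormatError(f"more than one '&' in record {name!r}")
    return out


@dataclass(kw_only=True)
class MirnaRecord:
    """One miRNA: hairpin precursor, mature arms and the annotated guide.

    Coordinates (``pos5p``/``pos3p``) are 1-based closed intervals within
    ``hairpin_seq``; ``None`` until located.  The 5p interval lies entirely
    upstream of the 3p interval when both are set.
    """

    name: str
    hairpin_seq: str | None = None
    seq5p: str | None = None
    seq3p: str | None = None
    pos5p: tuple[int, int] | None = None
    pos3p: tuple[int, int] | None = None
    guide_arm: str = "unknown"

    def __post_init__(self) -> None:
        if self.guide_arm not in GUIDE_ARMS:
            raise ValueError(f"guide_arm must be one of {GUIDE_ARMS}, got {self.guide_arm!r}")
        for attr in ("hairpin_seq", "seq5p", "seq3p"):
            val = getattr(self, attr)
            if val is not None:
                setattr(self, attr, normalize_rna(val, name=self.name))
        self._check_positions()

    def _check_positions(self) -> None:
        for arm, pos in (("seq5p", self.pos5p), ("seq3p", self.pos3p)):
            if pos is None:
                continue
            seq = getattr(self, arm)
            if self.hairpin_seq is None or seq is None:
                raise ValueError(f"{self.name}: positions set without sequences")
            lo, hi = pos
            if self.hairpin_seq[lo - 1 : hi] != seq:
                raise ValueError(
                    f"{self.name}: {arm} does not match hairpin interval [{lo},{hi}]"
                )
        if self.pos5p is not None and self.pos3p is not None:
            if not self.pos5p[1] < self.pos3p[0]:
                raise ValueError(f"{self.name}: 5p interval must lie upstream of 3p interval")

    @property
    def has_duplex(self) -> bool:
        return self.seq5p is not None and self.seq3p is not None

    @property
    def duplex_sequence(self) -> str:
        if not self.has_duplex:
            raise ValueError(f"{self.name}: both arms required for a duplex")
        return f"{self.seq5p}&{self.seq3p}"


def read_fasta(path: str | Path, *, allow_separator: bool = True) -> list[tuple[str, str]]:
    """Read FASTA into ``(name, sequence)`` pairs, order preserved.

    Sequences are normalised to uppercase RNA.  Duplex-dialect records
    (``SEQ5P&SEQ3P`` on the sequence line) are accepted when
    ``allow_separator`` is true.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        if not rec.id:
            raise FastaFormatError(f"{path}: record with empty header")
        out.append((rec.id, normalize_rna(str(rec.seq), allow_separator=allow_separator, name=rec.id)))
    return out


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, str(path), "fasta-2line")


def split_duplex_record(sequence: str) -> tuple[str, str]:
    """Split ``SEQ5P&SEQ3P`` into its two strands (5p arm first).

    Exactly one ``&`` must be present and both parts must be non-empty.
    """
    if sequence.count("&") != 1:
        raise FastaFormatError(
            f"duplex record must contain exactly one '&', got {sequence.count('&')}"
        )
    seq5p, seq3p = sequence.split("&")
    if not seq5p or not seq3p:
        raise FastaFormatError("duplex record has an empty strand")
    return seq5p, seq3p


def join_duplex(seq5p: str, seq3p: str) -> str:
    """Inverse of :func:`split_duplex_record`."""
    if not seq5p or not seq3p:
        raise FastaFormatError("duplex strands must be non-empty")
    return f"{seq5p}&{seq3p}"


def locate_mature_in_hairpin(record: MirnaRecord) -> MirnaRecord:
    """Return a copy of *record* with ``pos5p``/``pos3p`` filled.

    Each mature arm must occur exactly once as a contiguous substring of the
    hairpin; multiple hits raise :class:`MatureLocationError` listing all
    start positions rather than silently taking the first (a wrong placement
    would silently corrupt the hairpin-derived duplex structure downstream).
    """
    if record.hairpin_seq is None or not record.has_duplex:
        raise ValueError(f"{record.name}: hairpin and both mature arms are required")

    def find(arm: str, seq: str) -> tuple[int, int]:
        starts = [m.start() + 1 for m in re.finditer(f"(?={re.escape(seq)})", record.hairpin_seq)]
        if not starts:
            raise MatureLocationError(f"{record.name}: {arm} arm not found in hairpin")
        if len(starts) > 1:
            raise MatureLocationError(
                f"{record.name}: {arm} arm occurs at multiple hairpin positions {starts}"
            )
        return starts[0], starts[0] + len(seq) - 1

    pos5p = find("5p", record.seq5p)
    pos3p = find("3p", record.seq3p)
    return replace(record, pos5p=pos5p, pos3p=pos3p)


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Read the ``name / seq5p / seq3p / guide_arm`` TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"name", "seq5p", "seq3p", "guide_arm"}
    missing = required - set(df.columns)
    if missing:
        raise FastaFormatError(f"annotation table missing columns: {sorted(missing)}")
    return df


def write_annotation_table(path: str | Path, records: Sequence[MirnaRecord]) -> None:
    df = pd.DataFrame(
        {
            "name": [r.name for r in records],
            "seq5p": [r.seq5p for r in records],
            "seq3p": [r.seq3p for r in records],
            "guide_arm": [r.guide_arm for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def records_from_tables(
    annotation: pd.DataFrame,
    hairpins: Sequence[tuple[str, str]] | None = None,
    *,
    locate: bool = True,
) -> list[MirnaRecord]:
    """Assemble :class:`MirnaRecord` objects from an annotation table.

    Records lacking either mature arm are dropped (a duplex cannot be built
    without an annotated passenger strand).  When *hairpins* are given, each
    record's precursor is attached and the mature arms are located in it.
    """
    hp = dict(hairpins) if hairpins else {}
    out: list[MirnaRecord] = []
    for row in annotation.itertuples(index=False):
        if pd.isna(row.seq5p) or pd.isna(row.seq3p):
            continue
        rec = MirnaRecord(
            name=row.name,
            hairpin_seq=hp.get(row.name),
            seq5p=row.seq5p,
            seq3p=row.seq3p,
            guide_arm=row.guide_arm if row.guide_arm in GUIDE_ARMS else "unknown",
        )
        if locate and rec.hairpin_seq is not None:
            rec = locate_mature_in_hairpin(rec)
        out.append(rec)
    return out
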