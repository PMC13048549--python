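"""Thin adapter to the ViennaRNA nearest-neighbour folding engine.

Exposes the four primitives the pipeline needs — single-strand MFE folding,
two-strand cofolding, hard-constrained cofolding and fixed-structure energy
evaluation — all at a caller-specified temperature.  The engine is reached
through the :class:`FoldingEngine` protocol so tests can substitute a stub,
and every report the pipeline writes records the engine version and
parameter set (printed energies are engine-version sensitive).

Hard constraints use the engine's dot-bracket constraint alphabet: ``x``
forbids pairing at a position, matched ``()`` pins a pair (enforced when
``EngineConfig.enforce_constraints`` is set, mirroring the command-line
``-C --enforceConstraint`` usage), ``.`` leaves a position free.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

from .structure_model import (
    CANONICAL_PAIRS,
    DuplexStructure,
    SecondaryStructure,
    insert_separator,
    parse_dotbracket,
)

__all__ = [
    "EngineConfig",
    "FoldingEngine",
    "ViennaRNAEngine",
    "FoldingError",
    "EngineUnavailableError",
    "ConstraintInfeasibleError",
    "StructureEvalError",
    "default_engine",
]

#: temperatures the standard pipeline sweeps (°C)
STANDARD_TEMPERATURES = (15.0, 20.0, 25.0, 37.0)


class FoldingError(RuntimeError):
    pass


class EngineUnavailableError(FoldingError):
    pass


class ConstraintInfeasibleError(FoldingError):
    """No structure satisfies the hard constraints."""


class StructureEvalError(FoldingError):
    """Structure cannot be evaluated (e.g. a non-canonical pair)."""


def _import_rna():
    try:
        import RNA  # noqa: PLC0415
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise EngineUnavailableError(
            "the ViennaRNA python bindings (module 'RNA') are not installed; "
            "install the ViennaRNA package to enable folding"
        ) from exc
    return RNA


@dataclass(frozen=True, kw_only=True)
class EngineConfig:
    """Folding-engine configuration.

    temperature
        Folding temperature in °C.  20 °C is the default: the standard
        laboratory culture temperature of *C. elegans*, for which the 37 °C
        engine default is non-physiological.
    parameter_set
        Nearest-neighbour parameter table identifier.  ``rna_turner2004``
        is the engine's built-in default.
    dangle_mode
        Engine dangling-end treatment; ``None`` keeps the engine default,
        which is recorded in output provenance rather than guessed.
    enforce_constraints
        Whether pinned pairs in a hard-constraint string are enforced to be
        present (as opposed to merely allowed).
    """

    temperature: float = 20.0
    parameter_set: str = "rna_turner2004"
    dangle_mode: int | None = None
    enforce_constraints: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.temperature < 100.0):
            raise ValueError(f"temperature {self.temperature} outside supported range (0, 100)")


@runtime_checkable
class FoldingEngine(Protocol):
    def fold_hairpin(self, seq: str, cfg: EngineConfig) -> SecondaryStructure: ...

    def cofold_duplex(
        self, seq5p: str, seq3p: str, cfg: EngineConfig, constraint: str | None = None
    ) -> DuplexStructure: ...

    def eval_structure(self, sequence: str, dotbracket: str, cfg: EngineConfig) -> float: ...

    def version(self) -> str: ...


class ViennaRNAEngine:
    """Folding primitives backed by the ViennaRNA python bindings."""

    _PARAMETER_SETS = ("rna_turner2004", "rna_turner1999", "rna_andronescu2007")

    def version(self) -> str:
        return _import_rna().__version__

    def describe(self, cfg: EngineConfig) -> str:
        """One-line provenance string for report headers."""
        RNA = _import_rna()
        dangles = cfg.dangle_mode if cfg.dangle_mode is not None else RNA.md().dangles
        return (
            f"engine=ViennaRNA {self.version()} parameters={cfg.parameter_set} "
            f"dangles={dangles} temperature={cfg.temperature:g}C"
        )

    def _model_details(self, cfg: EngineConfig):
        RNA = _import_rna()
        if cfg.parameter_set not in self._PARAMETER_SETS:
            raise ValueError(
                f"unknown parameter_set {cfg.parameter_set!r}; choose from {self._PARAMETER_SETS}"
            )
        if cfg.parameter_set == "rna_turner1999":
            RNA.params_load_RNA_Turner1999()
        elif cfg.parameter_set == "rna_andronescu2007":
            RNA.params_load_RNA_Andronescu2007()
        else:
            RNA.params_load_RNA_Turner2004()
        md = RNA.md()
        md.temperature = cfg.temperature
        if cfg.dangle_mode is not None:
            md.dangles = cfg.dangle_mode
        return md

    # -- folding -----------------------------------------------------------

    def fold_hairpin(self, seq: str, cfg: EngineConfig) -> SecondaryStructure:
        if "&" in seq:
            raise ValueError("fold_hairpin expects a single strand (no '&')")
        RNA = _import_rna()
        fc = RNA.fold_compound(seq, self._model_details(cfg))
        db, energy = fc.mfe()
        return SecondaryStructure(
            sequence=seq, dotbracket=db, energy=float(energy), temperature=cfg.temperature
        )

    def cofold_duplex(
        self, seq5p: str, seq3p: str, cfg: EngineConfig, constraint: str | None = None
    ) -> DuplexStructure:
        """Two-strand MFE fold, optionally under hard constraints.

        *constraint* is a dot-bracket constraint string over
        ``seq5p & seq3p`` (the ``&`` may be included or omitted).  With
        ``cfg.enforce_constraints``, pinned pairs must appear in the output;
        ``x`` positions must come out unpaired.  An unsatisfiable constraint
        raises :class:`ConstraintInfeasibleError`.
        """
        RNA = _import_rna()
        seq = f"{seq5p}&{seq3p}"
        fc = RNA.fold_compound(seq, self._model_details(cfg))
        plain_constraint = None
        if constraint is not None:
            plain_constraint = constraint.replace("&", "")
            if len(plain_constraint) != len(seq5p) + len(seq3p):
                raise ValueError(
                    f"constraint length {len(plain_constraint)} does not match "
                    f"duplex length {len(seq5p) + len(seq3p)}"
                )
            options = RNA.CONSTRAINT_DB_DEFAULT
            if cfg.enforce_constraints:
                options |= RNA.CONSTRAINT_DB_ENFORCE_BP
            fc.hc_add_from_db(plain_constraint, options)
        db, energy = fc.mfe()
        structure = DuplexStructure(
            sequence=seq,
            dotbracket=insert_separator(db, len(seq5p)),
            energy=float(energy),
            temperature=cfg.temperature,
            strand_break=len(seq5p),
        )
        if plain_constraint is not None:
            self._check_satisfied(structure, plain_constraint, cfg.enforce_constraints)
        return structure

    @staticmethod
    def _check_satisfied(structure: DuplexStructure, constraint: str, enforced: bool) -> None:
        pairs = structure.pairs
        for pos, ch in enumerate(constraint, start=1):
            if ch == "x" and pos in pairs:
                raise ConstraintInfeasibleError(
                    f"position {pos} was forced unpaired but is paired in the result"
                )
        if enforced:
            for i, j in parse_dotbracket(constraint.replace("x", ".")).items():
                if pairs.get(i) != j:
                    raise ConstraintInfeasibleError(
                        f"enforced pair {i}<->{j} absent from the result"
                    )

    def eval_structure(self, sequence: str, dotbracket: str, cfg: EngineConfig) -> float:
        """Nearest-neighbour energy (kcal/mol) of exactly this structure."""
        RNA = _import_rna()
        if "&" in sequence and "&" not in dotbracket:
            dotbracket = insert_separator(dotbracket, sequence.index("&"))
        probe = (
            DuplexStructure(
                sequence=sequence,
                dotbracket=dotbracket,
                strand_break=sequence.index("&"),
            )
            if "&" in sequence
            else SecondaryStructure(sequence=sequence, dotbracket=dotbracket)
        )
        try:
            probe.check_canonical()
        except ValueError as exc:
            raise StructureEvalError(str(exc)) from exc
        fc = RNA.fold_compound(sequence, self._model_details(cfg))
        return float(fc.eval_structure(probe.plain_dotbracket))


_DEFAULT_ENGINE: ViennaRNAEngine | None = None


def default_engine() -> ViennaRNAEngine:
    """Shared :class:`ViennaRNAEngine` instance."""
    global _DEFAULT_ENGINE
    if _DEFAULT_ENGINE is None:
        _DEFAULT_ENGINE = ViennaRNAEngine()
    return _DEFAULT_ENGINE
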