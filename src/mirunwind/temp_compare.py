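"""Temperature sweeps of hairpin and duplex folds.

Folds every record at a list of temperatures (by default the physiological
range of *C. elegans*, 15/20/25 °C, plus the 37 °C algorithm default) and
classifies where the predicted MFE structures differ from a reference
temperature.  Difference detection is exact dot-bracket equality — the
reproducible analogue of calling an "altered MFE structure" by eye — and
localisation reuses :func:`mirunwind.structure_model.classify_difference`
with its configurable terminal margin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import pandas as pd

from .folding_engine import STANDARD_TEMPERATURES, EngineConfig, FoldingEngine, default_engine
from .sequence_io import MirnaRecord
from .structure_model import SecondaryStructure, classify_difference

MoleculeKind = Literal["hairpin", "duplex"]

__all__ = ["TempSweepResult", "sweep", "difference_report", "STANDARD_TEMPERATURES"]


@dataclass(kw_only=True)
class TempSweepResult:
    name: str
    molecule_kind: MoleculeKind
    structures: dict[float, SecondaryStructure]

    def category_vs(self, ref_temp: float, temp: float, terminal_margin: int = 4) -> str:
        return classify_difference(
            self.structures[temp], self.structures[ref_temp], terminal_margin
        )


def sweep(
    records: Sequence[MirnaRecord],
    temps: Iterable[float] = STANDARD_TEMPERATURES,
    cfg: EngineConfig | None = None,
    engine: FoldingEngine | None = None,
    kind: MoleculeKind = "hairpin",
) -> list[TempSweepResult]:
    """One MFE fold per (record, temperature); deterministic."""
    temps = list(temps)
    if not temps:
        raise ValueError("temps must be non-empty")
    engine = engine or default_engine()
    base = cfg or EngineConfig()
    out = []
    for rec in records:
        structures: dict[float, SecondaryStructure] = {}
        for t in temps:
            tcfg = EngineConfig(
                temperature=t,
                parameter_set=base.parameter_set,
                dangle_mode=base.dangle_mode,
                enforce_constraints=base.enforce_constraints,
            )
            try:
                if kind == "hairpin":
                    structures[t] = engine.fold_hairpin(rec.hairpin_seq, tcfg)
                else:
                    structures[t] = engine.cofold_duplex(rec.seq5p, rec.seq3p, tcfg)
            except Exception as exc:
                raise type(exc)(f"{rec.name} at {t}C: {exc}") from exc
        out.append(TempSweepResult(name=rec.name, molecule_kind=kind, structures=structures))
    return out


def difference_report(
    results: Sequence[TempSweepResult],
    ref_temp: float,
    terminal_margin: int = 4,
) -> pd.DataFrame:
    """Per-temperature counts of identical/terminal/central/both vs *ref_temp*.

    Category counts sum to the non-identical count and, with the identical
    count, to the number of records; percentages are over all records.  The
    report is invariant to record input order.
    """
    if not results:
        raise ValueError("no sweep results")
    temps = sorted(set().union(*(r.structures.keys() for r in results)))
    if ref_temp not in temps:
        raise ValueError(f"reference temperature {ref_temp} not present in the sweep")
    rows = []
    for t in temps:
        if t == ref_temp:
            continue
        counts = {"identical": 0, "terminal": 0, "central": 0, "both": 0}
        for r in results:
            counts[r.category_vs(ref_temp, t, terminal_margin)] += 1
        total = len(results)
        non_identical = total - counts["identical"]
        rows.append(
            {
                "temp": t,
                "ref_temp": ref_temp,
                "n_records": total,
                "identical": counts["identical"],
                "terminal": counts["terminal"],
                "central": counts["central"],
                "both": counts["both"],
                "non_identical": non_identical,
                "pct_non_identical": 100.0 * non_identical / total,
            }
        )
    return pd.DataFrame(rows)


def per_record_differences(
    results: Sequence[TempSweepResult],
    ref_temp: float,
    terminal_margin: int = 4,
) -> pd.DataFrame:
    """Long-form table: name, kind, temp, ref_temp, identical flag, category."""
    rows = []
    for r in results:
        for t in sorted(r.structures):
            if t == ref_temp:
                continue
            cat = r.category_vs(ref_temp, t, terminal_margin)
            rows.append(
                {
                    "name": r.name,
                    "kind": r.molecule_kind,
                    "temp": t,
                    "ref_temp": ref_temp,
                    "identical": cat == "identical",
                    "category": cat,
                }
            )
    return pd.DataFrame(rows)
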