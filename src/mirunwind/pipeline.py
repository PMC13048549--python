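"""End-to-end orchestration: records in, energy tables and predictions out.

Glues the per-module operations into the standard analysis: cofold every
duplex, project the hairpin fold onto the duplex region, compute unwinding
profiles under each constraint regime, look up nearest-neighbour terminal
stabilities, and run the twin-drive prediction for every energy method and
window width.  The prediction step consumes the same per-end energies the
profile tables report — one source of truth for both outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .folding_engine import EngineConfig, FoldingEngine, default_engine
from .nearest_neighbor import NNTable, terminal_nn_energy
from .sequence_io import MirnaRecord
from .strand_selection import (
    StrandPrediction,
    TwinDriveParams,
    default_params,
    make_prediction,
    predictions_to_frame,
)
from .structure_model import DuplexStructure, extract_hairpin_duplex
from .unwinding_energy import WIDTHS, UnwindingProfile, compute_profile

__all__ = ["AnalysisResult", "analyze_records"]


@dataclass(kw_only=True)
class AnalysisResult:
    profiles: list[UnwindingProfile]
    predictions: pd.DataFrame
    mfe_structures: dict[str, DuplexStructure] = field(default_factory=dict)
    hairpin_duplexes: dict[str, DuplexStructure] = field(default_factory=dict)


def analyze_records(
    records: Sequence[MirnaRecord],
    cfg: EngineConfig | None = None,
    engine: FoldingEngine | None = None,
    params: TwinDriveParams | None = None,
    methods: Iterable[str] = ("mfe_pinned", "hairpin_pinned", "ends_only", "nearest_neighbor"),
    widths: Iterable[int] = WIDTHS,
    nn_table: NNTable | None = None,
) -> AnalysisResult:
    """Run the full unwinding + prediction analysis over *records*.

    Regime methods requiring a hairpin (``hairpin_pinned``) are silently
    restricted to records that carry a precursor sequence with located
    arms.  Records without both mature arms are skipped entirely (no
    duplex can be formed).
    """
    cfg = cfg or EngineConfig()
    engine = engine or default_engine()
    params = params or default_params()
    methods = list(methods)
    widths = list(widths)
    if "nearest_neighbor" in methods and nn_table is None:
        nn_table = NNTable.from_engine()

    profiles: list[UnwindingProfile] = []
    predictions: list[StrandPrediction] = []
    mfe_structures: dict[str, DuplexStructure] = {}
    hairpin_duplexes: dict[str, DuplexStructure] = {}

    for rec in records:
        if not rec.has_duplex:
            continue
        mfe = engine.cofold_duplex(rec.seq5p, rec.seq3p, cfg)
        mfe_structures[rec.name] = mfe
        hp_duplex = None
        if rec.hairpin_seq is not None and rec.pos5p is not None:
            hp_fold = engine.fold_hairpin(rec.hairpin_seq, cfg)
            hp_duplex = extract_hairpin_duplex(rec, hp_fold)
            hairpin_duplexes[rec.name] = hp_duplex

        per_method_energies: dict[str, dict[str, dict[int, float]]] = {}
        for method in methods:
            if method == "nearest_neighbor":
                per_method_energies[method] = {
                    end: {n: terminal_nn_energy(mfe, end, n, nn_table) for n in widths}
                    for end in ("5p_end", "3p_end")
                }
                continue
            if method == "hairpin_pinned" and hp_duplex is None:
                continue
            profile = compute_profile(
                rec.name,
                rec.seq5p,
                rec.seq3p,
                method,
                cfg,
                engine,
                hairpin_duplex=hp_duplex,
                duplex_mfe=mfe,
            )
            profiles.append(profile)
            per_method_energies[method] = {
                end: {n: profile.ddG[end][n] for n in widths} for end in ("5p_end", "3p_end")
            }

        for method, energies in per_method_energies.items():
            for n in widths:
                predictions.append(
                    make_prediction(
                        rec.name,
                        method,
                        n,
                        energies["5p_end"][n],
                        energies["3p_end"][n],
                        rec.seq5p[0],
                        rec.seq3p[0],
                        rec.guide_arm,
                        params,
                    )
                )

    return AnalysisResult(
        profiles=profiles,
        predictions=predictions_to_frame(predictions),
        mfe_structures=mfe_structures,
        hairpin_duplexes=hairpin_duplexes,
    )
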