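"""Twin-drive prediction of miRNA guide-strand choice.

The twin-drive model combines two influences on Argonaute loading into a
single log strand ratio::

    ln(5p/3p) = k * ddG(5p−3p) + N[nt5p] − N[nt3p]

where ``ddG(5p−3p)`` is the difference between the unwinding energies (or
other end-stability measures) of the two duplex ends, ``nt5p``/``nt3p`` are
the 5'-terminal nucleotides of the two strands, ``k`` weighs the
thermodynamic drive and ``N`` maps each base to its 5'-nucleotide identity
drive (the MID domain of Argonaute prefers U > A > G > C).  A positive
ln(5p/3p) predicts 5p dominance, a negative one 3p dominance; an exact zero
is ambiguous and scored as incorrect rather than inflating accuracy.

Constants are a configuration input with a packaged, provenance-labelled
default file; prediction never looks at the annotated guide arm — guide and
passenger labels enter only at scoring time.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "TwinDriveParams",
    "StrandPrediction",
    "load_params",
    "default_params",
    "predict",
    "make_prediction",
    "score",
    "stratify_by_asymmetry",
    "consistency_tally",
]

BASES = ("U", "A", "G", "C")
ENERGY_METHODS = ("mfe_pinned", "hairpin_pinned", "ends_only", "nearest_neighbor")


@dataclass(frozen=True, kw_only=True)
class TwinDriveParams:
    """Constants of the twin-drive formula, with provenance."""

    k: float
    N: Mapping[str, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = set(BASES) - set(self.N)
        if missing:
            raise ValueError(f"N-drive values missing for bases: {sorted(missing)}")


def load_params(path: str | Path) -> TwinDriveParams:
    """Load constants from a YAML file with keys ``k``, ``N``, ``provenance``."""
    data = yaml.safe_load(Path(path).read_text())
    return TwinDriveParams(
        k=float(data["k"]),
        N={b: float(v) for b, v in data["N"].items()},
        provenance=str(data.get("provenance", "")),
    )


def default_params() -> TwinDriveParams:
    """Packaged default constants (see the file's provenance field)."""
    ref = resources.files("mirunwind").joinpath("data/twin_drive_constants.yaml")
    data = yaml.safe_load(ref.read_text())
    return TwinDriveParams(
        k=float(data["k"]),
        N={b: float(v) for b, v in data["N"].items()},
        provenance=str(data.get("provenance", "")),
    )


def predict(
    dG_5p_end: float,
    dG_3p_end: float,
    nt5p: str,
    nt3p: str,
    params: TwinDriveParams,
) -> float:
    """ln(5p/3p) for one duplex.

    *dG_5p_end*/*dG_3p_end* must come from the same energy method and
    window width; *nt5p*/*nt3p* are the 5'-terminal bases of the 5p and 3p
    strands.
    """
    try:
        n5, n3 = params.N[nt5p], params.N[nt3p]
    except KeyError as exc:
        raise ValueError(f"no N-drive value for base {exc.args[0]!r}") from None
    return params.k * (dG_5p_end - dG_3p_end) + n5 - n3


@dataclass(frozen=True, kw_only=True)
class StrandPrediction:
    name: str
    energy_method: str
    width: int
    ddG_5p_minus_3p: float
    nt5p: str
    nt3p: str
    ln_ratio: float
    predicted_arm: str
    annotated_arm: str
    correct: bool


def make_prediction(
    name: str,
    energy_method: str,
    width: int,
    dG_5p_end: float,
    dG_3p_end: float,
    nt5p: str,
    nt3p: str,
    annotated_arm: str,
    params: TwinDriveParams,
) -> StrandPrediction:
    ln_ratio = predict(dG_5p_end, dG_3p_end, nt5p, nt3p, params)
    if ln_ratio > 0:
        predicted = "5p"
    elif ln_ratio < 0:
        predicted = "3p"
    else:
        predicted = "ambiguous"
    return StrandPrediction(
        name=name,
        energy_method=energy_method,
        width=width,
        ddG_5p_minus_3p=dG_5p_end - dG_3p_end,
        nt5p=nt5p,
        nt3p=nt3p,
        ln_ratio=ln_ratio,
        predicted_arm=predicted,
        annotated_arm=annotated_arm,
        correct=predicted == annotated_arm,
    )


def predictions_to_frame(predictions: Sequence[StrandPrediction]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in predictions])


def score(predictions: Sequence[StrandPrediction] | pd.DataFrame) -> pd.DataFrame:
    """Accuracy per (energy_method, width); ambiguous counts as incorrect."""
    df = predictions if isinstance(predictions, pd.DataFrame) else predictions_to_frame(predictions)
    grouped = df.groupby(["energy_method", "width"], sort=True)["correct"]
    out = grouped.agg(n_correct="sum", n_total="count").reset_index()
    out["accuracy"] = out["n_correct"] / out["n_total"]
    return out


def _guide_minus_passenger(row: pd.Series) -> float:
    d = row["ddG_5p_minus_3p"]
    return d if row["annotated_arm"] == "5p" else -d


def stratify_by_asymmetry(predictions: Sequence[StrandPrediction] | pd.DataFrame) -> pd.DataFrame:
    """Accuracy split by the sign of ddG(guide end) − ddG(passenger end).

    Duplexes whose annotated guide end is the cheaper one to unwind
    (negative difference) are the thermodynamically "expected" cases.
    """
    df = predictions if isinstance(predictions, pd.DataFrame) else predictions_to_frame(predictions)
    df = df.copy()
    df["ddG_guide_minus_passenger"] = df.apply(_guide_minus_passenger, axis=1)
    df["stratum"] = df["ddG_guide_minus_passenger"].map(
        lambda v: "negative" if v < 0 else "non_negative"
    )
    grouped = df.groupby(["energy_method", "width", "stratum"], sort=True)["correct"]
    out = grouped.agg(n_correct="sum", n_total="count").reset_index()
    out["accuracy"] = out["n_correct"] / out["n_total"]
    return out


def consistency_tally(predictions: Sequence[StrandPrediction] | pd.DataFrame) -> pd.DataFrame:
    """Per-miRNA tally of always-/never-correct across methods and widths."""
    df = predictions if isinstance(predictions, pd.DataFrame) else predictions_to_frame(predictions)
    per = df.groupby("name")["correct"].agg(["all", "any"]).reset_index()
    per["always_correct"] = per["all"]
    per["never_correct"] = ~per["any"]
    return per[["name", "always_correct", "never_correct"]]
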