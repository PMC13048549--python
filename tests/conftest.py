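"""Shared fixtures: engine handles, reference sequences, small cohorts and
an exhaustive-enumeration folding oracle for tiny duplexes."""

from __future__ import annotations

from functools import lru_cache

import pytest

from mirunwind.folding_engine import EngineConfig, ViennaRNAEngine, default_engine
from mirunwind.structure_model import CANONICAL_PAIRS
from mirunwind.synthetic import make_cohort

# miRBase v22.1 mature arm sequences of cel-let-7
LET7_5P = "UGAGGUAGUAGGUUGUAUAGUU"
LET7_3P = "CUAUGCAAUUUUCUACCUUACC"


@pytest.fixture(scope="session")
def engine() -> ViennaRNAEngine:
    return default_engine()


@pytest.fixture(scope="session")
def cfg20() -> EngineConfig:
    return EngineConfig(temperature=20.0)


@pytest.fixture(scope="session")
def let7() -> tuple[str, str]:
    return LET7_5P, LET7_3P


@pytest.fixture(scope="session")
def small_cohort():
    """Twelve annotated synthetic records (seeded; mixed feature counts)."""
    return make_cohort(12, seed=7)


def brute_force_cofold(
    seq5p: str,
    seq3p: str,
    forbidden: frozenset[int] = frozenset(),
    temperature: float = 20.0,
) -> tuple[float, str]:
    """Exhaustive minimum over all canonical non-crossing pairings.

    Enumerates every nesting-compatible set of canonical pairs of the
    concatenated duplex (intra-strand pairs respect the 3-nt minimum
    hairpin loop; pairs spanning the strand break do not), skips pairs
    touching *forbidden* positions, scores each candidate structure with
    the engine's fixed-structure evaluator and returns the best
    ``(energy, dotbracket)``.  Independent of the engine's MFE recursion —
    only the additive energy evaluation is shared.
    """
    seq = seq5p + seq3p
    L1, L = len(seq5p), len(seq5p) + len(seq3p)
    engine = default_engine()
    cfg = EngineConfig(temperature=temperature)

    def ok(i: int, j: int) -> bool:
        if i in forbidden or j in forbidden:
            return False
        if seq[i - 1] + seq[j - 1] not in CANONICAL_PAIRS:
            return False
        return (i <= L1 < j) or j - i >= 4

    @lru_cache(maxsize=None)
    def enum(i: int, j: int) -> tuple[frozenset, ...]:
        if i > j:
            return (frozenset(),)
        out = list(enum(i + 1, j))
        for k in range(i + 1, j + 1):
            if ok(i, k):
                for a in enum(i + 1, k - 1):
                    for b in enum(k + 1, j):
                        out.append(a | b | {(i, k)})
        return tuple(out)

    best_e, best_db = 0.0, "." * L
    for pairing in enum(1, L):
        db = ["."] * L
        for i, j in pairing:
            db[i - 1], db[j - 1] = "(", ")"
        e = engine.eval_structure(f"{seq5p}&{seq3p}", "".join(db), cfg)
        if e < best_e:
            best_e, best_db = e, "".join(db)
    return best_e, best_db


@pytest.fixture(scope="session")
def brute_oracle():
    return brute_force_cofold
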