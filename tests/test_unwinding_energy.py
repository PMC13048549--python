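"""Unwinding-energy profiles: reference values, invariants across regimes,
and guide/passenger group statistics."""

import numpy as np
import pytest
from scipy import stats as sps

from mirunwind.folding_engine import EngineConfig
from mirunwind.sequence_io import MirnaRecord, locate_mature_in_hairpin
from mirunwind.structure_model import extract_hairpin_duplex
from mirunwind.unwinding_energy import (
    UnwindingProfile,
    WIDTHS,
    asymmetry,
    compute_profile,
    group_stats,
    profiles_to_frame,
)

# a synthetic duplex whose MFE leaves the 5p-end window open up to width 3
OPEN_END_5P = ("AUCCAAUUUGUCGAAAGUCCGG", "GGACUUUCGUCAAAUUGAUUG")


class TestLet7Profile:
    """The cel-let-7 duplex at 20 °C is the worked reference case."""

    @pytest.fixture(scope="class")
    def profile(self, let7, cfg20):
        return compute_profile("cel-let-7", *let7, "mfe_pinned", cfg20)

    def test_wound_reference_energy(self, profile):
        assert profile.dG_wound == pytest.approx(-30.12, abs=0.005)

    def test_four_nucleotide_unwinding_energies(self, profile):
        assert profile.ddG["5p_end"][4] == pytest.approx(8.26, abs=0.005)
        assert profile.ddG["3p_end"][4] == pytest.approx(7.41, abs=0.005)

    def test_asymmetry_is_difference_of_end_costs(self, profile):
        assert asymmetry(profile, 4) == pytest.approx(8.26 - 7.41, abs=0.01)

    def test_ddG_nonnegative_and_monotone(self, profile):
        for end in ("5p_end", "3p_end"):
            vals = [profile.ddG[end][n] for n in WIDTHS]
            assert all(v >= -0.005 for v in vals)
            assert vals == sorted(vals)  # pinned release only removes stacks


class TestZeroCostOpenEnd:
    def test_already_unwound_window_costs_nothing(self, cfg20):
        p = compute_profile("open5p", *OPEN_END_5P, "mfe_pinned", cfg20)
        for n in (1, 2, 3):
            assert p.ddG["5p_end"][n] == pytest.approx(0.0, abs=1e-6)


class TestNearNickPinnedPairs:
    """Hairpin-derived duplexes can pair arm termini across the strand nick
    at < 4 nt separation.  The engine's constraint parser omits such pins,
    so the profile falls back to fixed-structure evaluation; energies must
    still come out finite and consistent with the evaluator."""

    HAIRPIN = "GCCCGUCGCCGCUUUUGCAUUGCCCCACAUAGCAUAAGCGGCGACGGGCUC"
    SEQ5P = "GCCCGUCGCCGCUUUUGCAUUG"
    SEQ3P = "AUAGCAUAAGCGGCGACGGGCUC"

    def test_profile_completes_with_evaluator_fallback(self, engine, cfg20):
        rec = locate_mature_in_hairpin(
            MirnaRecord(
                name="near-nick", hairpin_seq=self.HAIRPIN, seq5p=self.SEQ5P, seq3p=self.SEQ3P
            )
        )
        hp_duplex = extract_hairpin_duplex(rec, engine.fold_hairpin(self.HAIRPIN, cfg20))
        # the problematic configuration: an inter-strand pair at 2 nt separation
        assert any(
            j - i < 4 for i, j in hp_duplex.interstrand_pairs()
        )
        p = compute_profile(
            rec.name, rec.seq5p, rec.seq3p, "hairpin_pinned", cfg20, hairpin_duplex=hp_duplex
        )
        wound = engine.eval_structure(hp_duplex.sequence, hp_duplex.dotbracket, cfg20)
        assert p.dG_wound == pytest.approx(wound, abs=1e-6)
        for end in ("5p_end", "3p_end"):
            for n in WIDTHS:
                assert p.dG_unwound[end][n] == pytest.approx(p.dG_unwound[end][n])  # finite


class TestRegimeRelations:
    @pytest.fixture(scope="class")
    def cohort_profiles(self, small_cohort, cfg20, engine):
        out = []
        for entry in small_cohort:
            rec = entry.record
            hp_fold = engine.fold_hairpin(rec.hairpin_seq, cfg20)
            hp_duplex = extract_hairpin_duplex(rec, hp_fold)
            per = {}
            for regime in ("mfe_pinned", "ends_only", "hairpin_pinned"):
                per[regime] = compute_profile(
                    rec.name, rec.seq5p, rec.seq3p, regime, cfg20, hairpin_duplex=hp_duplex
                )
            out.append(per)
        return out

    def test_ends_only_dominates_pinned(self, cohort_profiles):
        """The freely refolding feasible set contains the pinned structure."""
        for per in cohort_profiles:
            for end in ("5p_end", "3p_end"):
                for n in WIDTHS:
                    assert (
                        per["ends_only"].dG_unwound[end][n]
                        <= per["mfe_pinned"].dG_unwound[end][n] + 5e-3
                    )

    def test_mfe_wound_reference_is_global_minimum(self, cohort_profiles):
        for per in cohort_profiles:
            assert per["mfe_pinned"].dG_wound <= per["hairpin_pinned"].dG_wound + 5e-3

    def test_ddG_nonnegative_under_mfe_regimes(self, cohort_profiles):
        for per in cohort_profiles:
            for regime in ("mfe_pinned", "ends_only"):
                for end in ("5p_end", "3p_end"):
                    for n in WIDTHS:
                        assert per[regime].ddG[end][n] >= -5e-3

    def test_negative_ddG_rejected_for_mfe_regimes(self):
        with pytest.raises(ValueError, match="cannot"):
            UnwindingProfile(
                name="bad",
                regime="mfe_pinned",
                temperature=20.0,
                dG_wound=-10.0,
                dG_unwound={"5p_end": {1: -11.0}, "3p_end": {1: -9.0}},
            )


def _fake_profile(name, ddg5, ddg3):
    # hairpin_pinned: the one regime whose ddG may take either sign
    return UnwindingProfile(
        name=name,
        regime="hairpin_pinned",
        temperature=20.0,
        dG_wound=-20.0,
        dG_unwound={"5p_end": {1: -20.0 + ddg5}, "3p_end": {1: -20.0 + ddg3}},
    )


class TestGroupStats:
    def test_symmetric_profiles_give_p_of_one(self):
        profiles = [_fake_profile(f"m{i}", v, v) for i, v in enumerate([1.0, 2.0, 3.0, 4.0])]
        ann = {p.name: "5p" for p in profiles}
        out = group_stats(profiles, ann, widths=[1])
        assert out.loc[0, "p_value"] == pytest.approx(1.0)
        assert out.loc[0, "guide_mean"] == out.loc[0, "passenger_mean"]

    def test_unknown_annotations_excluded(self):
        profiles = [_fake_profile(f"m{i}", i, i + 1.0) for i in range(5)]
        ann = {p.name: "5p" for p in profiles}
        ann["m4"] = "unknown"
        out = group_stats(profiles, ann, widths=[1])
        assert out.loc[0, "n"] == 4

    def test_empirical_power_matches_closed_form(self):
        """Shifted-normal simulation through group_stats reproduces the
        analytic power of the equal-variance two-sample t-test."""
        rng = np.random.default_rng(42)
        n, delta, alpha, reps = 8, 1.5, 0.05, 400
        hits = 0
        for _ in range(reps):
            guide = rng.normal(0.0, 1.0, n)
            passenger = rng.normal(delta, 1.0, n)
            profiles = [
                _fake_profile(f"m{i}", g, p) for i, (g, p) in enumerate(zip(guide, passenger))
            ]
            ann = {p.name: "5p" for p in profiles}
            out = group_stats(profiles, ann, widths=[1])
            hits += out.loc[0, "p_value"] < alpha
        df = 2 * n - 2
        ncp = delta / np.sqrt(2.0 / n)
        tcrit = sps.t.ppf(1 - alpha / 2, df)
        power = 1 - sps.nct.cdf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp)
        assert hits / reps == pytest.approx(power, abs=0.07)


def test_profiles_to_frame_layout(let7, cfg20):
    p = compute_profile("cel-let-7", *let7, "mfe_pinned", cfg20)
    df = profiles_to_frame([p])
    assert len(df) == 8  # 2 ends x 4 widths
    assert set(df.columns) == {
        "name", "regime", "temperature", "end", "width", "dG_wound", "dG_unwound", "ddG"
    }
    row = df[(df["end"] == "5p_end") & (df["width"] == 4)].iloc[0]
    assert row["dG_wound"] == -30.12 and row["ddG"] == 8.26
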