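"""Class-I metric computation: alignment, foreignness, agretopicity,
threshold flags and the deterministic mock predictor."""

import itertools
import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from neoprio.design import PeptideCandidate
from neoprio.errors import MissingPredictionError, NeoprioError
from neoprio.io import PredictionRow
from neoprio.tesla import (
    ForeignnessParams,
    MockPredictor,
    TablePredictor,
    TeslaMetrics,
    agretopicity,
    alignment_score,
    best_binding,
    compute_tesla_metrics,
    foreignness,
    tesla_filter,
    tesla_rank,
)

AA = "ACDEFGHIKLMNPQRSTVWY"
BLOSUM62 = substitution_matrices.load("BLOSUM62")


def brute_force_alignment(a: str, b: str) -> int:
    """Exhaustive maximum over all gapless window pairs of equal length."""
    best = 0
    for la in range(1, len(a) + 1):
        for i in range(len(a) - la + 1):
            for j in range(len(b) - la + 1):
                score = sum(BLOSUM62[x, y]
                            for x, y in zip(a[i:i + la], b[j:j + la]))
                best = max(best, score)
    return int(best)


def make_candidate(sequence="SIINFEKL", wt=None, mut_offset=1):
    wt = wt or ("A" + sequence[1:] if sequence[0] != "A"
                else "C" + sequence[1:])
    return PeptideCandidate(sequence=sequence, wt_sequence=wt,
                            source_variant="P01:G1", mut_offset=mut_offset,
                            klass="tesla_short")


class TestAlignmentScore:
    def test_self_alignment_of_known_peptide(self):
        # sum of BLOSUM62 diagonal entries S+I+I+N+F+E+K+L = 38
        assert alignment_score("SIINFEKL", "SIINFEKL") == 38

    def test_self_alignment_is_maximal(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            k = int(rng.integers(8, 13))
            pep = "".join(rng.choice(list(AA), size=k))
            other = "".join(rng.choice(list(AA), size=k))
            assert alignment_score(pep, pep) >= alignment_score(pep, other)

    def test_matches_exhaustive_window_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(40):
            a = "".join(rng.choice(list(AA),
                                   size=int(rng.integers(8, 13))))
            b = "".join(rng.choice(list(AA),
                                   size=int(rng.integers(8, 13))))
            assert alignment_score(a, b) == brute_force_alignment(a, b)

    def test_score_floor_is_zero(self):
        # strongly mismatched single residues have negative BLOSUM scores
        assert alignment_score("W", "P") == 0

    def test_non_standard_residue_rejected(self):
        with pytest.raises(NeoprioError, match="non-standard"):
            alignment_score("SIINFEKX", "SIINFEKL")


class TestForeignness:
    def test_empty_reference_set_is_zero(self):
        assert foreignness("SIINFEKL", []) == 0.0

    def test_score_equal_to_midpoint_gives_half(self):
        # self-alignment of SIINFEKL scores 38; set the midpoint there
        params = ForeignnessParams(midpoint_a=38.0)
        assert foreignness("SIINFEKL", ["SIINFEKL"], params) == \
            pytest.approx(0.5)

    def test_adding_epitopes_never_decreases(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            pep = "".join(rng.choice(list(AA), size=9))
            epitopes = ["".join(rng.choice(list(AA), size=9))
                        for _ in range(int(rng.integers(1, 5)))]
            r_small = foreignness(pep, epitopes[:-1])
            r_full = foreignness(pep, epitopes)
            assert r_full >= r_small
            assert 0.0 <= r_full < 1.0

    def test_monotone_in_alignment_score(self):
        # an exact copy in the reference set dominates a mismatched one
        pep = "SIINFEKL"
        r_exact = foreignness(pep, [pep])
        r_far = foreignness(pep, ["WPWPWPWP"])
        assert r_exact > r_far

    def test_huge_scores_saturate_below_one(self):
        pep = "SIINFEKLSIIN"
        r = foreignness(pep, [pep] * 100,
                        ForeignnessParams(midpoint_a=0.0))
        assert 0.999 < r < 1.0


class TestAgretopicity:
    def test_ratio(self):
        assert agretopicity(5.0, 100.0) == pytest.approx(0.05)

    def test_identity(self):
        assert agretopicity(42.0, 42.0) == 1.0

    def test_non_positive_rejected(self):
        with pytest.raises(NeoprioError):
            agretopicity(5.0, 0.0)


class TestBestBinding:
    def test_minimum_across_alleles(self):
        rows = [
            PredictionRow(peptide="SIINFEKL", allele="HLA-A*02:01",
                          ic50_nm=40.0, stability_hours=2.0),
            PredictionRow(peptide="SIINFEKL", allele="HLA-B*07:02",
                          ic50_nm=900.0, stability_hours=9.0),
        ]
        ic50, allele, stab = best_binding(
            "SIINFEKL", ["HLA-A*02:01", "HLA-B*07:02"], TablePredictor(rows))
        assert (ic50, allele, stab) == (40.0, "HLA-A*02:01", 2.0)

    def test_single_allele(self):
        rows = [PredictionRow(peptide="SIINFEKL", allele="HLA-A*02:01",
                              ic50_nm=10.0)]
        assert best_binding("SIINFEKL", ["HLA-A*02:01"],
                            TablePredictor(rows))[0] == 10.0

    def test_missing_pair_names_peptide_and_allele(self):
        with pytest.raises(MissingPredictionError,
                           match="SIINFEKL.*HLA-A\\*02:01"):
            best_binding("SIINFEKL", ["HLA-A*02:01"], TablePredictor([]))

    def test_empty_allele_list_rejected(self):
        with pytest.raises(NeoprioError):
            best_binding("SIINFEKL", [], TablePredictor([]))


class TestTeslaFilter:
    def _metrics(self, ic50, stab, tpm, agre, foreign):
        return TeslaMetrics(
            peptide=make_candidate(), best_ic50_nm=ic50,
            best_allele="HLA-A*02:01", stability_hours=stab, tpm=tpm,
            agretopicity=agre, foreignness=foreign)

    def test_all_strict_inequalities_hold(self):
        m = tesla_filter(self._metrics(67.9, 1.8, 11.0, 0.09, 1e-15))
        assert m.overall_pass

    @pytest.mark.parametrize("field,value", [
        ("ic50", 68.0), ("stab", 1.7), ("tpm", 10.0), ("agre", 0.1),
        ("foreign", 1e-16),
    ])
    def test_boundary_values_fail_their_criterion(self, field, value):
        base = dict(ic50=67.9, stab=1.8, tpm=11.0, agre=0.09,
                    foreign=1e-15)
        base[field] = value
        m = tesla_filter(self._metrics(**base))
        assert not m.overall_pass

    def test_grid_matches_strict_inequality_oracle(self):
        """Every combination of values straddling each threshold matches a
        direct evaluation of the five strict comparisons."""
        eps = 1e-18
        grid = itertools.product(
            (67.99, 68.0, 68.01), (1.69, 1.7, 1.71), (9.99, 10.0, 10.01),
            (0.099, 0.1, 0.101), (1e-16 - eps, 1e-16, 1e-16 + eps))
        for ic50, stab, tpm, agre, foreign in grid:
            m = tesla_filter(self._metrics(ic50, stab, tpm, agre, foreign))
            expected = (ic50 < 68 and stab > 1.7 and tpm > 10
                        and agre < 0.1 and foreign > 1e-16)
            assert m.overall_pass == expected, (ic50, stab, tpm, agre,
                                                foreign)

    def test_missing_stability_fails_with_flag(self):
        m = tesla_filter(self._metrics(10.0, None, 50.0, 0.01, 0.5))
        assert m.stability_missing and not m.c_stability
        assert not m.overall_pass

    def test_random_tuples_match_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            ic50 = float(rng.uniform(1, 200))
            stab = float(rng.uniform(0, 5))
            tpm = float(rng.uniform(0, 50))
            agre = float(rng.uniform(0, 0.5))
            foreign = float(10 ** rng.uniform(-20, 0))
            m = tesla_filter(self._metrics(ic50, stab, tpm, agre, foreign))
            assert m.overall_pass == (
                ic50 < 68 and stab > 1.7 and tpm > 10 and agre < 0.1
                and foreign > 1e-16)


class TestTeslaRank:
    def _metrics(self, seq, ic50, foreign=0.5):
        return TeslaMetrics(
            peptide=make_candidate(sequence=seq), best_ic50_nm=ic50,
            best_allele="HLA-A*02:01", stability_hours=2.0, tpm=20.0,
            agretopicity=0.05, foreignness=foreign)

    def test_ascending_ic50(self):
        ms = [self._metrics("AAAAAAAC", 5.0), self._metrics("AAAAAAAD", 60.0),
              self._metrics("AAAAAAAE", 30.0)]
        ranked = tesla_rank([ms[1], ms[2], ms[0]])
        assert [m.best_ic50_nm for m in ranked] == [5.0, 30.0, 60.0]
        assert [m.rank for m in ranked] == [1, 2, 3]

    def test_single_candidate(self):
        (m,) = tesla_rank([self._metrics("AAAAAAAC", 5.0)])
        assert m.rank == 1

    def test_foreignness_breaks_ic50_ties(self):
        hi = self._metrics("AAAAAAAC", 10.0, foreign=0.9)
        lo = self._metrics("AAAAAAAD", 10.0, foreign=0.2)
        assert tesla_rank([lo, hi])[0] is hi


class TestMockPredictor:
    def test_deterministic(self):
        p = MockPredictor(seed=7)
        assert p.predict("SIINFEKL", "HLA-A*02:01") == \
            p.predict("SIINFEKL", "HLA-A*02:01")
        assert MockPredictor(seed=7).predict("SIINFEKL", "HLA-A*02:01") == \
            p.predict("SIINFEKL", "HLA-A*02:01")

    def test_alleles_and_seeds_vary_output(self):
        p = MockPredictor(seed=7)
        a = p.predict("SIINFEKL", "HLA-A*02:01").ic50_nm
        b = p.predict("SIINFEKL", "HLA-B*07:02").ic50_nm
        c = MockPredictor(seed=8).predict("SIINFEKL", "HLA-A*02:01").ic50_nm
        assert a != b and a != c

    def test_bounds_over_random_inputs(self):
        rng = np.random.default_rng(4)
        p = MockPredictor(seed=1)
        for _ in range(300):
            pep = "".join(rng.choice(list(AA), size=9))
            row = p.predict(pep, "HLA-A*02:01")
            assert 1.0 <= row.ic50_nm <= 50_000.0
            assert 0.1 <= row.stability_hours <= 10.0

    def test_log_uniform_ic50_spreads_over_decades(self):
        rng = np.random.default_rng(5)
        p = MockPredictor(seed=2)
        logs = [math.log10(p.predict(
            "".join(rng.choice(list(AA), size=9)), "X").ic50_nm)
            for _ in range(500)]
        assert min(logs) < 1 and max(logs) > 3.5


class TestComputeMetrics:
    def test_wild_type_scored_on_mutant_best_allele(self):
        cand = make_candidate("SIINFEKL", wt="SIINFEKV", mut_offset=8)
        rows = [
            PredictionRow(peptide="SIINFEKL", allele="A1", ic50_nm=10.0,
                          stability_hours=3.0),
            PredictionRow(peptide="SIINFEKL", allele="A2", ic50_nm=90.0,
                          stability_hours=9.0),
            PredictionRow(peptide="SIINFEKV", allele="A1", ic50_nm=400.0),
            PredictionRow(peptide="SIINFEKV", allele="A2", ic50_nm=4.0),
        ]
        m = compute_tesla_metrics(cand, ["A1", "A2"], TablePredictor(rows),
                                  tpm=25.0, reference_epitopes=["SIINFEKL"])
        assert m.best_allele == "A1"
        # agretopicity uses the wild type on A1 (400), not A2's better 4.0
        assert m.agretopicity == pytest.approx(10.0 / 400.0)
        assert m.c_affinity and m.c_tpm and m.c_agretopicity
        assert m.c_foreignness  # exact copy in the reference set
        assert m.overall_pass
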