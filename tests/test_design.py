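"""Cassette designs, diversity arithmetic, TRIM mixtures, degenerate codons, codon choice."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synlib.design import (
    CdrDesign,
    build_design,
    codon_optimize,
    degenerate_profile,
    design_diversity,
    expected_unique,
    preferred_codon_table,
    scientific_3sig,
    trim_mixture,
    uniform_cdr_design,
    uniform_library_design,
)
from synlib.errors import DesignError
from synlib.genetics import AA_ALPHABET, SENSE_CODONS_BY_AA, translate
from synlib.profiling import CompositionProfile


def _profile(matrix, cdr_id="H1"):
    counts = (np.asarray(matrix) * 1000).round().astype(int)
    return CompositionProfile(cdr_id=cdr_id, length=len(matrix), matrix=matrix, counts=counts)


# ---------------------------------------------------------------------------
# build_design


def test_build_design_exclusion_renormalizes():
    m = np.zeros((1, 20))
    m[0, AA_ALPHABET.index("A")] = 0.5
    m[0, AA_ALPHABET.index("C")] = 0.5
    d = build_design(_profile(m), exclude={"C"})
    assert d.frequency(0, "A") == pytest.approx(1.0)
    assert d.frequency(0, "C") == 0.0


def test_build_design_uniform20_minus_cys():
    m = np.full((2, 20), 0.05)
    d = build_design(_profile(m), exclude={"C"}, floor=0.0)
    for p in range(2):
        assert d.support(p) == [r for r in AA_ALPHABET if r != "C"]
        for r in d.support(p):
            assert d.frequency(p, r) == pytest.approx(1 / 19)


def test_build_design_all_mass_excluded_errors():
    m = np.zeros((1, 20))
    m[0, AA_ALPHABET.index("C")] = 1.0
    with pytest.raises(DesignError):
        build_design(_profile(m), exclude={"C"})


def test_build_design_floor_zeroes_rare_residues():
    m = np.zeros((1, 20))
    m[0, AA_ALPHABET.index("A")] = 0.97
    m[0, AA_ALPHABET.index("Y")] = 0.03
    d = build_design(_profile(m), exclude=set(), floor=0.05)
    assert d.support(0) == ["A"]
    with pytest.raises(ValueError):
        build_design(_profile(m), exclude=set(), floor=0.2)


# ---------------------------------------------------------------------------
# diversity


def test_single_support_position_diversity_is_one():
    m = np.zeros((1, 20))
    m[0, 0] = 1.0
    assert design_diversity(CdrDesign("H1", 1, m)) == 1


def test_diversity_matches_bruteforce_on_random_designs():
    rng = np.random.default_rng(9)
    for _ in range(10):
        length = int(rng.integers(1, 5))
        supports = []
        matrix = np.zeros((length, 20))
        for p in range(length):
            k = int(rng.integers(1, 4))
            chosen = rng.choice(20, size=k, replace=False)
            matrix[p, chosen] = 1.0 / k
            supports.append([AA_ALPHABET[j] for j in chosen])
        d = CdrDesign("H3", length, matrix)
        enumerated = len({"".join(t) for t in itertools.product(*supports)})
        assert design_diversity(d) == enumerated


def test_scientific_rendering():
    assert scientific_3sig(6859) == "6.86 x 10^3"
    assert scientific_3sig(130321) == "1.30 x 10^5"
    assert scientific_3sig(1) == "1.00 x 10^0"


def test_library_diversity_combines_over_h3_lengths(template):
    lib = uniform_library_design(template)
    report = design_diversity(lib)
    fixed = 1
    for cdr in ("H1", "H2", "L1", "L2", "L3"):
        fixed *= report.per_cassette[cdr]
    expected = sum(report.per_cassette[f"H3({L})"] * fixed for L in range(3, 19))
    assert report.combined == expected
    assert report.per_cassette["H1"] == 19**6


# ---------------------------------------------------------------------------
# TRIM mixtures


def test_trim_single_residue_design():
    m = np.zeros((1, 20))
    m[0, AA_ALPHABET.index("A")] = 1.0
    mix = trim_mixture(CdrDesign("H1", 1, m), codon_choice={"A": "GCT"})
    assert mix.positions == [[("GCT", 1.0)]]


def test_trim_uniform19_mixture():
    d = uniform_cdr_design("H2", 1)
    mix = trim_mixture(d)
    assert len(mix.positions[0]) == 19
    for codon, prop in mix.positions[0]:
        assert prop == pytest.approx(1 / 19)
        assert translate(codon) != "*"


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(1, 5))
def test_trim_expected_composition_round_trip(seed, length):
    rng = np.random.default_rng(seed)
    matrix = np.zeros((length, 20))
    for p in range(length):
        k = int(rng.integers(1, 8))
        chosen = rng.choice(20, size=k, replace=False)
        w = rng.random(k)
        matrix[p, chosen] = w / w.sum()
    d = CdrDesign("H3", length, matrix)
    mix = trim_mixture(d)
    np.testing.assert_allclose(mix.expected_composition(), matrix, atol=1e-9)


# ---------------------------------------------------------------------------
# degenerate codons


def test_nnk_profile_frozen_values():
    p = degenerate_profile("NNK")
    assert p.codon_count == 32
    assert p.stop_probability == pytest.approx(1 / 32)
    assert p.probabilities["W"] == pytest.approx(1 / 32)
    assert p.probabilities["L"] == pytest.approx(3 / 32)
    assert set(AA_ALPHABET) <= set(p.probabilities)


def test_nnn_and_concrete_patterns():
    p = degenerate_profile("NNN")
    assert p.codon_count == 64
    assert p.stop_probability == pytest.approx(3 / 64)
    assert sum(p.probabilities.values()) == pytest.approx(1.0, abs=1e-12)
    tgg = degenerate_profile("TGG")
    assert tgg.probabilities == {"W": 1.0}
    assert tgg.codon_count == 1
    with pytest.raises(ValueError):
        degenerate_profile("NNZ")


# ---------------------------------------------------------------------------
# codon optimization


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.text(alphabet=AA_ALPHABET, min_size=1, max_size=40))
def test_codon_optimize_round_trips(aa):
    assert translate(codon_optimize(aa)) == aa


def test_identical_tables_reduce_to_single_argmax():
    from synlib.codon_usage import ECOLI_USAGE

    table = preferred_codon_table(ECOLI_USAGE, ECOLI_USAGE)
    for aa, codons in SENSE_CODONS_BY_AA.items():
        best = max(sorted(codons), key=lambda c: ECOLI_USAGE[c])
        assert ECOLI_USAGE[table[aa]] == ECOLI_USAGE[best]


def test_uniform_tables_tie_break_alphabetically():
    uniform = {c: 1.0 for codons in SENSE_CODONS_BY_AA.values() for c in codons}
    table = preferred_codon_table(uniform, uniform)
    for aa, codons in SENSE_CODONS_BY_AA.items():
        assert table[aa] == sorted(codons)[0]


# ---------------------------------------------------------------------------
# sampling-coverage math


def test_expected_unique_edge_cases():
    assert expected_unique(10, 0) == 0.0
    assert expected_unique(1, 5) == 1.0


def test_expected_unique_two_by_two_enumeration():
    # 4 equiprobable outcomes of 2 draws from {1,2}: distinct counts 1,2,2,1
    assert expected_unique(2, 2) == pytest.approx(1.5)


def test_expected_unique_monotone_and_bounded():
    D = 1000
    prev = 0.0
    for N in (0, 1, 10, 100, 1000, 10000):
        e = expected_unique(D, N)
        assert e >= prev - 1e-12
        assert e <= min(D, N) + 1e-9
        prev = e


def test_expected_unique_stable_for_huge_diversity():
    assert expected_unique(10**30, 10**6) == pytest.approx(1e6, rel=1e-9)
    assert expected_unique(10**400, 10**6) == pytest.approx(1e6, rel=1e-9)
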