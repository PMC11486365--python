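import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import helpers
from conftest import torsions_from_matrix
from tango.comparison import (
    DEFAULT_ANGLES,
    SEVERITY_BINS,
    angle_diff,
    coverage_fractions,
    global_mcq,
    lcs_ta,
    mcq,
    pair_residues,
    per_residue_mcq,
    severity_bin,
)
from tango.errors import ConfigError
from tango.torsion_core import AngleKind


@pytest.mark.parametrize(
    "a,b,expected",
    [(350.0, 10.0, 20.0), (90.0, 270.0, 180.0), (-170.0, 170.0, 20.0), (5.0, 5.0, 0.0)],
)
def test_angle_diff_examples(a, b, expected):
    assert angle_diff(a, b).delta == pytest.approx(expected, abs=1e-12)


@settings(derandomize=True, max_examples=200, deadline=None)
@given(st.floats(-720.0, 720.0), st.floats(-720.0, 720.0))
def test_angle_diff_matches_brute_force_and_is_symmetric(a, b):
    got = angle_diff(a, b).delta
    assert got == pytest.approx(helpers.circular_diff_oracle(a, b), abs=1e-9)
    assert got == pytest.approx(angle_diff(b, a).delta, abs=1e-12)
    assert 0.0 <= got <= 180.0


def test_angle_diff_undefined_propagates():
    assert not angle_diff(float("nan"), 10.0).defined
    assert not angle_diff(10.0, float("nan")).defined


def test_mcq_constant_sets_and_quadrant_rule():
    assert mcq([30.0, 30.0, 30.0]).degrees == pytest.approx(30.0, abs=1e-9)
    # Above 90° a plain arctangent would fold 170° to -10°.
    assert mcq([170.0, 170.0]).degrees == pytest.approx(170.0, abs=1e-9)
    assert mcq([0.0, 90.0]).degrees == pytest.approx(45.0, abs=1e-9)
    assert mcq([10.0, float("nan"), 20.0]).n_terms == 2
    assert not mcq([float("nan")]).defined


def test_pair_residues_examples_and_oracle():
    pairs = pair_residues("ACGU", "AGU")
    assert [("ACGU"[i], "AGU"[j]) for i, j in pairs] == [("A", "A"), ("G", "G"), ("U", "U")]
    assert len(pair_residues("ACGT", "TGCA")) == helpers.lcs_length_oracle("ACGT", "TGCA") == 1
    assert pair_residues("GCAU", "GCAU") == [(i, i) for i in range(4)]
    assert pair_residues("AAAA", "GGGG") == []
    # Case-insensitive: modified residues carry lowercase parent letters.
    assert len(pair_residues("acgu", "ACGU")) == 4


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.text(alphabet="ACGU", min_size=1, max_size=7),
       st.text(alphabet="ACGU", min_size=1, max_size=7))
def test_pair_residues_is_maximal_and_increasing(s, t):
    pairs = pair_residues(s, t)
    assert len(pairs) == helpers.lcs_length_oracle(s, t)
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        assert i1 < i2 and j1 < j2
    for i, j in pairs:
        assert s[i] == t[j]


def test_per_residue_mcq_and_severity():
    kinds = (AngleKind.alpha, AngleKind.gamma)
    target = torsions_from_matrix([[10.0, 20.0], [0.0, 0.0], [50.0, 50.0]], kinds)
    model = torsions_from_matrix([[20.0, 50.0], [0.0, 0.0], [130.0, 130.0]], kinds)
    pairing = [(0, 0), (1, 1), (2, 2)]
    rows = per_residue_mcq(target, model, pairing, kinds)
    assert rows[0].mcq.degrees == pytest.approx(helpers.mcq_oracle([10.0, 30.0]))
    assert rows[0].severity == "15-30"
    assert rows[1].mcq.degrees == pytest.approx(0.0, abs=1e-12)
    assert rows[1].severity == "0-15"
    assert rows[2].mcq.degrees == pytest.approx(80.0, abs=1e-9)
    assert rows[2].severity == ">60"


def test_per_residue_mcq_reports_unpaired_targets():
    kinds = (AngleKind.gamma,)
    target = torsions_from_matrix([[10.0], [20.0], [30.0]], kinds)
    model = torsions_from_matrix([[10.0]], kinds)
    rows = per_residue_mcq(target, model, [(1, 0)], kinds)
    assert [r.mcq.defined for r in rows] == [False, True, False]
    assert rows[0].severity is None and rows[0].model_position is None


def test_global_mcq_pools_rather_than_averages():
    kinds = (AngleKind.alpha, AngleKind.gamma)
    target = torsions_from_matrix([[0.0, 0.0], [0.0, 0.0]], kinds)
    model = torsions_from_matrix([[10.0, 20.0], [30.0, 40.0]], kinds)
    pairing = [(0, 0), (1, 1)]
    g = global_mcq(target, model, pairing, kinds)
    assert g.degrees == pytest.approx(helpers.mcq_oracle([10.0, 20.0, 30.0, 40.0]))
    assert g.n_terms == 4
    # Symmetry
    assert g.degrees == pytest.approx(
        global_mcq(model, target, pairing, kinds).degrees, abs=1e-12
    )
    assert not global_mcq(target, model, [], kinds).defined


def test_coverage_fractions():
    kinds = (AngleKind.gamma,)
    values = [[10.0], [20.0], [40.0], [70.0]]
    target = torsions_from_matrix([[0.0]] * 4, kinds)
    model = torsions_from_matrix(values, kinds)
    rows = per_residue_mcq(target, model, [(i, i) for i in range(4)], kinds)
    fracs, n = coverage_fractions(rows)
    assert fracs == pytest.approx([0.25, 0.5, 0.75]) and n == 4
    zero = per_residue_mcq(target, target, [(i, i) for i in range(4)], kinds)
    assert coverage_fractions(zero)[0] == pytest.approx([1.0, 1.0, 1.0])
    empty, n0 = coverage_fractions([])
    assert n0 == 0 and all(math.isnan(f) for f in empty)


def test_severity_bins_partition_the_range():
    edges = [b[0] for b in SEVERITY_BINS] + [180.0]
    assert edges == [0.0, 15.0, 30.0, 60.0, 180.0]
    for value, label in [(0.0, "0-15"), (14.999, "0-15"), (15.0, "15-30"),
                         (30.0, "30-60"), (60.0, ">60"), (180.0, ">60")]:
        assert severity_bin(value) == label
    assert severity_bin(float("nan")) is None


def test_selection_validation():
    kinds = (AngleKind.gamma,)
    t = torsions_from_matrix([[0.0]], kinds)
    with pytest.raises(ConfigError):
        global_mcq(t, t, [(0, 0)], ())
    with pytest.raises(ConfigError):
        global_mcq(t, t, [(0, 0)], (AngleKind.pseudorotation,))


# ---------------------------------------------------------------------------
# LCS-TA

def _segment_inputs(target, model, pairing, sel):
    from tango.comparison import _pair_sums

    s, c, n = _pair_sums(target, model, pairing, sel)
    runs = []
    start = 0
    for idx in range(1, len(pairing)):
        tp, mp = pairing[idx - 1]
        tc, mc = pairing[idx]
        if tc != tp + 1 or mc != mp + 1:
            runs.append((start, idx))
            start = idx
    if pairing:
        runs.append((start, len(pairing)))
    return s, c, n, runs


def test_lcs_ta_identical_structures_cover_full_range():
    kinds = (AngleKind.gamma,)
    t = torsions_from_matrix([[v] for v in range(10)], kinds)
    seg = lcs_ta(t, t, [(i, i) for i in range(10)], kinds, threshold=1.0)
    assert (seg.target_start, seg.model_start, seg.length) == (0, 0, 10)
    assert seg.mcq.degrees == pytest.approx(0.0, abs=1e-12)


def test_lcs_ta_corrupted_residue_splits_segment():
    # One residue shifted by 90°; the pooled MCQ of any window containing it
    # is atan2(1, L-1), which exceeds a 5° threshold for every feasible
    # window length here, so the best segment is the clean 5-residue prefix
    # (leftmost tie rule beats the 4-residue suffix).
    kinds = (AngleKind.gamma,)
    base = [[10.0]] * 10
    target = torsions_from_matrix(base, kinds)
    corrupted = [row.copy() for row in base]
    corrupted[5] = [100.0]
    model = torsions_from_matrix(corrupted, kinds)
    pairing = [(i, i) for i in range(10)]
    seg = lcs_ta(target, model, pairing, kinds, threshold=5.0)
    assert seg.length == 5
    assert seg.target_start == 0


def test_lcs_ta_threshold_180_covers_everything():
    kinds = (AngleKind.gamma,)
    rngv = np.random.default_rng(5)
    target = torsions_from_matrix([[v] for v in rngv.uniform(-180, 180, 12)], kinds)
    model = torsions_from_matrix([[v] for v in rngv.uniform(-180, 180, 12)], kinds)
    pairing = [(i, i) for i in range(12)]
    seg = lcs_ta(target, model, pairing, kinds, threshold=180.0)
    assert seg.length == 12


def test_lcs_ta_no_residue_under_threshold():
    kinds = (AngleKind.gamma,)
    target = torsions_from_matrix([[0.0]] * 3, kinds)
    model = torsions_from_matrix([[170.0]] * 3, kinds)
    seg = lcs_ta(target, model, [(i, i) for i in range(3)], kinds, threshold=5.0)
    assert seg.length == 0 and seg.target_start is None and not seg.mcq.defined


def test_lcs_ta_respects_run_boundaries():
    kinds = (AngleKind.gamma,)
    target = torsions_from_matrix([[0.0]] * 6, kinds)
    model = torsions_from_matrix([[0.0]] * 6, kinds)
    # Pairing jumps between positions 2 and 3 in the model.
    pairing = [(0, 0), (1, 1), (2, 2), (3, 5)]
    seg = lcs_ta(target, model, pairing, kinds, threshold=15.0)
    assert seg.length == 3  # run [0, 3)


def test_lcs_ta_matches_exhaustive_oracle_on_random_instances(rng):
    kinds = (AngleKind.alpha, AngleKind.gamma, AngleKind.chi)
    for _ in range(40):
        n = int(rng.integers(2, 31))
        target = torsions_from_matrix(rng.uniform(-180, 180, size=(n, 3)), kinds)
        model = torsions_from_matrix(rng.uniform(-180, 180, size=(n, 3)), kinds)
        pairing = [(i, i) for i in range(n)]
        threshold = float(rng.uniform(5.0, 170.0))
        seg = lcs_ta(target, model, pairing, kinds, threshold=threshold)
        s, c, cnt, runs = _segment_inputs(target, model, pairing, kinds)
        length, value, _ = helpers.lcs_ta_oracle(s, c, cnt, runs, threshold)
        assert seg.length == length
        if length:
            assert seg.mcq.degrees <= threshold + 1e-9


def test_lcs_ta_length_monotone_in_threshold(rng):
    kinds = (AngleKind.gamma,)
    n = 20
    target = torsions_from_matrix(rng.uniform(-180, 180, size=(n, 1)), kinds)
    model = torsions_from_matrix(rng.uniform(-180, 180, size=(n, 1)), kinds)
    pairing = [(i, i) for i in range(n)]
    lengths = [
        lcs_ta(target, model, pairing, kinds, threshold=t).length
        for t in (5.0, 15.0, 30.0, 60.0, 120.0, 180.0)
    ]
    assert lengths == sorted(lengths)
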