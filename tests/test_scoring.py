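"""Assembly scores: TS-score terms, Symmetric Index, constraint function, decision."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from domex.library import Source
from domex.scoring import (
    Reason,
    Thresholds,
    coverage_factor,
    decide,
    length_error,
    normalized_evalue,
    si_cutoff,
    symmetric_index,
    ts_score,
)
from domex.search import TemplateHit
from domex.segments import AssembledCandidate, Segment


@pytest.mark.parametrize(
    "evalue, expected",
    [(0.001, 0.3), (1e-10, 1.0), (1e-12, 1.0), (1.0, 0.0), (5.0, 0.0)],
)
def test_normalized_evalue(evalue, expected):
    assert normalized_evalue(evalue) == pytest.approx(expected)


def test_normalized_evalue_rejects_nonpositive():
    with pytest.raises(ValueError):
        normalized_evalue(0.0)


@pytest.mark.parametrize(
    "c, expected",
    [(0.30, 0.0), (1 / 3, 0.0), (1.0, 0.969697), (2 / 3, 0.5), (0.0, 0.0)],
)
def test_coverage_factor(c, expected):
    assert coverage_factor(c) == pytest.approx(expected, abs=1e-6)


def test_coverage_factor_rejects_out_of_range():
    with pytest.raises(ValueError):
        coverage_factor(1.2)


@pytest.mark.parametrize(
    "s, h, l, expected",
    [(1, 1, 1, 1.0), (0.5, 1.0, 0.969697, 0.484848), (0.9, 0.7, 0.0, 0.0)],
)
def test_ts_score_product(s, h, l, expected):
    assert ts_score(s, h, l) == pytest.approx(expected, abs=1e-6)


@pytest.mark.parametrize(
    "v_p, v_q, expected",
    [
        ((0.7, 0.9), (0.7, 0.9), 0.0),
        ((1, 1), (0, 0), math.sqrt(2)),
        ((0.4, 0.8), (0.1, 0.4), 0.5),
    ],
)
def test_symmetric_index(v_p, v_q, expected):
    assert symmetric_index(v_p, v_q) == pytest.approx(expected, abs=1e-6)


@pytest.mark.parametrize(
    "lq, lt, expected", [(100, 100, 0.0), (100, 115, 0.15), (100, 125, 0.25)]
)
def test_length_error(lq, lt, expected):
    assert length_error(lq, lt) == pytest.approx(expected)


@pytest.mark.parametrize(
    "t_ts, b, expected",
    [
        (0.30, 0.4, 0.2),   # the ramp piece of the constraint, worked value
        (0.10, 0.4, 0.0),   # below b/2: assembly never accepted
        (0.90, 0.4, 0.3),   # high-TS plateau
        (0.18, 0.3, 0.1),   # low plateau just above b/2
        (0.30, 0.3, 0.3),   # breakpoint 0.15 + b/2: ramp and plateau agree by continuity
    ],
)
def test_si_cutoff_pieces(t_ts, b, expected):
    assert si_cutoff(t_ts, b) == pytest.approx(expected)


def test_si_cutoff_rejects_bad_b():
    for b in (0.0, 1.0, -0.2):
        with pytest.raises(ValueError):
            si_cutoff(0.3, b)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.floats(min_value=0.0, max_value=1.5),
    st.floats(min_value=0.01, max_value=0.99),
)
def test_si_cutoff_range_property(t_ts, b):
    v = si_cutoff(t_ts, b)
    assert v == 0.0 or 0.1 <= v <= 0.3


def test_si_cutoff_monotone_on_dense_grid():
    ts_grid = np.linspace(0.0, 1.2, 241)
    b_grid = np.linspace(0.05, 0.95, 91)
    for b in b_grid:
        vals = [si_cutoff(t, b) for t in ts_grid]
        assert all(v2 >= v1 for v1, v2 in zip(vals, vals[1:]))
    for t in ts_grid:
        vals = [si_cutoff(t, b) for b in b_grid]
        assert all(v2 <= v1 for v1, v2 in zip(vals, vals[1:]))


def _candidate(len_a=50, len_b=50):
    a = "A" * len_a
    b = "L" * len_b
    s1 = Segment(index=1, start=1, end=len_a, sequence=a)
    s2 = Segment(index=3, start=len_a + 11, end=len_a + 10 + len_b, sequence=b)
    return AssembledCandidate(first=s1, second=s2)


def _hit(s=0.309375, evalue=1e-12, c=1.0, per_segment=((0.95, 1.0), (0.8, 1.0)),
         template_length=110, source=Source.STRUCTURE, template_id="cath|t0",
         ppa_score=None):
    """Default values give TS-score 0.30, SI 0.15, e 0.1 for a 100-residue candidate."""
    hit = TemplateHit(
        template_id=template_id, source=source, evalue=evalue, raw_score=60.0,
        template_length=template_length, columns=(), per_segment=per_segment,
    )
    hit.s, hit.c, hit.ppa_score = s, c, ppa_score
    return hit


def test_worked_example_hit_is_accepted_as_discontinuous():
    # TS-score 0.30 >= the cutoff, SI 0.15 <= f(0.30, 0.4) = 0.2, e = 0.1 < 0.2
    cand = _candidate()
    d = decide(cand, [_hit()], Thresholds(b=0.4))
    assert d.accepted and d.reason is Reason.ACCEPTED
    assert d.scores.ts_score == pytest.approx(0.30, abs=1e-6)
    assert d.scores.si == pytest.approx(0.15, abs=1e-9)
    assert d.scores.e == pytest.approx(0.1)


def test_no_hits_yields_no_hit_reason():
    d = decide(_candidate(), [], Thresholds(b=0.4))
    assert not d.accepted and d.reason is Reason.NO_HIT and d.winning_hit is None


def test_excess_length_error_rejects_with_length_reason():
    d = decide(_candidate(), [_hit(template_length=125)], Thresholds(b=0.4))
    assert not d.accepted and d.reason is Reason.LENGTH_ERROR


def test_asymmetric_hit_rejected_by_si():
    hit = _hit(per_segment=((1.0, 1.0), (0.2, 0.4)))
    d = decide(_candidate(), [hit], Thresholds(b=0.4))
    assert not d.accepted and d.reason is Reason.TS_SI_FAIL


def test_sequence_source_hit_requires_good_ppa_below_b_half():
    bad = _hit(source=Source.SEQUENCE, template_id="pfam|t0", ppa_score=-0.5)
    good = _hit(source=Source.SEQUENCE, template_id="pfam|t1", ppa_score=-2.5)
    th = Thresholds(b=0.4)
    assert not decide(_candidate(), [bad], th).accepted
    assert decide(_candidate(), [bad], th).reason is Reason.PPA_FAIL
    assert decide(_candidate(), [good], th).accepted
    # ... but the PPA filter does not apply at high b
    strong_bad = _hit(s=0.9, source=Source.SEQUENCE, template_id="pfam|t2", ppa_score=-0.5)
    assert decide(_candidate(), [strong_bad], Thresholds(b=0.6)).accepted


def test_lowest_ppa_score_wins_among_passing_hits():
    h1 = _hit(source=Source.SEQUENCE, template_id="pfam|a", ppa_score=-2.0)
    h2 = _hit(source=Source.SEQUENCE, template_id="pfam|b", ppa_score=-2.5)
    d = decide(_candidate(), [h1, h2], Thresholds(b=0.4))
    assert d.winning_hit.template_id == "pfam|b"


def test_decide_invariant_to_hit_ordering():
    hits = [
        _hit(template_id="cath|x", s=0.35),
        _hit(source=Source.SEQUENCE, template_id="pfam|y", ppa_score=-2.2),
        _hit(template_id="cath|z", evalue=1e-8),
    ]
    th = Thresholds(b=0.4)
    outcomes = set()
    for perm in itertools.permutations(hits):
        d = decide(_candidate(), list(perm), th)
        outcomes.add((d.accepted, d.winning_hit.template_id if d.winning_hit else None))
    assert len(outcomes) == 1


def test_acceptance_is_monotone_in_scores():
    base = _hit()
    th = Thresholds(b=0.4)
    assert decide(_candidate(), [base], th).accepted
    # raising identity (hence TS-score), lowering SI asymmetry, or a closer
    # template length can never flip acceptance to rejection
    better = [
        _hit(s=0.5),
        _hit(per_segment=((0.9, 1.0), (0.85, 1.0))),
        _hit(template_length=100),
        _hit(evalue=1e-15),
    ]
    for hit in better:
        assert decide(_candidate(), [hit], th).accepted


def test_strict_inequality_flag_flips_si_boundary():
    # values chosen exactly representable: ts = 0.1328125 at b = 0.015625
    # gives SI cutoff 2*ts - b = 0.25, and the hit's SI is exactly 0.25;
    # equality passes the default (<=) reading but fails the strict (<) one
    hit = _hit(s=0.136962890625, per_segment=((1.0, 1.0), (1.0, 0.75)))
    assert decide(_candidate(), [hit], Thresholds(b=0.015625)).accepted
    assert not decide(
        _candidate(), [hit], Thresholds(b=0.015625, strict_inequalities=True)
    ).accepted
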