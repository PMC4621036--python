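"""Sample construction, metrics, NDO overlap score, and calibration sweeps."""

import numpy as np
import pytest

from domex.evaluation import (
    ChainAnnotation,
    EvalCounts,
    Label,
    ScoredSample,
    best_est_cells,
    calibrate_ecv,
    calibrate_est,
    calibrate_pct,
    generate_samples,
    metrics,
    ndo_score,
    parse_ranges,
    read_annotations_tsv,
    write_annotations_tsv,
)
from domex.library import Source
from domex.pipeline import DomainPrediction


def _chain(chain_id, seg_lengths, discontinuous_pairs=()):
    """Annotated chain with given segment lengths; listed pairs (1-based
    segment ordinals) form discontinuous domains, the rest are singletons."""
    seq = "".join("ACDEFGHIKLMNPQRSTVWY"[i % 20] for i in range(sum(seg_lengths)))
    starts = np.cumsum([1, *seg_lengths[:-1]])
    ranges = [(int(s), int(s + L - 1)) for s, L in zip(starts, seg_lengths)]
    in_pair = {i for pair in discontinuous_pairs for i in pair}
    domains = [tuple(ranges[i - 1] for i in pair) for pair in discontinuous_pairs]
    domains += [(r,) for i, r in enumerate(ranges, start=1) if i not in in_pair]
    return ChainAnnotation(chain_id=chain_id, sequence=seq, domains=tuple(domains))


def test_fig4_style_chain_yields_one_positive_two_negatives():
    # segments A1, B, A2, C where (A1, A2) is the true discontinuous domain
    chain = _chain("c", [50, 45, 60, 55], discontinuous_pairs=[(1, 3)])
    samples = generate_samples([chain])
    by_pair = {s.candidate.segment_indices: s.label for s in samples}
    assert by_pair == {
        (1, 3): Label.POSITIVE,
        (1, 4): Label.NEGATIVE,
        (2, 4): Label.NEGATIVE,
    }


def test_all_continuous_chain_yields_only_negatives():
    chain = _chain("c", [50, 45, 60])
    samples = generate_samples([chain])
    assert [(s.candidate.segment_indices, s.label) for s in samples] == [
        ((1, 3), Label.NEGATIVE)
    ]


def test_short_segments_excluded_from_sampling():
    chain = _chain("c", [50, 45, 30], discontinuous_pairs=[(1, 3)])
    assert generate_samples([chain], min_len=40) == []


def test_two_segment_chain_skipped_with_warning():
    chain = _chain("c", [50, 60])
    with pytest.warns(UserWarning, match="fewer than 3"):
        assert generate_samples([chain]) == []


@pytest.mark.parametrize(
    "counts, expected",
    [
        (EvalCounts(TP=10, FN=0, FP=0, TN=10), (1.0, 1.0, 1.0)),
        (EvalCounts(TP=5, FN=5, FP=5, TN=5), (0.5, 0.5, 0.0)),
    ],
)
def test_metrics_formulas(counts, expected):
    assert metrics(counts) == pytest.approx(expected)


def test_metrics_undefined_denominator_gives_nan_with_warning():
    with pytest.warns(UserWarning, match="precision"):
        recall, precision, mcc = metrics(EvalCounts(TP=0, FP=0, TN=5, FN=5))
    assert np.isnan(precision)


def _prediction(chain_id, length, domains):
    return DomainPrediction(
        chain_id=chain_id, chain_length=length,
        domains=[list(d) for d in domains],
        discontinuous_flags=[len(d) > 1 for d in domains],
        provenance=[None] * len(domains),
    )


def test_ndo_identical_partitions_score_one():
    ref = _prediction("c", 100, [[(1, 40), (81, 100)], [(41, 80)]])
    assert ndo_score(ref, ref) == pytest.approx(1.0)


def test_ndo_split_domain_scores_half():
    ref = _prediction("c", 100, [[(1, 100)]])
    pred = _prediction("c", 100, [[(1, 50)], [(51, 100)]])
    assert ndo_score(pred, ref) == pytest.approx(0.5)


def test_ndo_best_matching_oracle_value():
    # best one-to-one matching covers 60 + 0 of 100 residues... construct:
    # pred domains (1-60)(61-100); ref (1-30|61-90)(31-60)(91-100):
    # overlap matrix [[30,30],[30,10]] -> best assignment 30+30 = 60
    pred = _prediction("c", 100, [[(1, 60)], [(61, 100)]])
    ref = _prediction("c", 100, [[(1, 30), (61, 90)], [(31, 60)], [(91, 100)]])
    assert ndo_score(pred, ref) == pytest.approx(0.6)


def test_ndo_symmetric_for_full_partitions():
    a = _prediction("c", 120, [[(1, 50), (91, 120)], [(51, 90)]])
    b = _prediction("c", 120, [[(1, 60)], [(61, 120)]])
    assert ndo_score(a, b) == pytest.approx(ndo_score(b, a))


def test_ndo_length_mismatch_is_error():
    with pytest.raises(ValueError):
        ndo_score(_prediction("c", 100, [[(1, 100)]]), _prediction("c", 90, [[(1, 90)]]))


def _separable_samples():
    pos = [ScoredSample(label=Label.POSITIVE, ts=0.9, si=0.05, e=0.1)] * 20
    neg = [ScoredSample(label=Label.NEGATIVE, ts=0.1, si=0.4, e=0.1)] * 40
    return pos + neg


def test_est_grid_dimensions_and_separable_maximum():
    grid = calibrate_est(_separable_samples())
    assert len(grid) == 19 * 10
    assert sorted(grid["t_ts"].unique()) == pytest.approx(list(np.arange(0.10, 1.0001, 0.05)))
    assert sorted(grid["t_si"].unique()) == pytest.approx(list(np.arange(0.05, 0.5001, 0.05)))
    best = best_est_cells(grid)
    assert best["mcc"].iloc[0] == pytest.approx(1.0)
    # e.g. (0.5, 0.2) separates the planted clusters perfectly
    cell = grid[(grid.t_ts == 0.5) & (grid.t_si == 0.2)].iloc[0]
    assert cell["mcc"] == pytest.approx(1.0)


def test_est_degenerate_identical_scores():
    samples = [
        ScoredSample(label=Label.POSITIVE, ts=0.5, si=0.1, e=0.1),
        ScoredSample(label=Label.NEGATIVE, ts=0.5, si=0.1, e=0.1),
    ]
    grid = calibrate_est(samples)
    assert ((grid["mcc"] == 0) | grid["mcc"].isna()).all()


def test_ecv_runs_decision_over_b_grid():
    grid = calibrate_ecv(_separable_samples())
    assert list(grid["b"]) == pytest.approx(list(np.arange(0.1, 0.9001, 0.1)))
    # positives (ts 0.9, si 0.05) pass at every b; negatives never do
    assert (grid["recall"] == 1.0).all()
    assert (grid["precision"] == 1.0).all()


def test_pct_sweep_picks_most_permissive_separating_cutoff():
    pos = [ScoredSample(label=Label.POSITIVE, ts=0.9, si=0.05, e=0.1,
                        ppa=-3.5, source=Source.SEQUENCE)] * 10
    neg = [ScoredSample(label=Label.NEGATIVE, ts=0.9, si=0.05, e=0.1,
                        ppa=-0.5, source=Source.SEQUENCE)] * 10
    grid = calibrate_pct(pos + neg, b_values=[0.3])
    row = grid.iloc[0]
    # any cutoff in [-3.4, -0.5] separates; the most permissive one is reported
    assert row["t_ppa"] == pytest.approx(-0.5)
    assert row["mcc"] == pytest.approx(1.0)


def test_pct_evaluates_51_cutoffs_and_degenerates_without_sequence_hits():
    ppa_grid = np.round(np.arange(0.0, -5.0001, -0.1), 10)
    assert len(ppa_grid) == 51
    pos = [ScoredSample(label=Label.POSITIVE, ts=0.9, si=0.05, e=0.1,
                        source=Source.STRUCTURE)] * 5
    neg = [ScoredSample(label=Label.NEGATIVE, ts=0.1, si=0.4, e=0.1,
                        source=Source.STRUCTURE)] * 5
    grid = calibrate_pct(pos + neg, b_values=[0.3])
    # the PPA filter is a no-op for structure-only hits: cutoff 0.0 already maximal
    assert grid.iloc[0]["t_ppa"] == 0.0
    assert grid.iloc[0]["mcc"] == pytest.approx(1.0)


def test_annotation_tsv_roundtrip(tmp_path):
    chain = _chain("c1", [50, 45, 60], discontinuous_pairs=[(1, 3)])
    path = tmp_path / "ann.tsv"
    write_annotations_tsv([chain], path)
    back = read_annotations_tsv(path, {"c1": chain.sequence})
    assert back == [chain]


def test_parse_ranges_accepts_cath_notation():
    assert parse_ranges("1-156|342-393") == ((1, 156), (342, 393))
    assert parse_ranges("1–156,342–393") == ((1, 156), (342, 393))  # en-dash
    with pytest.raises(ValueError):
        parse_ranges("x-10")
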