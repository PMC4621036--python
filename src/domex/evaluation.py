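"""Sample construction, classification metrics, domain-overlap score, calibration.

Labeled samples come from chains with known domain annotations: every
non-adjacent segment pair is a sample, positive iff the two segments form
one annotated (discontinuous) domain; adjacent pairs are never assembled
and reversed pairs are included only on request.  Recall, precision and the
Matthews correlation coefficient summarize detection performance; the
NDO score measures residue-level overlap between a predicted and a
reference domain partition.  The calibration sweeps reproduce the
three-stage training protocol: an exhaustive (T_TS, T_SI) grid search, the
one-parameter constraint validation over b, and the PPA-cutoff sweep.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .library import Source
from .pipeline import DomainPrediction
from .scoring import si_cutoff
from .segments import DEFAULT_MIN_SEGMENT_LEN, AssembledCandidate, Segment, enumerate_candidates


class Label(Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


@dataclass(frozen=True)
class ChainAnnotation:
    """Known domain partition of one chain (ranges 1-based inclusive)."""

    chain_id: str
    sequence: str
    domains: tuple[tuple[tuple[int, int], ...], ...]

    @property
    def segments(self) -> list[Segment]:
        ranges = sorted(r for dom in self.domains for r in dom)
        return [
            Segment(index=i, start=s, end=e, sequence=self.sequence[s - 1 : e])
            for i, (s, e) in enumerate(ranges, start=1)
        ]

    @property
    def discontinuous_domains(self) -> list[tuple[tuple[int, int], ...]]:
        return [dom for dom in self.domains if len(dom) == 2]


@dataclass(frozen=True)
class LabeledSample:
    candidate: AssembledCandidate
    label: Label
    origin_chain: str


@dataclass(frozen=True)
class EvalCounts:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("counts must be non-negative")


def generate_samples(
    chains: Iterable[ChainAnnotation],
    min_len: int = DEFAULT_MIN_SEGMENT_LEN,
    include_reversed: bool = False,
) -> list[LabeledSample]:
    """Label every assemblable segment pair of every annotated chain.

    A pair is positive iff its two segments are exactly the two ranges of
    one annotated discontinuous domain.  Chains with fewer than three
    segments carry no non-adjacent pair and are skipped with a warning.
    """
    samples: list[LabeledSample] = []
    for chain in chains:
        segments = chain.segments
        if len(segments) < 3:
            warnings.warn(f"chain {chain.chain_id}: fewer than 3 segments, skipped")
            continue
        true_pairs = {
            frozenset(dom) for dom in chain.discontinuous_domains
        }
        for cand in enumerate_candidates(segments, min_len=min_len, allow_reversed=include_reversed):
            pair = frozenset(
                ((cand.first.start, cand.first.end), (cand.second.start, cand.second.end))
            )
            label = Label.POSITIVE if pair in true_pairs else Label.NEGATIVE
            samples.append(LabeledSample(candidate=cand, label=label, origin_chain=chain.chain_id))
    return samples


def metrics(counts: EvalCounts) -> tuple[float, float, float]:
    """(recall, precision, MCC); a zero denominator yields NaN with a warning."""
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    recall = tp / (tp + fn) if tp + fn else _undef("recall")
    precision = tp / (tp + fp) if tp + fp else _undef("precision")
    denom = (tp + fp) * (tp + fn) * (fp + tn) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else _undef("MCC")
    return recall, precision, mcc


def _undef(name: str) -> float:
    warnings.warn(f"{name} undefined (zero denominator)")
    return float("nan")


def ndo_score(predicted: DomainPrediction, reference: DomainPrediction) -> float:
    """Normalized domain-overlap between two partitions of the same chain.

    The best one-to-one matching between predicted and reference domains
    (maximizing summed residue overlap) is found by assignment; the score
    is matched overlap divided by chain length, so identical partitions
    score 1.
    """
    if predicted.chain_length != reference.chain_length:
        raise ValueError("predictions are for chains of different lengths")

    def residue_sets(p: DomainPrediction) -> list[set[int]]:
        return [
            {r for s, e in dom for r in range(s, e + 1)} for dom in p.domains
        ]

    pred_sets = residue_sets(predicted)
    ref_sets = residue_sets(reference)
    overlap = np.zeros((len(pred_sets), len(ref_sets)))
    for i, ps in enumerate(pred_sets):
        for j, rs in enumerate(ref_sets):
            overlap[i, j] = len(ps & rs)
    rows, cols = linear_sum_assignment(overlap, maximize=True)
    return float(overlap[rows, cols].sum() / predicted.chain_length)


@dataclass(frozen=True)
class ScoredSample:
    """One labeled sample with its best-hit scores (None = no hit)."""

    label: Label
    ts: float | None = None
    si: float | None = None
    e: float | None = None
    ppa: float | None = None
    source: Source | None = None


def _counts(
    samples: Sequence[ScoredSample], predicted: Sequence[bool]
) -> EvalCounts:
    tp = fp = tn = fn = 0
    for s, p in zip(samples, predicted):
        if s.label is Label.POSITIVE:
            tp, fn = tp + int(p), fn + int(not p)
        else:
            fp, tn = fp + int(p), tn + int(not p)
    return EvalCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def _predict_est(s: ScoredSample, t_ts: float, t_si: float, e_max: float) -> bool:
    if s.ts is None:
        return False
    return s.e < e_max and s.ts >= t_ts and s.si <= t_si


def calibrate_est(
    samples: Sequence[ScoredSample],
    t_ts_grid: Sequence[float] | None = None,
    t_si_grid: Sequence[float] | None = None,
    e_max: float = 0.2,
) -> pd.DataFrame:
    """Exhaustive (T_TS, T_SI) grid search over cached sample scores.

    Defaults sweep T_TS over [0.1, 1] and T_SI over [0.05, 0.5], both with
    step 0.05 (a 19 x 10 grid).  Returns one row per cell with recall,
    precision and MCC.
    """
    if t_ts_grid is None:
        t_ts_grid = np.round(np.arange(0.10, 1.0001, 0.05), 10)
    if t_si_grid is None:
        t_si_grid = np.round(np.arange(0.05, 0.5001, 0.05), 10)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for t_ts in t_ts_grid:
            for t_si in t_si_grid:
                counts = _counts(samples, [_predict_est(s, t_ts, t_si, e_max) for s in samples])
                recall, precision, mcc = metrics(counts)
                rows.append(
                    dict(t_ts=t_ts, t_si=t_si, recall=recall, precision=precision, mcc=mcc)
                )
    return pd.DataFrame(rows)


def best_est_cells(grid: pd.DataFrame) -> pd.DataFrame:
    """All grid cells achieving the maximum MCC."""
    best = grid["mcc"].max()
    return grid[grid["mcc"] == best].reset_index(drop=True)


def _predict_constraint(
    s: ScoredSample, b: float, e_max: float, t_ppa: float | None
) -> bool:
    if s.ts is None:
        return False
    if not (s.e < e_max and s.ts > b / 2.0 and s.si <= si_cutoff(s.ts, b)):
        return False
    if t_ppa is not None and s.source is Source.SEQUENCE and s.ppa is not None:
        return s.ppa < t_ppa
    return True


def calibrate_ecv(
    samples: Sequence[ScoredSample],
    b_values: Sequence[float] | None = None,
    e_max: float = 0.2,
) -> pd.DataFrame:
    """Constraint-function validation: the standard decision over a b grid."""
    if b_values is None:
        b_values = np.round(np.arange(0.1, 0.9001, 0.1), 10)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for b in b_values:
            counts = _counts(samples, [_predict_constraint(s, b, e_max, None) for s in samples])
            recall, precision, mcc = metrics(counts)
            rows.append(dict(b=b, recall=recall, precision=precision, mcc=mcc))
    return pd.DataFrame(rows)


def calibrate_pct(
    samples: Sequence[ScoredSample],
    b_values: Sequence[float] | None = None,
    ppa_grid: Sequence[float] | None = None,
    e_max: float = 0.2,
) -> pd.DataFrame:
    """Per-b sweep of the PPA cutoff, 0.0 down to -5.0 in steps of -0.1.

    For each b the cutoff maximizing MCC is reported; among ties the most
    permissive (largest) cutoff wins.  Sequence-source samples without a
    PPA score pass the filter unchanged.
    """
    if b_values is None:
        b_values = np.round(np.arange(0.9, 0.0999, -0.1), 10)
    if ppa_grid is None:
        ppa_grid = np.round(np.arange(0.0, -5.0001, -0.1), 10)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for b in b_values:
            best = None
            for t_ppa in ppa_grid:
                counts = _counts(
                    samples, [_predict_constraint(s, b, e_max, t_ppa) for s in samples]
                )
                recall, precision, mcc = metrics(counts)
                mcc_key = -np.inf if np.isnan(mcc) else mcc
                # strict > keeps the most permissive cutoff among ties
                if best is None or mcc_key > best[0]:
                    best = (mcc_key, t_ppa, recall, precision, mcc)
            rows.append(
                dict(b=b, t_ppa=best[1], recall=best[2], precision=best[3], mcc=best[4])
            )
    return pd.DataFrame(rows)


def count_discontinuous_detections(
    predictions: Sequence[DomainPrediction],
    annotations: Sequence[ChainAnnotation],
    min_len: int = DEFAULT_MIN_SEGMENT_LEN,
) -> EvalCounts:
    """Sample-level confusion counts for discontinuous-domain calls.

    A predicted discontinuous domain is a true positive iff its two ranges
    equal an annotated discontinuous domain; annotated domains never called
    are false negatives; callable negative pairs never called are true
    negatives.
    """
    ann_by_id = {a.chain_id: a for a in annotations}
    tp = fp = fn = tn = 0
    for pred in predictions:
        ann = ann_by_id[pred.chain_id]
        true_pairs = {frozenset(dom) for dom in ann.discontinuous_domains}
        called = {
            frozenset(map(tuple, dom))
            for dom, flag in zip(pred.domains, pred.discontinuous_flags)
            if flag
        }
        n_negative_pairs = sum(
            1
            for s in generate_samples([ann], min_len=min_len)
            if s.label is Label.NEGATIVE
        )
        tp_chain = len(called & true_pairs)
        fp_chain = len(called - true_pairs)
        tp += tp_chain
        fp += fp_chain
        fn += len(true_pairs - called)
        tn += max(n_negative_pairs - fp_chain, 0)
    return EvalCounts(TP=tp, FP=fp, TN=tn, FN=fn)


_RANGE_RE = re.compile(r"(\d+)\s*[-–]\s*(\d+)")


def parse_ranges(text: str) -> tuple[tuple[int, int], ...]:
    """Parse '1-156|342-393' (also en-dash or comma separated) into ranges."""
    parts = re.split(r"[|,]", text.strip())
    ranges = []
    for part in parts:
        m = _RANGE_RE.fullmatch(part.strip())
        if not m:
            raise ValueError(f"bad range {part!r} in {text!r}")
        ranges.append((int(m.group(1)), int(m.group(2))))
    return tuple(ranges)


def read_annotations_tsv(path: str | Path, sequences: dict[str, str]) -> list[ChainAnnotation]:
    """Read a domain-annotation TSV (chain_id, domain_id, ranges)."""
    doms: dict[str, dict[str, tuple[tuple[int, int], ...]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("chain_id"):
                continue
            chain_id, domain_id, ranges = line.split("\t")[:3]
            doms.setdefault(chain_id, {})[domain_id] = parse_ranges(ranges)
    out = []
    for chain_id, by_dom in doms.items():
        if chain_id not in sequences:
            raise KeyError(f"annotated chain {chain_id!r} has no sequence")
        out.append(
            ChainAnnotation(
                chain_id=chain_id,
                sequence=sequences[chain_id],
                domains=tuple(by_dom[k] for k in sorted(by_dom)),
            )
        )
    return out


def write_annotations_tsv(annotations: Sequence[ChainAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chain_id\tdomain_id\tranges\n")
        for ann in annotations:
            for i, dom in enumerate(ann.domains, start=1):
                rng = "|".join(f"{s}-{e}" for s, e in dom)
                fh.write(f"{ann.chain_id}\tD{i}\t{rng}\n")
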