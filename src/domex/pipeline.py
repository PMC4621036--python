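"""End-to-end prediction: segments -> candidates -> search -> decision -> report.

For one chain, the pipeline derives segments from predicted boundaries,
enumerates every assemblable non-adjacent segment pair, searches the domain
library for each assembly, runs the accept/reject decision tree, resolves
conflicts between accepted assemblies (each segment may belong to at most
one discontinuous domain; the best profile-profile alignment wins), and
reports a full partition of the chain into continuous and discontinuous
domains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .library import DomainLibrary
from .ppa import PPAWeights, make_ppa_scorer
from .scoring import Decision, PpaScorer, Thresholds, decide
from .search import DEFAULT_MAX_EVALUE, BuiltinBackend, SearchBackend, search_templates
from .segments import (
    DEFAULT_MIN_SEGMENT_LEN,
    BoundarySet,
    Segment,
    enumerate_candidates,
    segments_from_boundaries,
)


@dataclass
class DomainPrediction:
    """Final domain partition for one chain.

    Each domain is a list of one or two (start, end) 1-based inclusive
    ranges; two ranges mean a discontinuous domain.  ``provenance`` records
    the winning template and scores for each discontinuous call.
    """

    chain_id: str
    chain_length: int
    domains: list[list[tuple[int, int]]] = field(default_factory=list)
    discontinuous_flags: list[bool] = field(default_factory=list)
    provenance: list[dict | None] = field(default_factory=list)

    def validate_partition(self) -> None:
        covered = [0] * (self.chain_length + 1)
        for dom in self.domains:
            for start, end in dom:
                for r in range(start, end + 1):
                    covered[r] += 1
        if any(c != 1 for c in covered[1:]):
            raise ValueError(f"{self.chain_id}: domains do not partition the chain")

    @property
    def n_discontinuous(self) -> int:
        return sum(self.discontinuous_flags)


def resolve_conflicts(accepted: Sequence[Decision]) -> list[Decision]:
    """Keep a segment-disjoint subset of accepted candidates, best PPA first.

    Candidates are ranked by ascending PPA score (absent treated as 0),
    then descending TS-score, then input order; a candidate is retained
    only if neither of its segments was already claimed.
    """
    order = {id(d): i for i, d in enumerate(accepted)}

    def key(d: Decision):
        sb = d.scores
        ppa = sb.ppa_score if sb and sb.ppa_score is not None else 0.0
        ts = sb.ts_score if sb else 0.0
        return (ppa, -ts, order[id(d)])

    used: set[int] = set()
    kept: list[Decision] = []
    for d in sorted(accepted, key=key):
        segs = set(d.candidate.segment_indices)
        if segs & used:
            continue
        used |= segs
        kept.append(d)
    kept.sort(key=lambda d: order[id(d)])
    return kept


def predict_chain(
    chain_id: str,
    sequence: str,
    boundaries: Sequence[int],
    lib: DomainLibrary,
    backend: SearchBackend | None = None,
    thresholds: Thresholds = Thresholds(),
    min_len: int = DEFAULT_MIN_SEGMENT_LEN,
    allow_reversed: bool = False,
    max_evalue: float = DEFAULT_MAX_EVALUE,
    ppa: PpaScorer | None = None,
    ppa_weights: PPAWeights = PPAWeights(),
    audit: list | None = None,
) -> DomainPrediction:
    """Predict continuous and discontinuous domains for one chain.

    ``ppa=None`` builds the default stub-profile scorer over the library;
    an ``audit`` list, if given, collects every candidate's Decision for
    per-run score logging.
    """
    bset = BoundarySet(chain_id=chain_id, chain_length=len(sequence), boundaries=tuple(boundaries))
    segments = segments_from_boundaries(sequence, bset)
    candidates = enumerate_candidates(segments, min_len=min_len, allow_reversed=allow_reversed)
    if backend is None:
        backend = BuiltinBackend()
    if ppa is None:
        ppa = make_ppa_scorer(lib, ppa_weights)

    decisions: list[Decision] = []
    for cand in candidates:
        hits = search_templates(cand, lib, backend, max_evalue=max_evalue)
        decisions.append(decide(cand, hits, thresholds, ppa=ppa))
    if audit is not None:
        audit.extend(decisions)

    winners = resolve_conflicts([d for d in decisions if d.accepted])
    return _assemble_prediction(chain_id, segments, winners)


def _assemble_prediction(
    chain_id: str, segments: Sequence[Segment], winners: Sequence[Decision]
) -> DomainPrediction:
    pred = DomainPrediction(chain_id=chain_id, chain_length=segments[-1].end)
    claimed: set[int] = set()
    for d in winners:
        cand = d.candidate
        lo, hi = sorted((cand.first, cand.second), key=lambda s: s.index)
        pred.domains.append([(lo.start, lo.end), (hi.start, hi.end)])
        pred.discontinuous_flags.append(True)
        sb = d.scores
        pred.provenance.append(
            {
                "template_id": d.winning_hit.template_id,
                "template_source": d.winning_hit.source.value,
                "reversed": cand.reversed,
                "ts_score": sb.ts_score,
                "si": sb.si,
                "e": sb.e,
                "ppa_score": sb.ppa_score,
            }
        )
        claimed |= set(cand.segment_indices)
    for seg in segments:
        if seg.index not in claimed:
            pred.domains.append([(seg.start, seg.end)])
            pred.discontinuous_flags.append(False)
            pred.provenance.append(None)
    # report domains in order of their first residue
    order = sorted(range(len(pred.domains)), key=lambda i: pred.domains[i][0][0])
    pred.domains = [pred.domains[i] for i in order]
    pred.discontinuous_flags = [pred.discontinuous_flags[i] for i in order]
    pred.provenance = [pred.provenance[i] for i in order]
    pred.validate_partition()
    return pred


def format_ranges(domain: Sequence[tuple[int, int]]) -> str:
    return "|".join(f"{s}-{e}" for s, e in domain)


def write_prediction_tsv(predictions: Sequence[DomainPrediction], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chain_id\tdomain_index\tranges\tdiscontinuous\ttemplate_id\t"
            "ts_score\tsi\te\tppa_score\n"
        )
        for pred in predictions:
            for i, (dom, flag, prov) in enumerate(
                zip(pred.domains, pred.discontinuous_flags, pred.provenance), start=1
            ):
                if prov:
                    extra = "\t".join(
                        [
                            prov["template_id"],
                            f"{prov['ts_score']:.4f}",
                            f"{prov['si']:.4f}",
                            f"{prov['e']:.4f}",
                            "" if prov["ppa_score"] is None else f"{prov['ppa_score']:.4f}",
                        ]
                    )
                else:
                    extra = "\t\t\t\t"
                fh.write(
                    f"{pred.chain_id}\t{i}\t{format_ranges(dom)}\t{int(flag)}\t{extra}\n"
                )


def write_prediction_json(predictions: Sequence[DomainPrediction], path: str | Path) -> None:
    payload = [
        {
            "chain_id": p.chain_id,
            "chain_length": p.chain_length,
            "domains": [[list(r) for r in dom] for dom in p.domains],
            "discontinuous": p.discontinuous_flags,
            "provenance": p.provenance,
        }
        for p in predictions
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_audit_tsv(decisions: Sequence[Decision], path: str | Path) -> None:
    """Per-candidate score log: every hit's full score bundle."""
    with open(path, "w") as fh:
        fh.write(
            "candidate\taccepted\treason\ttemplate_id\tts_score\th\tl\tsi\te\tppa_score\n"
        )
        for d in decisions:
            if not d.all_scored:
                fh.write(f"{d.candidate.label}\t0\t{d.reason.value}\t\t\t\t\t\t\t\n")
                continue
            for hit, sb in d.all_scored:
                win = d.winning_hit is hit and d.accepted
                ppa = "" if sb.ppa_score is None else f"{sb.ppa_score:.4f}"
                fh.write(
                    f"{d.candidate.label}\t{int(win)}\t{d.reason.value}\t{hit.template_id}\t"
                    f"{sb.ts_score:.4f}\t{sb.h:.4f}\t{sb.l:.4f}\t{sb.si:.4f}\t{sb.e:.4f}\t{ppa}\n"
                )
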