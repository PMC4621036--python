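"""Assembly scores and the accept/reject decision.

A candidate–template alignment is scored by three quantities:

* **TS-score** ``= s * h * l`` — sequence identity ``s`` weighted by a
  normalized E-value term ``h = min(E0, -log10 E) / E0`` (E0 = 10) and a
  sigmoidal coverage factor ``l`` that vanishes for coverage <= 1/3.
* **Symmetric Index (SI)** — Euclidean distance between the per-segment
  (identity, coverage) vectors of the two halves of the candidate; a small
  SI means the template matches both segments symmetrically, as expected
  when the two segments really form one domain.
* **length variation** ``e = |L_T - L_Q| / L_Q`` — homologous domains have
  similar lengths, so large e disqualifies a template.

The TS-score and SI cutoffs are tied by a one-parameter piecewise
constraint ``T_SI = f(T_TS, b)`` that keeps the SI cutoff inside its useful
[0.1, 0.3] band; a single parameter ``b`` then trades precision against
recall.  Sequence-database (Pfam-like) templates additionally require a
profile–profile alignment score below a cutoff (default -1.90) when
``b < 0.5``, since sequence-derived domain definitions are less reliable
than structure-derived ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

from .library import Source
from .search import TemplateHit
from .segments import AssembledCandidate

DEFAULT_E0 = 10.0


def normalized_evalue(E: float, E0: float = DEFAULT_E0) -> float:
    """Normalized E-value term h = min(E0, -log10 E) / E0, clamped at 0.

    h = 1 for E <= 1e-10 (with E0 = 10) and h = 0 for E >= 1.
    """
    if E <= 0:
        raise ValueError("E-value must be positive")
    return max(0.0, min(E0, -math.log10(E)) / E0)


def coverage_factor(c: float) -> float:
    """Sigmoidal weight of the alignment coverage c.

    Zero at or below c = 1/3, then 1 / (1 + (1/(3c-1))^5), approaching
    ~0.97 at full coverage.
    """
    if not (0.0 <= c <= 1.0):
        raise ValueError("coverage must be in [0, 1]")
    if c <= 1.0 / 3.0:
        return 0.0
    return 1.0 / (1.0 + (1.0 / (3.0 * c - 1.0)) ** 5)


def ts_score(s: float, h: float, l: float) -> float:
    """Template similarity score: the product s * h * l."""
    return s * h * l


def symmetric_index(v_p: tuple[float, float], v_q: tuple[float, float]) -> float:
    """Euclidean distance between the two per-segment (identity, coverage) vectors."""
    return math.hypot(v_p[0] - v_q[0], v_p[1] - v_q[1])


def length_error(L_Q: int, L_T: int) -> float:
    """Relative length variation e = |L_T - L_Q| / L_Q."""
    if L_Q <= 0:
        raise ValueError("candidate length must be positive")
    return abs(L_T - L_Q) / L_Q


def si_cutoff(t_ts: float, b: float) -> float:
    """The SI cutoff T_SI = f(T_TS, b), piecewise in T_TS.

    0.3 above 0.15 + b/2; the ramp 2*T_TS - b on (0.05 + b/2, 0.15 + b/2];
    0.1 on (b/2, 0.05 + b/2]; and 0 at or below b/2.  Boundary points fall
    in the lower piece; the two inner breakpoints are continuous either way.
    """
    if not (0.0 < b < 1.0):
        raise ValueError("b must be in (0, 1)")
    if t_ts < 0:
        raise ValueError("T_TS must be non-negative")
    if t_ts > 0.15 + b / 2.0:
        return 0.3
    if t_ts > 0.05 + b / 2.0:
        # clamp float spill at the breakpoints; the ramp lies in [0.1, 0.3]
        return min(0.3, max(0.1, 2.0 * t_ts - b))
    if t_ts > b / 2.0:
        return 0.1
    return 0.0


class Reason(Enum):
    NO_HIT = "no_hit"
    LENGTH_ERROR = "length_error"
    TS_SI_FAIL = "ts_si_fail"
    PPA_FAIL = "ppa_fail"
    ACCEPTED = "accepted"


# failure reasons ordered by how far the hit progressed through the filters
_REASON_RANK = {Reason.NO_HIT: 0, Reason.LENGTH_ERROR: 1, Reason.TS_SI_FAIL: 2, Reason.PPA_FAIL: 3}


@dataclass(frozen=True)
class Thresholds:
    """Decision cutoffs; defaults are the published operating point."""

    b: float = 0.3
    e_max: float = 0.2
    t_ppa: float = -1.90
    ppa_applies_below_b: float = 0.5
    e0: float = DEFAULT_E0
    strict_inequalities: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.b < 1.0):
            raise ValueError("b must be in (0, 1)")
        if self.e_max <= 0:
            raise ValueError("e_max must be positive")


@dataclass(frozen=True)
class ScoreBundle:
    """All assembly scores for one candidate-template pair."""

    ts_score: float
    h: float
    l: float
    si: float
    e: float
    ppa_score: float | None = None


@dataclass
class Decision:
    """Accept/reject outcome for one assembled candidate."""

    candidate: AssembledCandidate
    accepted: bool
    reason: Reason
    winning_hit: TemplateHit | None = None
    scores: ScoreBundle | None = None
    all_scored: list[tuple[TemplateHit, ScoreBundle]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.accepted and (self.winning_hit is None or self.reason is not Reason.ACCEPTED):
            raise ValueError("accepted decision must carry a winning hit")


def score_hit(candidate: AssembledCandidate, hit: TemplateHit, e0: float = DEFAULT_E0) -> ScoreBundle:
    """Compute the full score bundle for one candidate-template pair."""
    h = normalized_evalue(hit.evalue, e0)
    l = coverage_factor(hit.c)
    ts = ts_score(hit.s, h, l)
    si = symmetric_index(*hit.per_segment)
    e = length_error(len(candidate.sequence), hit.template_length)
    return ScoreBundle(ts_score=ts, h=h, l=l, si=si, e=e, ppa_score=hit.ppa_score)


PpaScorer = Callable[[AssembledCandidate, TemplateHit], float]


def _hit_passes(
    sb: ScoreBundle, hit: TemplateHit, th: Thresholds
) -> Reason:
    """Which filter (if any) a scored hit fails; ACCEPTED if it passes all."""
    if sb.e >= th.e_max:
        return Reason.LENGTH_ERROR
    cutoff = si_cutoff(sb.ts_score, th.b)
    if th.strict_inequalities:
        ts_si_ok = sb.ts_score > th.b / 2.0 and sb.si < cutoff
    else:
        ts_si_ok = sb.ts_score > th.b / 2.0 and sb.si <= cutoff
    if not ts_si_ok:
        return Reason.TS_SI_FAIL
    if (
        hit.source is Source.SEQUENCE
        and th.b < th.ppa_applies_below_b
        and sb.ppa_score is not None
        and not (sb.ppa_score < th.t_ppa)
    ):
        return Reason.PPA_FAIL
    return Reason.ACCEPTED


def _ranking_key(hit: TemplateHit, sb: ScoreBundle) -> tuple:
    ppa = sb.ppa_score if sb.ppa_score is not None else 0.0
    return (ppa, -sb.ts_score, hit.evalue, hit.template_id)


def decide(
    candidate: AssembledCandidate,
    hits: Sequence[TemplateHit],
    th: Thresholds = Thresholds(),
    ppa: PpaScorer | None = None,
) -> Decision:
    """Run the decision tree over all hits of one candidate.

    A hit passes iff e < e_max, TS-score exceeds the zero region of the
    constraint (ts > b/2), SI is within f(TS-score, b), and — for
    sequence-database templates in the b < 0.5 regime — the PPA score is
    below t_ppa.  Among passing hits the lowest PPA score wins; hits
    without a PPA score fall back to highest TS-score, then lowest
    E-value, then template id.
    """
    if not hits:
        return Decision(candidate=candidate, accepted=False, reason=Reason.NO_HIT)

    scored: list[tuple[TemplateHit, ScoreBundle]] = []
    best_failure = Reason.NO_HIT
    passing: list[tuple[TemplateHit, ScoreBundle]] = []
    for hit in hits:
        sb = score_hit(candidate, hit, th.e0)
        # PPA is only worth computing for hits that survive the cheap filters
        needs_ppa = (
            hit.source is Source.SEQUENCE
            and th.b < th.ppa_applies_below_b
            and ppa is not None
            and sb.ppa_score is None
            and _hit_passes(sb, hit, th) is Reason.ACCEPTED
        )
        if needs_ppa:
            hit.ppa_score = ppa(candidate, hit)
            sb = ScoreBundle(sb.ts_score, sb.h, sb.l, sb.si, sb.e, ppa_score=hit.ppa_score)
        outcome = _hit_passes(sb, hit, th)
        scored.append((hit, sb))
        if outcome is Reason.ACCEPTED:
            passing.append((hit, sb))
        elif _REASON_RANK[outcome] > _REASON_RANK[best_failure]:
            best_failure = outcome

    scored.sort(key=lambda pair: _ranking_key(*pair))
    if not passing:
        return Decision(
            candidate=candidate, accepted=False, reason=best_failure, all_scored=scored
        )
    win_hit, win_sb = min(passing, key=lambda pair: _ranking_key(*pair))
    return Decision(
        candidate=candidate,
        accepted=True,
        reason=Reason.ACCEPTED,
        winning_hit=win_hit,
        scores=win_sb,
        all_scored=scored,
    )
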