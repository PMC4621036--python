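"""Profile-profile alignment with predicted secondary structure.

Sequence-database (Pfam-like) domain definitions are less reliable than
structure-derived ones, so candidates whose winning template comes from a
sequence library are re-checked with a profile-profile alignment (PPA).
Each position of query and template is represented by a frequency vector
and a log-odds vector over the 20 amino acids plus a predicted secondary
structure state (H/E/C).  The column score is the symmetrized
frequency-times-log-odds dot product plus a secondary-structure agreement
bonus; a global affine-gap dynamic program finds the best alignment.

The reported PPA score is the negated, per-column-normalized alignment
score, so a *lower* (more negative) score means a *better* alignment; the
default acceptance cutoff is -1.90.

Profiles come from a PSI-BLAST ASCII PSSM when one is supplied; otherwise a
single-sequence BLOSUM62 pseudo-profile is used (one-hot frequencies,
BLOSUM62 log-odds rows), which reduces the column score to a BLOSUM62
substitution score.  Secondary structure comes from a PSIPRED-style ``.ss2``
file when given, else an all-coil stub.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
# 20x20 log-odds block in AA_ORDER
_B62 = np.array(
    [[float(_BLOSUM62[a, b]) for b in AA_ORDER] for a in AA_ORDER]
)


@dataclass
class SequenceProfile:
    """Per-position frequency and log-odds columns with secondary structure."""

    sequence: str
    freqs: np.ndarray  # (n, 20) frequency (or one-hot) vectors
    logodds: np.ndarray  # (n, 20) log-odds vectors
    ss: str  # per-position state in {H, E, C}
    ss_conf: np.ndarray  # per-position confidence in [0, 1]

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if not (self.freqs.shape == (n, 20) and self.logodds.shape == (n, 20)):
            raise ValueError("profile column shape mismatch")
        if len(self.ss) != n or self.ss_conf.shape != (n,):
            raise ValueError("secondary-structure length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PPAResult:
    """Outcome of one profile-profile alignment."""

    score: float  # negated length-normalized score; lower = better
    raw_dp_score: float  # the dynamic-programming optimum
    alignment_length: int  # columns including gaps
    aligned: tuple[tuple[int, int], ...]  # matched (query, template) 0-based pairs


@dataclass(frozen=True)
class PPAWeights:
    """Scoring weights of the profile-profile dynamic program."""

    w_ss: float = 1.0
    gap_open: float = 7.0
    gap_extend: float = 0.5


def build_profile(
    sequence: str,
    pssm_path: str | Path | None = None,
    ss_path: str | Path | None = None,
) -> SequenceProfile:
    """Build the query/template profile from PSSM and ss files, or stubs.

    Without a PSSM the profile is a single-sequence pseudo-profile (one-hot
    frequencies, BLOSUM62 log-odds).  Without an ss file the structure
    string is all-coil.
    """
    if not sequence:
        raise ValueError("empty sequence")
    n = len(sequence)
    if pssm_path is not None:
        logodds, freqs = parse_ascii_pssm(pssm_path, expected_length=n)
    else:
        freqs = np.zeros((n, 20))
        logodds = np.zeros((n, 20))
        for i, aa in enumerate(sequence):
            j = _AA_INDEX.get(aa)
            if j is not None:  # X contributes flat zero columns
                freqs[i, j] = 1.0
                logodds[i] = _B62[j]
    if ss_path is not None:
        ss, ss_conf = parse_ss2(ss_path, expected_length=n)
    else:
        ss, ss_conf = "C" * n, np.ones(n)
    return SequenceProfile(sequence=sequence, freqs=freqs, logodds=logodds, ss=ss, ss_conf=ss_conf)


def parse_ascii_pssm(path: str | Path, expected_length: int | None = None):
    """Parse an NCBI PSI-BLAST ASCII PSSM into (logodds, frequency) arrays."""
    path = Path(path)
    logodds_rows: list[list[float]] = []
    freq_rows: list[list[float]] = []
    header_cols: list[str] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if header_cols is None:
                if parts[0] == "A" or (len(parts) >= 40 and all(len(p) == 1 for p in parts[:40])):
                    header_cols = parts[:20]
                continue
            if not parts[0].isdigit():
                continue  # footer statistics
            if len(parts) < 22:
                raise ValueError(f"{path}:{lineno}: truncated PSSM row")
            try:
                values = [float(v) for v in parts[2:22]]
                perc = [float(v) for v in parts[22:42]] if len(parts) >= 42 else None
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric PSSM value") from exc
            # reorder from the file's column order to AA_ORDER
            row_l = [0.0] * 20
            row_f = [0.0] * 20
            for col_aa, lo in zip(header_cols, values):
                if col_aa in _AA_INDEX:
                    row_l[_AA_INDEX[col_aa]] = lo
            if perc is not None:
                for col_aa, p in zip(header_cols, perc):
                    if col_aa in _AA_INDEX:
                        row_f[_AA_INDEX[col_aa]] = p / 100.0
            logodds_rows.append(row_l)
            freq_rows.append(row_f)
    if header_cols is None or not logodds_rows:
        raise ValueError(f"{path}: no PSSM matrix found")
    if expected_length is not None and len(logodds_rows) != expected_length:
        raise ValueError(
            f"{path}: PSSM has {len(logodds_rows)} rows for a {expected_length}-residue query"
        )
    freqs = np.array(freq_rows)
    if not freq_rows or not freqs.any():
        freqs = np.array(logodds_rows)  # degenerate PSSM without percentages
    return np.array(logodds_rows), freqs


def parse_ss2(path: str | Path, expected_length: int | None = None):
    """Parse PSIPRED vertical (.ss2) secondary-structure output."""
    path = Path(path)
    states: list[str] = []
    confs: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0] == "#":
                continue
            if not parts[0].isdigit():
                continue
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: truncated ss2 row")
            state = parts[2]
            if state not in "HEC":
                raise ValueError(f"{path}:{lineno}: unknown ss state {state!r}")
            probs = [float(p) for p in parts[3:6]]
            states.append(state)
            confs.append(max(probs))
    if expected_length is not None and len(states) != expected_length:
        raise ValueError(
            f"{path}: ss2 has {len(states)} rows for a {expected_length}-residue query"
        )
    return "".join(states), np.array(confs)


def column_scores(query: SequenceProfile, template: SequenceProfile, weights: PPAWeights) -> np.ndarray:
    """(n_q, n_t) matrix of symmetric profile column scores plus ss bonus."""
    prof = 0.5 * (query.freqs @ template.logodds.T + (template.freqs @ query.logodds.T).T)
    qs = np.frombuffer(query.ss.encode(), dtype=np.uint8)
    ts = np.frombuffer(template.ss.encode(), dtype=np.uint8)
    ss_match = (qs[:, None] == ts[None, :]).astype(float)
    ss_w = np.sqrt(np.outer(query.ss_conf, template.ss_conf))
    return prof + weights.w_ss * ss_match * ss_w


def ppa_score(
    query: SequenceProfile,
    template: SequenceProfile,
    weights: PPAWeights = PPAWeights(),
) -> PPAResult:
    """Best global affine-gap alignment of two profiles (Gotoh dynamic program).

    The reported score is -(raw optimum / alignment length), so better
    alignments give lower (more negative) scores.
    """
    S = column_scores(query, template, weights)
    n, m = S.shape
    go, ge = weights.gap_open, weights.gap_extend
    NEG = -1e30

    M = np.full((n + 1, m + 1), NEG)  # best ending in a match at (i, j)
    X = np.full((n + 1, m + 1), NEG)  # best ending in a gap in the template (query consumed)
    Y = np.full((n + 1, m + 1), NEG)  # best ending in a gap in the query
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -go - (i - 1) * ge
    for j in range(1, m + 1):
        Y[0, j] = -go - (j - 1) * ge
    for i in range(1, n + 1):
        Si = S[i - 1]
        for j in range(1, m + 1):
            best_prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = best_prev + Si[j - 1]
            X[i, j] = max(M[i - 1, j] - go, X[i - 1, j] - ge, Y[i - 1, j] - go)
            Y[i, j] = max(M[i, j - 1] - go, X[i, j - 1] - go, Y[i, j - 1] - ge)
    raw = max(M[n, m], X[n, m], Y[n, m])

    aligned, length = _traceback(S, M, X, Y, weights)
    score = -(raw / length) if length else 0.0
    return PPAResult(score=score, raw_dp_score=float(raw), alignment_length=length, aligned=aligned)


def _traceback(S, M, X, Y, weights: PPAWeights):
    go, ge = weights.gap_open, weights.gap_extend
    n, m = S.shape
    i, j = n, m
    state = max(((M[n, m], "M"), (X[n, m], "X"), (Y[n, m], "Y")), key=lambda t: t[0])[1]
    pairs: list[tuple[int, int]] = []
    length = 0
    tol = 1e-9
    while i > 0 or j > 0:
        length += 1
        if state == "M":
            pairs.append((i - 1, j - 1))
            prev = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            state = _pick(prev, M[i, j], X[i, j], Y[i, j], tol)
        elif state == "X":
            if abs(X[i, j] - (X[i - 1, j] - ge)) < tol and i > 1:
                state = "X"
            elif abs(X[i, j] - (M[i - 1, j] - go)) < tol:
                state = "M"
            else:
                state = "Y"
            i -= 1
        else:  # Y
            if abs(Y[i, j] - (Y[i, j - 1] - ge)) < tol and j > 1:
                state = "Y"
            elif abs(Y[i, j] - (M[i, j - 1] - go)) < tol:
                state = "M"
            else:
                state = "X"
            j -= 1
        if i == 0 and j > 0:
            state = "Y"
        elif j == 0 and i > 0:
            state = "X"
    pairs.reverse()
    return tuple(pairs), length


def _pick(value, m, x, y, tol):
    if abs(value - m) < tol:
        return "M"
    if abs(value - x) < tol:
        return "X"
    return "Y"


def make_ppa_scorer(
    library,
    weights: PPAWeights = PPAWeights(),
    query_profiles: dict[str, SequenceProfile] | None = None,
):
    """A scorer ``(candidate, hit) -> PPA score`` over a domain library.

    Template sequences are looked up in the library by hit id.  Profiles
    are single-sequence pseudo-profiles unless precomputed profiles (e.g.
    from PSI-BLAST PSSMs) are supplied in ``query_profiles`` keyed by
    sequence string; all profiles are cached across calls.
    """
    cache: dict[str, SequenceProfile] = dict(query_profiles or {})

    def profile_for(seq: str) -> SequenceProfile:
        if seq not in cache:
            cache[seq] = build_profile(seq)
        return cache[seq]

    def scorer(candidate, hit) -> float:
        template_seq = library.get(hit.template_id).sequence
        return ppa_score(profile_for(candidate.sequence), profile_for(template_seq), weights).score

    return scorer
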