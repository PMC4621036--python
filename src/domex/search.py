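"""Template search for assembled candidates.

A candidate (the concatenation of two non-adjacent segments) is searched
against the single-domain library.  Each hit carries the global alignment
statistics used by the assembly scores — sequence identity ``s`` (identical
aligned columns / aligned columns), alignment coverage ``c`` (aligned query
residues / candidate length) — plus per-segment identity/coverage pairs
obtained by splitting the alignment at the candidate's junction.

Two backends implement the search contract:

* :class:`BuiltinBackend` — deterministic local affine-gap alignment of the
  bare candidate against every library record (BLOSUM62, via Biopython's
  ``PairwiseAligner``) with a Karlin–Altschul-style E-value.  The whole
  pipeline runs with no external binaries on this backend.
* :class:`PsiBlastBackend` — adapter around NCBI ``psiblast``: stage one
  builds a query profile against a background set, stage two searches the
  domain library with that profile (tabular output with alignment strings).
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Protocol, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .library import DomainLibrary, DomainRecord, Source, write_library_fasta
from .segments import AssembledCandidate

# Karlin-Altschul parameters for BLOSUM62 with gap open 11 / extend 1
KA_LAMBDA = 0.267
KA_K = 0.041

DEFAULT_MAX_EVALUE = 10.0


@dataclass(frozen=True)
class AlignedColumn:
    """One aligned residue pair (no gaps), 1-based positions."""

    q_pos: int
    t_pos: int
    match: bool


@dataclass
class TemplateHit:
    """One library match for an assembled candidate."""

    template_id: str
    source: Source
    evalue: float
    raw_score: float
    template_length: int
    columns: tuple[AlignedColumn, ...]
    query_aln: str = ""
    template_aln: str = ""
    s: float = 0.0  # global identity fraction over aligned columns
    c: float = 0.0  # aligned query residues / candidate length
    per_segment: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 0.0), (0.0, 0.0))
    ppa_score: float | None = None

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError("E-value must be positive")


class SearchBackend(Protocol):
    """Contract: deterministic search of a candidate sequence against a library."""

    name: str

    def search(self, query: str, lib: DomainLibrary) -> list[TemplateHit]:
        ...


class BackendError(RuntimeError):
    """Raised when a search backend fails, carrying its diagnostics."""


def _columns_from_alignment(aln: Align.Alignment) -> tuple[tuple[AlignedColumn, ...], str, str]:
    """Extract aligned residue pairs and gapped strings from a Biopython alignment.

    The aligner is invoked as align(candidate, template), so the alignment
    "target" is the candidate and the "query" is the template.
    """
    cand = str(aln.target)
    tmpl = str(aln.query)
    cols: list[AlignedColumn] = []
    q_parts: list[str] = []
    t_parts: list[str] = []
    blocks_q, blocks_t = aln.aligned  # (target blocks, query blocks)
    prev_q_end = prev_t_end = None
    for (qs, qe), (ts, te) in zip(blocks_q, blocks_t):
        if prev_q_end is not None:
            gq = cand[prev_q_end:qs]
            gt = tmpl[prev_t_end:ts]
            q_parts.append(gq + "-" * len(gt))
            t_parts.append("-" * len(gq) + gt)
        for dq, dt in zip(range(qs, qe), range(ts, te)):
            cols.append(AlignedColumn(q_pos=dq + 1, t_pos=dt + 1, match=cand[dq] == tmpl[dt]))
        q_parts.append(cand[qs:qe])
        t_parts.append(tmpl[ts:te])
        prev_q_end, prev_t_end = qe, te
    return tuple(cols), "".join(q_parts), "".join(t_parts)


def karlin_altschul_evalue(score: float, query_len: int, db_len: int) -> float:
    """E = K * m * n * exp(-lambda * S), floored to stay strictly positive."""
    e = KA_K * query_len * db_len * math.exp(-KA_LAMBDA * score)
    return max(e, 1e-300)


class BuiltinBackend:
    """Deterministic BLOSUM62 local affine-gap search against every record."""

    name = "builtin"

    def __init__(self, open_gap: float = -11.0, extend_gap: float = -1.0) -> None:
        self.open_gap = open_gap
        self.extend_gap = extend_gap
        self._aligner = Align.PairwiseAligner()
        self._aligner.mode = "local"
        self._aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        self._aligner.open_gap_score = open_gap
        self._aligner.extend_gap_score = extend_gap

    def search(self, query: str, lib: DomainLibrary) -> list[TemplateHit]:
        if not query:
            raise ValueError("empty query sequence")
        db_len = sum(r.length for r in lib.records)
        hits: list[TemplateHit] = []
        for rec in lib.records:
            alignments = self._aligner.align(query, rec.sequence)
            score = alignments.score
            if score <= 0:
                continue
            evalue = karlin_altschul_evalue(score, len(query), db_len)
            cols, q_aln, t_aln = _columns_from_alignment(alignments[0])
            if not cols:
                continue
            hits.append(
                TemplateHit(
                    template_id=rec.id,
                    source=rec.source,
                    evalue=evalue,
                    raw_score=score,
                    template_length=rec.length,
                    columns=cols,
                    query_aln=q_aln,
                    template_aln=t_aln,
                )
            )
        hits.sort(key=lambda h: (h.evalue, h.template_id))
        return hits


class PsiBlastBackend:
    """Two-stage profile search with NCBI ``psiblast``.

    Stage 1 iterates the query against a background FASTA to build a PSSM;
    stage 2 searches the domain library with that profile.  Tabular output
    with alignment strings (qseq/sseq) is parsed into hits.  Requires the
    BLAST+ binaries on PATH.
    """

    name = "psiblast"
    _OUTFMT = "6 sseqid evalue bitscore length sstart send qstart qend qseq sseq"

    def __init__(
        self,
        background_fasta: str | Path | None = None,
        iterations: int = 3,
        stage1_evalue: float = 0.001,
        stage2_evalue: float = DEFAULT_MAX_EVALUE,
    ) -> None:
        self.background_fasta = Path(background_fasta) if background_fasta else None
        self.iterations = iterations
        self.stage1_evalue = stage1_evalue
        self.stage2_evalue = stage2_evalue

    def search(self, query: str, lib: DomainLibrary) -> list[TemplateHit]:
        if shutil.which("psiblast") is None or shutil.which("makeblastdb") is None:
            raise BackendError("psiblast/makeblastdb not found on PATH")
        source_by_id = {r.id: r.source for r in lib.records}
        length_by_id = {r.id: r.length for r in lib.records}
        with tempfile.TemporaryDirectory() as tmp:
            tmpdir = Path(tmp)
            qfa = tmpdir / "query.fasta"
            qfa.write_text(f">query\n{query}\n")
            libfa = tmpdir / "library.fasta"
            write_library_fasta(lib.records, libfa)
            self._run(["makeblastdb", "-in", str(libfa), "-dbtype", "prot"])
            cmd = ["psiblast", "-query", str(qfa), "-outfmt", self._OUTFMT,
                   "-evalue", str(self.stage2_evalue)]
            pssm = tmpdir / "query.pssm"
            if self.background_fasta is not None:
                self._run(["makeblastdb", "-in", str(self.background_fasta), "-dbtype", "prot"])
                self._run([
                    "psiblast", "-query", str(qfa), "-db", str(self.background_fasta),
                    "-num_iterations", str(self.iterations),
                    "-evalue", str(self.stage1_evalue),
                    "-out_pssm", str(pssm), "-out", str(tmpdir / "stage1.out"),
                ])
            if pssm.exists():
                cmd += ["-in_pssm", str(pssm), "-db", str(libfa)]
                cmd = [c for c in cmd if c not in ("-query", str(qfa))]
            else:
                cmd += ["-db", str(libfa)]
            out = self._run(cmd)
        return parse_tabular_hits(out, source_by_id, length_by_id)

    @staticmethod
    def _run(cmd: Sequence[str]) -> str:
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise BackendError(f"{cmd[0]} failed: {proc.stderr.strip()}")
        return proc.stdout


def parse_tabular_hits(
    text: str,
    source_by_id: dict[str, Source],
    length_by_id: dict[str, int],
) -> list[TemplateHit]:
    """Parse BLAST tabular output with qseq/sseq alignment string fields."""
    hits: list[TemplateHit] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 10:
            raise BackendError(f"malformed tabular hit line: {line!r}")
        sid, evalue, bits, _length, _ss, _se, qstart, _qend, qseq, sseq = fields[:10]
        if sid not in source_by_id:
            raise BackendError(f"hit to unknown library record {sid!r}")
        cols: list[AlignedColumn] = []
        q_pos = int(qstart) - 1
        t_pos = int(_ss) - 1
        for qc, tc in zip(qseq, sseq):
            if qc != "-":
                q_pos += 1
            if tc != "-":
                t_pos += 1
            if qc != "-" and tc != "-":
                cols.append(AlignedColumn(q_pos=q_pos, t_pos=t_pos, match=qc == tc))
        hits.append(
            TemplateHit(
                template_id=sid,
                source=source_by_id[sid],
                evalue=float(evalue),
                raw_score=float(bits),
                template_length=length_by_id[sid],
                columns=tuple(cols),
                query_aln=qseq,
                template_aln=sseq,
            )
        )
    hits.sort(key=lambda h: (h.evalue, h.template_id))
    return hits


def split_hit_at_junction(
    hit: TemplateHit, junction: int, len_first: int, len_second: int
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Per-segment (identity, coverage) pairs, split at the junction.

    Aligned columns with query position <= junction belong to the first
    segment.  For part k: s_k = identities / aligned columns in the part,
    c_k = aligned query residues / segment length.  A part with no aligned
    columns yields (0, 0).
    """
    parts: dict[bool, list[AlignedColumn]] = {True: [], False: []}
    for col in hit.columns:
        parts[col.q_pos <= junction].append(col)

    def stats(cols: list[AlignedColumn], seg_len: int) -> tuple[float, float]:
        if not cols:
            return (0.0, 0.0)
        matches = sum(c.match for c in cols)
        return (matches / len(cols), len(cols) / seg_len)

    return stats(parts[True], len_first), stats(parts[False], len_second)


def annotate_hit(hit: TemplateHit, candidate: AssembledCandidate) -> TemplateHit:
    """Fill in global and per-segment identity/coverage for one hit."""
    n_cols = len(hit.columns)
    matches = sum(c.match for c in hit.columns)
    s = matches / n_cols if n_cols else 0.0
    c = n_cols / len(candidate.sequence)
    per_seg = split_hit_at_junction(
        hit, candidate.junction, len(candidate.first), len(candidate.second)
    )
    return replace(hit, s=s, c=c, per_segment=per_seg)


def search_templates(
    candidate: AssembledCandidate,
    lib: DomainLibrary,
    backend: SearchBackend,
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> list[TemplateHit]:
    """Search the library for homologous templates of an assembled candidate.

    Returns hits with E-value <= max_evalue, each annotated with global
    (s, c) and per-segment (s_k, c_k) statistics.  An empty result is not
    an error.
    """
    if not candidate.sequence:
        raise ValueError("candidate sequence is empty")
    if len(lib) == 0:
        raise ValueError("domain library is empty")
    hits = backend.search(candidate.sequence, lib)
    return [annotate_hit(h, candidate) for h in hits if h.evalue <= max_evalue]
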