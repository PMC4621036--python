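"""Single-domain sequence library: loading, source tagging, redundancy filtering.

Assembled candidate domains are searched against a library of known
single-domain sequences.  Records carry a *source* tag distinguishing
structure-derived domain definitions (CATH/SCOP-like) from sequence-derived
ones (Pfam-like); downstream filtering treats the two classes differently.
The library is made non-redundant with a pairwise sequence-identity cutoff
(default 90%), mirroring how large domain databases are deduplicated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids plus the ambiguity code X.
AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Default header-prefix rules mapping FASTA id prefixes to source tags.
DEFAULT_SOURCE_RULES: dict[str, "Source"] = {}


class Source(Enum):
    """Provenance class of a library domain definition."""

    STRUCTURE = "structure"  # boundaries defined from a 3D structure (CATH/SCOP-like)
    SEQUENCE = "sequence"  # boundaries defined from sequence models (Pfam-like)


@dataclass(frozen=True)
class DomainRecord:
    """One single-domain sequence in the library."""

    id: str
    sequence: str
    source: Source

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - AMINO_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid residue characters {sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class DomainLibrary:
    """A collection of domain records with a redundancy cutoff.

    After :func:`deduplicate`, no two retained records share pairwise
    sequence identity at or above ``identity_cutoff``.
    """

    records: list[DomainRecord] = field(default_factory=list)
    identity_cutoff: float = 0.90

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate record ids in library")
        if not (0.0 < self.identity_cutoff <= 1.0):
            raise ValueError("identity_cutoff must be in (0, 1]")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, record_id: str) -> DomainRecord:
        for r in self.records:
            if r.id == record_id:
                return r
        raise KeyError(record_id)


def resolve_source(record_id: str, source_rules: Mapping[str, Source]) -> Source:
    """Map a FASTA record id to a source tag via prefix rules.

    Rules are checked in insertion order; the first prefix match wins.
    """
    for prefix, src in source_rules.items():
        if record_id.startswith(prefix):
            return src
    raise ValueError(f"record {record_id!r}: no source rule matches its id")


def default_source_rules() -> dict[str, Source]:
    """Prefix rules for the conventional ``cath|/scop|/pfam|`` header style."""
    return {
        "cath|": Source.STRUCTURE,
        "scop|": Source.STRUCTURE,
        "pfam|": Source.SEQUENCE,
    }


def load_library(
    fasta_path: str | Path,
    source_rules: Mapping[str, Source] | None = None,
    identity_cutoff: float = 0.90,
) -> DomainLibrary:
    """Load a domain library from FASTA, tagging each record with a source.

    Records whose sequences contain characters outside the 20 canonical
    amino acids plus X are dropped with a warning.  An id that no source
    rule resolves is a fatal error, as is a missing or empty FASTA file.
    """
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise FileNotFoundError(f"library FASTA not found: {fasta_path}")
    if source_rules is None:
        source_rules = default_source_rules()

    records: list[DomainRecord] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper()
        src = resolve_source(rec.id, source_rules)
        bad = set(seq) - AMINO_ALPHABET
        if bad or not seq:
            logger.warning(
                "dropping record %s: invalid residue characters %s",
                rec.id,
                sorted(bad),
            )
            continue
        records.append(DomainRecord(id=rec.id, sequence=seq, source=src))
    if not records:
        raise ValueError(f"no usable records in library FASTA: {fasta_path}")
    return DomainLibrary(records=records, identity_cutoff=identity_cutoff)


def _identity_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def pairwise_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Global-alignment sequence identity, normalized by the shorter sequence.

    identity = identical aligned residues / length of the shorter sequence.
    """
    if aligner is None:
        aligner = _identity_aligner()
    aln = aligner.align(a, b)[0]
    identities = aln.counts().identities
    return identities / min(len(a), len(b))


def deduplicate(lib: DomainLibrary, cutoff: float | None = None) -> DomainLibrary:
    """Greedy longest-first redundancy filter.

    Records are visited in descending length (ties by id); a record is
    discarded iff its identity to an already-retained record is >= cutoff.
    Idempotent, and with cutoff 1.0 removes only (sub)sequences aligning
    identically over their full shorter length.
    """
    if cutoff is None:
        cutoff = lib.identity_cutoff
    if not (0.0 < cutoff <= 1.0):
        raise ValueError("cutoff must be in (0, 1]")
    aligner = _identity_aligner()
    retained: list[DomainRecord] = []
    for rec in sorted(lib.records, key=lambda r: (-r.length, r.id)):
        if any(
            pairwise_identity(rec.sequence, kept.sequence, aligner) >= cutoff
            for kept in retained
        ):
            continue
        retained.append(rec)
    # restore the input ordering among retained records
    order = {r.id: i for i, r in enumerate(lib.records)}
    retained.sort(key=lambda r: order[r.id])
    return DomainLibrary(records=retained, identity_cutoff=cutoff)


def save_manifest(lib: DomainLibrary, tsv_path: str | Path) -> None:
    """Persist a sidecar manifest (id, source, length) next to the FASTA."""
    with open(tsv_path, "w") as fh:
        fh.write("id\tsource\tlength\n")
        for r in lib.records:
            fh.write(f"{r.id}\t{r.source.value}\t{r.length}\n")


def write_library_fasta(records: Iterable[DomainRecord], fasta_path: str | Path) -> None:
    with open(fasta_path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.sequence), 60):
                fh.write(r.sequence[i : i + 60] + "\n")
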