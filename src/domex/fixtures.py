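"""Deterministic synthetic fixtures: toy libraries, queries, boundaries, labels.

The generator emulates the benchmark construction used to train and test
the detector: multi-segment chains whose two non-adjacent segments are
homologous (point-mutated copies) to a single-domain library template are
positives; chains whose segment pairs share no joint template are
negatives.  Continuous segments may carry their own single-segment
templates, and random-composition decoys are length-matched to candidate
assemblies so the length-error filter is exercised nontrivially.  All
output is byte-identical for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .evaluation import ChainAnnotation, Label, ScoredSample, write_annotations_tsv
from .library import DomainLibrary, DomainRecord, Source, write_library_fasta
from .segments import write_boundary_tsv

#: Background amino-acid frequencies (Robinson & Robinson-style composition).
BACKGROUND_FREQS = {
    "A": 0.078, "R": 0.051, "N": 0.045, "D": 0.054, "C": 0.019,
    "Q": 0.043, "E": 0.063, "G": 0.074, "H": 0.022, "I": 0.051,
    "L": 0.091, "K": 0.057, "M": 0.022, "F": 0.039, "P": 0.052,
    "S": 0.071, "T": 0.058, "W": 0.013, "Y": 0.032, "V": 0.065,
}
_AAS = np.array(list(BACKGROUND_FREQS))
_FREQS = np.array(list(BACKGROUND_FREQS.values()))
_FREQS = _FREQS / _FREQS.sum()


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions of the synthetic benchmark."""

    seed: int = 0
    n_chains: int = 30
    segments_per_chain: tuple[int, int] = (3, 4)  # inclusive range
    segment_length: tuple[int, int] = (40, 80)  # inclusive range
    mutation_rate: float = 0.1
    fraction_discontinuous: float = 0.5
    library_decoys: int = 30
    reversed_fraction: float = 0.0
    indel_rate: float = 0.0
    structure_fraction: float = 0.5  # fraction of templates tagged STRUCTURE
    continuous_template_prob: float = 0.5

    def __post_init__(self) -> None:
        if self.n_chains <= 0 or self.segment_length[0] < 1:
            raise ValueError("invalid fixture spec: counts and lengths must be positive")
        for rate in (self.mutation_rate, self.fraction_discontinuous,
                     self.reversed_fraction, self.indel_rate):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("invalid fixture spec: rates must be in [0, 1]")


@dataclass
class FixtureSet:
    """Generated fixture: library, annotated chains, boundaries and truth."""

    spec: FixtureSpec
    library: DomainLibrary
    chains: list[ChainAnnotation]
    boundaries: dict[str, list[int]]
    positive_info: dict[str, dict] = field(default_factory=dict)

    @property
    def sequences(self) -> dict[str, str]:
        return {c.chain_id: c.sequence for c in self.chains}

    def without_templates(self) -> DomainLibrary:
        """The same library with every joint (positive) template withheld."""
        joint = {info["template_id"] for info in self.positive_info.values()}
        return DomainLibrary(
            records=[r for r in self.library.records if r.id not in joint],
            identity_cutoff=self.library.identity_cutoff,
        )


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AAS, size=length, p=_FREQS))


def mutate(seq: str, rate: float, rng: np.random.Generator, indel_rate: float = 0.0) -> str:
    """Position-independent substitution (and optional indel) mutation."""
    out: list[str] = []
    for aa in seq:
        if indel_rate and rng.random() < indel_rate / 2.0:
            continue  # deletion
        if rng.random() < rate:
            choices = [a for a in _AAS if a != aa]
            out.append(str(rng.choice(choices)))
        else:
            out.append(aa)
        if indel_rate and rng.random() < indel_rate / 2.0:
            out.append(random_sequence(rng, 1))  # insertion
    return "".join(out) or random_sequence(rng, 1)


def _template_source(rng: np.random.Generator, structure_fraction: float) -> tuple[Source, str]:
    if rng.random() < structure_fraction:
        return Source.STRUCTURE, "cath|"
    return Source.SEQUENCE, "pfam|"


def generate(spec: FixtureSpec, out_dir: str | Path | None = None) -> FixtureSet:
    """Generate the full fixture set; optionally write it to standard files.

    Writes library.fasta, queries.fasta, boundaries.tsv, annotations.tsv
    and labels.tsv under ``out_dir`` when given.
    """
    rng = np.random.default_rng(spec.seed)
    n_pos = int(round(spec.fraction_discontinuous * spec.n_chains))
    n_rev = int(round(spec.reversed_fraction * n_pos))

    records: list[DomainRecord] = []
    chains: list[ChainAnnotation] = []
    boundaries: dict[str, list[int]] = {}
    positive_info: dict[str, dict] = {}
    candidate_lengths: list[int] = []

    for i in range(spec.n_chains):
        chain_id = f"chain{i:03d}"
        k = int(rng.integers(spec.segments_per_chain[0], spec.segments_per_chain[1] + 1))
        lengths = [
            int(rng.integers(spec.segment_length[0], spec.segment_length[1] + 1))
            for _ in range(k)
        ]
        seqs = [random_sequence(rng, L) for L in lengths]
        starts = np.cumsum([1, *lengths[:-1]])
        ranges = [(int(s), int(s) + L - 1) for s, L in zip(starts, lengths)]
        boundaries[chain_id] = [int(r[1]) for r in ranges[:-1]]

        is_positive = i < n_pos
        if is_positive:
            pairs = [(p, q) for p in range(k) for q in range(p + 2, k)]
            p, q = pairs[int(rng.integers(len(pairs)))]
            as_reversed = i < n_rev
            joint = seqs[q] + seqs[p] if as_reversed else seqs[p] + seqs[q]
            template = mutate(joint, spec.mutation_rate, rng, spec.indel_rate)
            src, prefix = _template_source(rng, spec.structure_fraction)
            tid = f"{prefix}joint_{chain_id}"
            records.append(DomainRecord(id=tid, sequence=template, source=src))
            candidate_lengths.append(len(joint))
            positive_info[chain_id] = {
                "template_id": tid,
                "pair": (p + 1, q + 1),
                "reversed": as_reversed,
            }
            domains = [(ranges[p], ranges[q])] + [
                (ranges[m],) for m in range(k) if m not in (p, q)
            ]
        else:
            domains = [(r,) for r in ranges]
        # continuous segments may carry their own single-segment templates
        for dom in domains:
            if len(dom) == 1 and rng.random() < spec.continuous_template_prob:
                start, end = dom[0]
                seg_seq = "".join(seqs)[start - 1 : end]
                src, prefix = _template_source(rng, spec.structure_fraction)
                records.append(
                    DomainRecord(
                        id=f"{prefix}cont_{chain_id}_{start}",
                        sequence=mutate(seg_seq, spec.mutation_rate, rng, spec.indel_rate),
                        source=src,
                    )
                )
        chains.append(
            ChainAnnotation(
                chain_id=chain_id,
                sequence="".join(seqs),
                domains=tuple(tuple(d) for d in domains),
            )
        )

    # length-matched random decoys so e < 0.2 is exercised nontrivially
    if not candidate_lengths:
        candidate_lengths = [2 * spec.segment_length[0]]
    for d in range(spec.library_decoys):
        L = int(candidate_lengths[d % len(candidate_lengths)] + rng.integers(-5, 6))
        src, prefix = _template_source(rng, spec.structure_fraction)
        records.append(
            DomainRecord(id=f"{prefix}decoy{d:03d}", sequence=random_sequence(rng, max(L, 10)), source=src)
        )

    fixture = FixtureSet(
        spec=spec,
        library=DomainLibrary(records=records),
        chains=chains,
        boundaries=boundaries,
        positive_info=positive_info,
    )
    if out_dir is not None:
        _write(fixture, Path(out_dir))
    return fixture


def _write(fixture: FixtureSet, out_dir: Path) -> None:
    from .evaluation import generate_samples

    out_dir.mkdir(parents=True, exist_ok=True)
    write_library_fasta(fixture.library.records, out_dir / "library.fasta")
    with open(out_dir / "queries.fasta", "w") as fh:
        for chain in fixture.chains:
            fh.write(f">{chain.chain_id}\n")
            for i in range(0, len(chain.sequence), 60):
                fh.write(chain.sequence[i : i + 60] + "\n")
    write_boundary_tsv(fixture.boundaries, out_dir / "boundaries.tsv")
    write_annotations_tsv(fixture.chains, out_dir / "annotations.tsv")
    with open(out_dir / "labels.tsv", "w") as fh:
        fh.write("chain_id\tsegments\tlabel\n")
        for s in generate_samples(fixture.chains):
            fh.write(
                f"{s.origin_chain}\tS{s.candidate.first.index}+S{s.candidate.second.index}\t"
                f"{s.label.value}\n"
            )


def planted_threshold_scores(
    seed: int,
    n_pos: int = 200,
    n_neg: int = 400,
    t_ts: float = 0.5,
    t_si: float = 0.2,
) -> list[ScoredSample]:
    """Separable score-level benchmark with a planted (T_TS, T_SI) boundary.

    Positives score ts >= t_ts with si <= t_si; negatives fail one of the
    two margins by more than half a 0.05 grid step, so an exhaustive grid
    search recovers the planted cell.
    """
    rng = np.random.default_rng(seed)
    samples: list[ScoredSample] = []
    for _ in range(n_pos):
        samples.append(
            ScoredSample(
                label=Label.POSITIVE,
                ts=float(rng.uniform(t_ts, 1.0)),
                si=float(rng.uniform(0.0, t_si)),
                e=float(rng.uniform(0.0, 0.15)),
                source=Source.STRUCTURE,
            )
        )
    for j in range(n_neg):
        if j % 2 == 0:  # fails the TS-score margin
            ts = float(rng.uniform(0.1, t_ts - 0.03))
            si = float(rng.uniform(0.0, 0.5))
        else:  # fails the SI margin
            ts = float(rng.uniform(t_ts, 1.0))
            si = float(rng.uniform(t_si + 0.03, 0.5))
        samples.append(
            ScoredSample(
                label=Label.NEGATIVE, ts=ts, si=si,
                e=float(rng.uniform(0.0, 0.15)), source=Source.STRUCTURE,
            )
        )
    return samples
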