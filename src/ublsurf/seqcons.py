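"""Sequence identity, MSA column conservation, and surface mapping.

Pairwise identity uses a global BLOSUM62 alignment with affine gaps
(open 10, extend 0.5); identity is the number of identical aligned pairs
divided by all alignment columns that are not double gaps (columns with a
gap on exactly one side count as non-identical).  Column conservation is a
defined, fully reproducible per-column score (modal-residue frequency, or a
normalised Shannon-entropy complement), intended for qualitative surface
colouring; it deliberately does not attempt phylogeny-aware rate
estimation.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .structio import Structure, three_to_one
from .superpose import ResidueCorrespondence

GAP_OPEN = 10.0
GAP_EXTEND = 0.5
SUBSTITUTION_TABLE = "BLOSUM62"

_GAP_CHARS = {"-", "."}


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.substitution_matrix = substitution_matrices.load(SUBSTITUTION_TABLE)
    al.open_gap_score = -GAP_OPEN
    al.extend_gap_score = -GAP_EXTEND
    al.mode = "global"
    return al


def _align_pair(seq_a: str, seq_b: str) -> tuple[str, str]:
    aln = _aligner().align(seq_a, seq_b)[0]
    return str(aln[0]), str(aln[1])


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment percent identity between two ungapped sequences."""
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    ga, gb = _align_pair(seq_a.upper(), seq_b.upper())
    identical = sum(1 for x, y in zip(ga, gb) if x == y and x not in _GAP_CHARS)
    columns = sum(
        1 for x, y in zip(ga, gb) if not (x in _GAP_CHARS and y in _GAP_CHARS)
    )
    return 100.0 * identical / columns


def sequence_correspondence(
    seq_a: str,
    seq_b: str,
    start_a: int = 1,
    start_b: int = 1,
    numbers_a: Sequence[int] | None = None,
    numbers_b: Sequence[int] | None = None,
) -> ResidueCorrespondence:
    """Residue correspondence from a global sequence alignment.

    Residue numbers default to consecutive numbering from ``start_*``; an
    explicit per-residue numbering (author numbering of a chain) may be
    given instead.
    """
    ga, gb = _align_pair(seq_a.upper(), seq_b.upper())
    num_a = list(numbers_a) if numbers_a is not None else \
        list(range(start_a, start_a + len(seq_a)))
    num_b = list(numbers_b) if numbers_b is not None else \
        list(range(start_b, start_b + len(seq_b)))
    if len(num_a) != len(seq_a) or len(num_b) != len(seq_b):
        raise ValueError("numbering length does not match sequence length")
    pairs: list[tuple[int | None, int | None]] = []
    ia = ib = 0
    for x, y in zip(ga, gb):
        a = b = None
        if x not in _GAP_CHARS:
            a = num_a[ia]
            ia += 1
        if y not in _GAP_CHARS:
            b = num_b[ib]
            ib += 1
        pairs.append((a, b))
    return ResidueCorrespondence(
        pairs=pairs,
        method="sequence",
        names_a=dict(zip(num_a, seq_a.upper())),
        names_b=dict(zip(num_b, seq_b.upper())),
    )


@dataclasses.dataclass
class Msa:
    """A parsed multiple sequence alignment: ordered (id, gapped sequence)."""

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("empty alignment")
        lengths = {len(s) for _, s in self.records}
        if len(lengths) != 1:
            raise ValueError(f"gapped sequences differ in length: {lengths}")
        ids = [i for i, _ in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record ids in alignment")

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def n_seqs(self) -> int:
        return len(self.records)

    def record(self, record_id: str) -> str:
        for i, s in self.records:
            if i == record_id:
                return s
        raise KeyError(f"record {record_id!r} not in alignment")

    @classmethod
    def read_fasta(cls, path: str | Path) -> "Msa":
        from .structio import read_fasta

        return cls(records=read_fasta(path))


@dataclasses.dataclass
class ConservationProfile:
    """Per-column conservation scores in [0, 1] (None for all-gap columns)."""

    per_column: list  # float | None
    gap_fraction: list
    method: str
    low_coverage: list  # bool flags, gap fraction > 0.5


def column_conservation(msa: Msa, method: str = "identity") -> ConservationProfile:
    """Column-wise conservation of an MSA.

    ``identity``: frequency of the modal residue among non-gap symbols.
    ``entropy``: 1 - H/ln(20) with H the Shannon entropy of the non-gap
    residue frequencies.  All-gap columns yield a missing value.
    """
    if msa.n_seqs < 2:
        raise ValueError("need >= 2 sequences")
    if method not in ("identity", "entropy"):
        raise ValueError(f"unknown conservation method {method!r}")
    scores: list[float | None] = []
    gap_fraction: list[float] = []
    low: list[bool] = []
    seqs = [s.upper() for _, s in msa.records]
    for col in range(msa.length):
        symbols = [s[col] for s in seqs]
        residues = [c for c in symbols if c not in _GAP_CHARS]
        gf = 1.0 - len(residues) / len(symbols)
        gap_fraction.append(gf)
        low.append(gf > 0.5)
        if not residues:
            scores.append(None)
            continue
        counts: dict[str, int] = {}
        for c in residues:
            counts[c] = counts.get(c, 0) + 1
        if method == "identity":
            scores.append(max(counts.values()) / len(residues))
        else:
            h = -sum(
                (k / len(residues)) * math.log(k / len(residues))
                for k in counts.values()
            )
            scores.append(max(0.0, 1.0 - h / math.log(20.0)))
    return ConservationProfile(
        per_column=scores, gap_fraction=gap_fraction, method=method, low_coverage=low
    )


def map_profile_to_structure(
    profile: ConservationProfile,
    msa: Msa,
    record_id: str,
    structure: Structure,
    chain_id: str | None = None,
    mismatch_tolerance: float = 0.10,
) -> dict[int, float]:
    """Transfer column scores onto residue numbers of a chain.

    The named record's ungapped sequence is matched position-by-position
    against the chain sequence; more than *mismatch_tolerance* disagreement
    is an error, less is a warning.  Gapped columns are skipped.
    """
    chain_id = chain_id or structure.chain_ids(0)[0]
    residues = structure.chain(chain_id)
    gapped = msa.record(record_id)
    ungapped_cols = [i for i, c in enumerate(gapped) if c not in _GAP_CHARS]
    seq = "".join(gapped[i] for i in ungapped_cols).upper()
    chain_seq = structure.one_letter_sequence(chain_id)
    if len(seq) != len(chain_seq):
        raise ValueError(
            f"record {record_id!r} length {len(seq)} != chain {chain_id} "
            f"length {len(chain_seq)}"
        )
    mismatches = [
        (residues[k].seq_number, seq[k], chain_seq[k])
        for k in range(len(seq))
        if seq[k] != chain_seq[k]
    ]
    if len(mismatches) > mismatch_tolerance * len(seq):
        raise ValueError(
            f"{len(mismatches)}/{len(seq)} sequence mismatches between MSA record "
            f"and chain: {mismatches[:5]}..."
        )
    if mismatches:
        import warnings

        warnings.warn(f"{len(mismatches)} sequence mismatches: {mismatches}",
                      stacklevel=2)
    out: dict[int, float] = {}
    for k, col in enumerate(ungapped_cols):
        score = profile.per_column[col]
        if score is not None:
            out[residues[k].seq_number] = score
    return out
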