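"""Sequence similarity kernels.

Pairwise similarities between lncRNAs (and between proteins) are computed
from exact Smith-Waterman local alignment scores, normalized by the larger
of the two self-alignment scores:

    S(a, b) = sw(a, b) / max(sw(a, a), sw(b, b))

which yields a symmetric matrix with entries in [0, 1] and unit diagonal,
since a local alignment of (a, b) can never outscore the better
self-alignment.

Alignment itself is delegated to :class:`Bio.Align.PairwiseAligner` in
local mode with affine gap penalties (a gap of length L costs
``gap_open + (L - 1) * gap_extend``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .exceptions import DegenerateInputError, InputError

NUCLEOTIDE = "nucleotide"
PROTEIN = "protein"

_NT_CANONICAL = set("ACGT")
_NT_AMBIGUOUS = set("RYSWKMBDHVN")
_AA_CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")
_AA_AMBIGUOUS = set("BZXUOJ*")

#: default local-alignment scoring per alphabet (conventional values;
#: every field is overridable through config / CLI flags)
DEFAULT_NUCLEOTIDE_SCORING: "AlignmentScoring"
DEFAULT_PROTEIN_SCORING: "AlignmentScoring"


@dataclass(frozen=True)
class SequenceRecord:
    """A single identified sequence.

    The sequence is uppercased on construction; for nucleotides, ``U`` is
    mapped to ``T`` so RNA FASTA files are accepted transparently.
    Ambiguity codes are permitted but flagged via :attr:`has_ambiguous`.
    """

    id: str
    sequence: str
    alphabet: str

    def __post_init__(self):
        if not self.id:
            raise InputError("sequence record id must be nonempty")
        if self.alphabet not in (NUCLEOTIDE, PROTEIN):
            raise InputError(f"unknown alphabet {self.alphabet!r}")
        seq = self.sequence.upper()
        if self.alphabet == NUCLEOTIDE:
            seq = seq.replace("U", "T")
            allowed = _NT_CANONICAL | _NT_AMBIGUOUS
        else:
            allowed = _AA_CANONICAL | _AA_AMBIGUOUS
        if not seq:
            raise InputError(f"sequence for {self.id!r} is empty")
        bad = set(seq) - allowed
        if bad:
            raise InputError(
                f"sequence for {self.id!r} contains characters {sorted(bad)} "
                f"outside the {self.alphabet} alphabet"
            )
        object.__setattr__(self, "sequence", seq)

    @property
    def has_ambiguous(self) -> bool:
        amb = _NT_AMBIGUOUS if self.alphabet == NUCLEOTIDE else _AA_AMBIGUOUS
        return bool(set(self.sequence) & amb)


@dataclass(frozen=True)
class AlignmentScoring:
    """Affine-gap local alignment parameters.

    For nucleotides, ``match``/``mismatch`` scores are used and ambiguity
    codes always score as a mismatch.  For proteins, ``matrix_name`` names a
    Biopython substitution matrix (default BLOSUM62); residues absent from
    the matrix alphabet (U, O, J) are scored as X.
    """

    alphabet: str
    match: float = 2.0
    mismatch: float = -1.0
    matrix_name: str = "BLOSUM62"
    gap_open: float = 5.0
    gap_extend: float = 2.0

    def __post_init__(self):
        if self.alphabet == NUCLEOTIDE and self.match <= 0:
            raise InputError("match reward must be positive")
        if not (self.gap_open >= self.gap_extend >= 0):
            raise InputError("require gap_open >= gap_extend >= 0")

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner(mode="local")
        if self.alphabet == NUCLEOTIDE:
            # explicit matrix so ambiguity codes (incl. N vs N) score as mismatch
            letters = "ACGT" + "".join(sorted(_NT_AMBIGUOUS))
            mat = substitution_matrices.Array(alphabet=letters, dims=2)
            mat[:, :] = self.mismatch
            for x in "ACGT":
                mat[x, x] = self.match
            aligner.substitution_matrix = mat
        else:
            aligner.substitution_matrix = substitution_matrices.load(self.matrix_name)
        aligner.open_gap_score = -float(self.gap_open)
        aligner.extend_gap_score = -float(self.gap_extend)
        return aligner


DEFAULT_NUCLEOTIDE_SCORING = AlignmentScoring(
    alphabet=NUCLEOTIDE, match=2.0, mismatch=-1.0, gap_open=5.0, gap_extend=2.0
)
DEFAULT_PROTEIN_SCORING = AlignmentScoring(
    alphabet=PROTEIN, matrix_name="BLOSUM62", gap_open=10.0, gap_extend=1.0
)


def default_scoring(alphabet: str) -> AlignmentScoring:
    if alphabet == NUCLEOTIDE:
        return DEFAULT_NUCLEOTIDE_SCORING
    if alphabet == PROTEIN:
        return DEFAULT_PROTEIN_SCORING
    raise InputError(f"unknown alphabet {alphabet!r}")


@dataclass
class SimilarityMatrix:
    """Symmetric similarity matrix over one entity set, entries in [0, 1],
    unit diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        q = len(self.ids)
        if len(set(self.ids)) != q:
            raise InputError("similarity matrix ids must be unique")
        if self.values.shape != (q, q):
            raise InputError(
                f"similarity matrix shape {self.values.shape} does not match "
                f"{q} ids"
            )
        self.validate()

    def validate(self, tol: float = 1e-9):
        v = self.values
        if not np.allclose(v, v.T, atol=max(tol, 1e-12)):
            raise InputError("similarity matrix is not symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise InputError("similarity entries must lie in [0, 1]")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise InputError("similarity diagonal must equal 1")

    @property
    def size(self) -> int:
        return len(self.ids)

    def index_of(self, entity_id: str) -> int:
        return self.ids.index(entity_id)


def _prepare_for_alignment(record: SequenceRecord) -> str:
    """Map residues the BLOSUM alphabet lacks onto X (proteins only)."""
    if record.alphabet == PROTEIN:
        return record.sequence.translate(str.maketrans("UOJ", "XXX"))
    return record.sequence


def smith_waterman_score(
    a: SequenceRecord, b: SequenceRecord, scoring: AlignmentScoring | None = None
) -> float:
    """Maximum local-alignment score of two sequences under affine gaps.

    Symmetric and nonnegative; an alignment of zero length scores 0, so a
    pair with no positively scoring residue pair returns 0.
    """
    if a.alphabet != b.alphabet:
        raise InputError(
            f"alphabet mismatch: {a.id!r} is {a.alphabet}, {b.id!r} is {b.alphabet}"
        )
    if scoring is None:
        scoring = default_scoring(a.alphabet)
    if scoring.alphabet != a.alphabet:
        raise InputError(
            f"scoring is for {scoring.alphabet}, sequences are {a.alphabet}"
        )
    aligner = scoring.make_aligner()
    return float(aligner.score(_prepare_for_alignment(a), _prepare_for_alignment(b)))


def normalized_similarity_matrix(
    records: Sequence[SequenceRecord], scoring: AlignmentScoring | None = None
) -> SimilarityMatrix:
    """All-pairs self-score-normalized Smith-Waterman similarity.

    Entry (i, j) is ``sw(i, j) / max(sw(i, i), sw(j, j))``; the diagonal is
    set to exactly 1.  A record whose self-alignment score is not strictly
    positive (e.g. an all-ambiguous sequence) makes the normalization
    ill-posed and raises :class:`DegenerateInputError` naming the record.
    """
    records = list(records)
    if len(records) < 2:
        raise InputError("need at least 2 records to build a similarity matrix")
    alphabets = {r.alphabet for r in records}
    if len(alphabets) != 1:
        raise InputError(f"records mix alphabets: {sorted(alphabets)}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise InputError(f"duplicate record ids: {dup}")
    if scoring is None:
        scoring = default_scoring(records[0].alphabet)

    q = len(records)
    aligner = scoring.make_aligner()
    seqs = [_prepare_for_alignment(r) for r in records]
    self_scores = np.array([float(aligner.score(s, s)) for s in seqs])
    for r, s in zip(records, self_scores):
        if s <= 0:
            raise DegenerateInputError(
                f"record {r.id!r} has non-positive self-alignment score {s}; "
                "cannot normalize"
            )
    values = np.eye(q)
    for i in range(q):
        for j in range(i + 1, q):
            sw = float(aligner.score(seqs[i], seqs[j]))
            values[i, j] = values[j, i] = sw / max(self_scores[i], self_scores[j])
    return SimilarityMatrix(ids=ids, values=values)
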