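"""Smith-Waterman sequence similarity for clustering protein families.

Pairwise optimal local alignments under the PAM250 log-odds matrix with
an affine gap penalty (a gap of length L costs open + extend*(L-1);
defaults 10.0 and 0.5).  Two similarity definitions are offered for
building a clustering input matrix:

``identity``
    fraction of identical residues over the aligned columns of the
    optimal local alignment (gapped columns included in the
    denominator), matching the "percent identity" a practitioner would
    quote for closely related family members;
``normalized_score``
    score_ij / sqrt(score_ii * score_jj), a self-normalized alignment
    score in (0, 1].

Either matrix feeds the similarity-to-distance conversion and then the
chaotic-map clustering engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
import numpy as np

from .matrices import LabeledSquareMatrix

__all__ = [
    "AlignmentResult",
    "load_pam250",
    "smith_waterman",
    "sequence_similarity_matrix",
    "read_fasta",
]

# the vendored matrix covers the 20 standard residues plus X (scored 0
# against everything, itself included)
PAM250_FILE = "pam250.txt"
PAM250_SHA256 = "ceacaf2602dc391668fb8021089fa5c5c2d2aeae664b96ea42a17ccf6d4de458"


@lru_cache(maxsize=1)
def load_pam250():
    """The vendored PAM250 substitution matrix as a biopython Array."""
    ref = resources.files("cmclust.data").joinpath(PAM250_FILE)
    with resources.as_file(ref) as path:
        return substitution_matrices.read(str(path))


@dataclass(frozen=True)
class AlignmentResult:
    """Optimal local alignment summary."""

    score: float
    aligned_length: int
    identities: int

    @property
    def identity_fraction(self) -> float:
        if self.aligned_length == 0:
            return 0.0
        return self.identities / self.aligned_length


def _validate(seq: str, which: str) -> str:
    seq = str(seq).upper()
    if len(seq) < 1:
        raise ValueError(f"sequence {which} is empty")
    alphabet = set(load_pam250().alphabet)
    for pos, letter in enumerate(seq):
        if letter not in alphabet:
            raise ValueError(
                f"illegal residue {letter!r} at position {pos} of sequence {which}"
            )
    return seq


def _aligner(gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = load_pam250()
    # biopython charges open_gap_score on the first gapped position and
    # extend_gap_score on each further one, i.e. a length-L gap costs
    # open + extend*(L-1) — the EMBOSS water convention used here
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    return aligner


def smith_waterman(
    a: str, b: str, gap_open: float = 10.0, gap_extend: float = 0.5
) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment of two residue sequences.

    The score is the PAM250 sum over aligned pairs minus affine gap
    costs, maximised over all pairs of substrings; it is never negative
    (the empty alignment scores 0).
    """
    a = _validate(a, "a")
    b = _validate(b, "b")
    aligner = _aligner(gap_open, gap_extend)
    score = float(aligner.score(a, b))
    if score <= 0.0:
        return AlignmentResult(0.0, 0, 0)
    alignment = next(iter(aligner.align(a, b)))
    cols = alignment.shape[1]
    counts = alignment.counts()
    return AlignmentResult(score, int(cols), int(counts.identities))


def read_fasta(path) -> dict[str, str]:
    """Multi-record FASTA to an ordered {id: sequence} mapping."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        records[rec.id] = str(rec.seq)
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def sequence_similarity_matrix(
    sequences: dict[str, str],
    mode: str = "identity",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> LabeledSquareMatrix:
    """All-pairs Smith-Waterman similarity matrix over a labelled set.

    ``identity`` uses the identity fraction of the optimal alignment;
    ``normalized_score`` uses score_ij / sqrt(score_ii score_jj).  The
    diagonal is 1 in both modes.
    """
    if mode not in ("identity", "normalized_score"):
        raise ValueError(f"mode must be 'identity' or 'normalized_score', got {mode!r}")
    labels = list(sequences)
    if len(labels) < 2:
        raise ValueError("need at least two sequences")
    seqs = {l: _validate(s, l) for l, s in sequences.items()}
    n = len(labels)
    sim = np.eye(n)
    if mode == "normalized_score":
        self_scores = np.array(
            [smith_waterman(seqs[l], seqs[l], gap_open, gap_extend).score for l in labels]
        )
        if (self_scores <= 0).any():
            bad = labels[int(np.argmin(self_scores))]
            raise ValueError(
                f"sequence {bad!r} has non-positive self-alignment score; "
                "cannot normalize"
            )
    for i in range(n):
        for j in range(i + 1, n):
            res = smith_waterman(seqs[labels[i]], seqs[labels[j]], gap_open, gap_extend)
            if mode == "identity":
                sim[i, j] = sim[j, i] = res.identity_fraction
            else:
                sim[i, j] = sim[j, i] = res.score / float(
                    np.sqrt(self_scores[i] * self_scores[j])
                )
    return LabeledSquareMatrix(tuple(labels), sim, "similarity")
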