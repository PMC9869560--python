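"""Global alignment utilities shared across the package.

One scoring scheme backs everything that aligns proteins: BLOSUM62
substitution scores with affine gaps (open 10, extend 1), computed with
Biopython's PairwiseAligner.  :func:`align_to_model` maps a domain sequence
onto the bundled 57-column AP2 model so residues can be read at fixed model
columns and insertion runs can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .profiles import AP2_MODEL_CONSENSUS


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


_ALIGNER = make_aligner()


def global_score(a: str, b: str) -> float:
    """Global alignment score between two protein sequences."""
    return float(_ALIGNER.score(a, b))


def global_alignment(a: str, b: str) -> tuple[str, str, float]:
    """Gapped strings of the optimal global alignment (first optimum)."""
    alignment = _ALIGNER.align(a, b)[0]
    return str(alignment[0]), str(alignment[1]), float(alignment.score)


@dataclass(frozen=True)
class ModelAlignment:
    """A domain sequence threaded onto the model's fixed columns.

    ``model_residues`` has one character per model column ('-' where the
    domain has a deletion).  ``insertions`` lists (after_column, length)
    runs of domain residues not matched to any model column; runs after
    column 0 or after the final column are sequence overhangs, the rest are
    internal insertions.
    """

    score: float
    model_residues: str
    insertions: tuple[tuple[int, int], ...]
    unalignable: bool

    @property
    def width(self) -> int:
        return len(self.model_residues)

    def residue(self, column: int) -> str:
        """Residue at a 1-based model column ('-' for a deletion)."""
        return self.model_residues[column - 1]

    @property
    def max_internal_insertion(self) -> int:
        internal = [length for after, length in self.insertions
                    if 1 <= after <= self.width - 1]
        return max(internal, default=0)

    def distance_to(self, consensus: str) -> int:
        """Mismatch count against a profile consensus over aligned columns.

        Deleted columns count as mismatches, so a barely-alignable sequence
        does not look artificially close to every profile.
        """
        return sum(1 for a, b in zip(self.model_residues, consensus)
                   if a != b)


def align_to_model(sequence: str, model: str = AP2_MODEL_CONSENSUS,
                   score_floor: float = 0.0) -> ModelAlignment:
    """Globally align a domain sequence against the bundled model.

    Sequences scoring below ``score_floor`` are flagged unalignable (the
    classifier routes those to the Soloist-candidate path).
    """
    if len(sequence) == 0:
        raise ValueError("empty domain sequence")
    alignment = _ALIGNER.align(model, sequence)[0]
    width = len(model)
    model_res = ["-"] * width
    insertions: list[tuple[int, int]] = []
    prev_t = prev_q = 0
    blocks = alignment.aligned
    for (ts, te), (qs, qe) in zip(blocks[0], blocks[1]):
        if qs > prev_q:
            insertions.append((prev_t, qs - prev_q))
        for k in range(ts, te):
            model_res[k] = sequence[qs + (k - ts)]
        prev_t, prev_q = te, qe
    if len(sequence) > prev_q:
        insertions.append((prev_t, len(sequence) - prev_q))
    score = float(alignment.score)
    return ModelAlignment(score=score,
                          model_residues="".join(model_res),
                          insertions=tuple(insertions),
                          unalignable=score < score_floor)
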