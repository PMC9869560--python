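"""Bundled AP2/ERF domain models.

The package ships a small, self-contained set of position-specific models for
the ~57-residue AP2/ERF DNA-binding domain and the B3 DNA-binding domain.
Every model is a per-subgroup consensus sequence plus a position-frequency
matrix derived from it.  The models encode the classification signals used
throughout the package:

* ERF-type domains carry Ala/Asp at the two diagnostic columns (default
  14 and 19), DREB-type domains carry Val/Glu.
* The four ERF subgroups B1-B4 differ at columns 49 and 56:
  B1=(F,L), B2=(L,T), B3=(F,T), B4=(M,L).
* The AP2 subfamily carries a 10-residue insertion inside the domain;
  ANT does not.
* RAV proteins pair one AP2 domain with a B3 domain.
* Soloist has a domain sequence distinct from every other subfamily.

The consensus strings are synthetic: plausible AP2/ERF-like sequences
constructed so that the diagnostic columns and inter-subgroup distances are
exactly controlled.  They are a modelling device for classification and
simulation, not curated biological consensus sequences.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

AP2_MODEL_WIDTH = 57

# Columns (1-based, model coordinates) that carry classification signal.
DIAGNOSTIC_COLUMNS = (14, 19, 49, 56)

# Base ERF-type consensus; column 14=A, 19=D, 49=F, 56=L.
_BASE_ERF = "RYRGVRQRPWGKWAEIRDDTRKGARVWLGTFDTAEEAARAYDEAARLLFGPRARTLN"
assert len(_BASE_ERF) == AP2_MODEL_WIDTH


def _variant(base: str, subs: dict[int, str]) -> str:
    """Apply 1-based column substitutions to a consensus string."""
    chars = list(base)
    for col, aa in subs.items():
        chars[col - 1] = aa
    return "".join(chars)


_DREB = _variant(_BASE_ERF, {14: "V", 19: "E"})

#: Per-subgroup 57-column consensus of the AP2 domain.  A1-A4 (DREB) differ
#: at columns 24/26/28; B1-B4 (ERF) differ at the key columns 49/56 plus a
#: separator at column 22; ANT/AP2/RAV/Soloist carry non-ERF, non-DREB
#: residues at the diagnostic columns.
SUBGROUP_CONSENSUS: dict[str, str] = {
    "A1": _DREB,
    "A2": _variant(_DREB, {24: "S", 26: "I"}),
    "A3": _variant(_DREB, {24: "T", 28: "M"}),
    "A4": _variant(_DREB, {26: "L", 28: "V"}),
    "B1": _BASE_ERF,
    "B2": _variant(_BASE_ERF, {49: "L", 56: "T", 22: "R"}),
    "B3": _variant(_BASE_ERF, {49: "F", 56: "T", 22: "S"}),
    "B4": _variant(_BASE_ERF, {49: "M", 56: "L", 22: "Q"}),
    "ANT": _variant(_BASE_ERF, {14: "G", 19: "N", 33: "W"}),
    "AP2": _variant(_BASE_ERF, {14: "G", 19: "N", 33: "Y"}),
    "RAV": _variant(_BASE_ERF, {14: "S", 19: "Q", 33: "H"}),
    "Soloist": _variant(
        _BASE_ERF,
        {
            2: "F", 5: "T", 7: "K", 10: "L", 13: "N", 14: "T", 16: "V",
            19: "S", 21: "E", 25: "G", 29: "D", 34: "P", 38: "S", 42: "N",
            46: "K", 50: "W", 53: "E", 57: "G",
        },
    ),
}

#: Ten-residue insertion planted inside the first AP2 domain of AP2-subfamily
#: proteins (after model column 20, i.e. between the beta2 strand and beta3).
AP2_SUBFAMILY_INSERTION = "GSSGSSGSSG"
AP2_SUBFAMILY_INSERTION_AFTER = 20

#: Subfamily-level consensus used for nearest-profile fallback when the two
#: diagnostic residues match neither the ERF nor the DREB pattern.
SUBFAMILY_CONSENSUS: dict[str, str] = {
    "ERF": _BASE_ERF,
    "DREB": _DREB,
    "Soloist": SUBGROUP_CONSENSUS["Soloist"],
}

#: Shared model the classifier aligns every single-AP2 domain against.
AP2_MODEL_CONSENSUS = _BASE_ERF

#: Synthetic B3 DNA-binding domain consensus (RAV subfamily second domain).
B3_DOMAIN_CONSENSUS = "MESSNKSSPVVVLDLFPKGVRFRPTDEELVGYLKRKVLGEKLPWDIIPEV"
B3_MODEL_WIDTH = len(B3_DOMAIN_CONSENSUS)

SUBFAMILIES = ("ERF", "DREB", "AP2", "ANT", "RAV", "Soloist")
SUBGROUPS = ("A1", "A2", "A3", "A4", "B1", "B2", "B3", "B4",
             "AP2", "ANT", "RAV", "Soloist")

SUBGROUP_TO_SUBFAMILY = {
    "A1": "DREB", "A2": "DREB", "A3": "DREB", "A4": "DREB",
    "B1": "ERF", "B2": "ERF", "B3": "ERF", "B4": "ERF",
    "AP2": "AP2", "ANT": "ANT", "RAV": "RAV", "Soloist": "Soloist",
}

SUBFAMILY_TO_SUBGROUPS = {
    "DREB": ("A1", "A2", "A3", "A4"),
    "ERF": ("B1", "B2", "B3", "B4"),
    "AP2": ("AP2",),
    "ANT": ("ANT",),
    "RAV": ("RAV",),
    "Soloist": ("Soloist",),
}


def position_frequency_matrix(consensus: str, conservation: float = 0.9) -> np.ndarray:
    """Per-column residue probabilities around a consensus.

    Each column assigns ``conservation`` to the consensus residue and spreads
    the remainder uniformly over the other 19 amino acids.
    """
    if not 0.0 < conservation <= 1.0:
        raise ValueError("conservation must be in (0, 1]")
    off = (1.0 - conservation) / (len(AMINO_ACIDS) - 1)
    pfm = np.full((len(consensus), len(AMINO_ACIDS)), off)
    for i, aa in enumerate(consensus):
        pfm[i, AA_INDEX[aa]] = conservation
    return pfm
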