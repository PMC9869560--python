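"""Position-wise conservation statistics of the aligned AP2 domain.

Computes per-column residue frequencies (gaps excluded from denominators),
the majority consensus with the >50% uppercase convention, and the mean
consensus fraction ("consensus ratio") within the eight divisions induced
by the domain's secondary structure: three beta strands (columns 1-7,
14-20, 31-33), one alpha helix (48-57) and the intervals between them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles import AA_INDEX, AMINO_ACIDS, AP2_MODEL_WIDTH

#: Secondary-structure intervals over model columns (1-based inclusive).
SECONDARY_STRUCTURE = {
    "beta1": (1, 7),
    "beta2": (14, 20),
    "beta3": (31, 33),
    "alpha": (48, 57),
}


def divisions(model_width: int = AP2_MODEL_WIDTH) -> dict[str, tuple[int, int]]:
    """Eight-division partition of [1, model_width] around the structure.

    D1=beta1, D3=beta2, D5=beta3, D7=alpha; D2/D4/D6 are the intervening
    loops and D8 is the tail beyond the helix (empty at width 57).
    """
    div = {
        "D1": (1, 7), "D2": (8, 13), "D3": (14, 20), "D4": (21, 30),
        "D5": (31, 33), "D6": (34, 47), "D7": (48, 57),
    }
    if model_width > 57:
        div["D8"] = (58, model_width)
    covered = sorted(c for lo, hi in div.values() for c in range(lo, hi + 1))
    if covered != list(range(1, model_width + 1)):
        raise ValueError("divisions must cover the model exactly")
    return div


@dataclass
class ConservationProfile:
    """Frequencies, consensus and division ratios for one aligned set.

    ``frequencies`` is (width x 20), rows normalized over non-gap residues;
    all-gap columns are flagged and excluded from division means.
    """

    frequencies: np.ndarray
    n_sequences: int
    all_gap: np.ndarray  # boolean per column

    @property
    def width(self) -> int:
        return self.frequencies.shape[0]

    @property
    def consensus_fractions(self) -> np.ndarray:
        return self.frequencies.max(axis=1)

    def consensus(self) -> str:
        """Majority consensus; uppercase iff the fraction exceeds 0.5.

        Frequency ties are broken alphabetically, which keeps the output
        independent of input order.
        """
        out = []
        for col in range(self.width):
            if self.all_gap[col]:
                out.append("-")
                continue
            freqs = self.frequencies[col]
            # Lowest index among maxima = alphabetical tie-break.
            best = int(np.flatnonzero(freqs == freqs.max())[0])
            aa = AMINO_ACIDS[best]
            out.append(aa.upper() if freqs[best] > 0.5 else aa.lower())
        return "".join(out)

    def division_ratios(self, division_map: dict[str, tuple[int, int]] | None = None
                        ) -> dict[str, float]:
        """Mean consensus fraction per division; NaN when fully gapped."""
        division_map = division_map or divisions(self.width)
        fractions = self.consensus_fractions
        out = {}
        for name, (lo, hi) in division_map.items():
            cols = np.arange(lo - 1, hi)
            keep = cols[~self.all_gap[cols]]
            out[name] = float(fractions[keep].mean()) if len(keep) else float("nan")
        return out

    def to_frame(self) -> pd.DataFrame:
        consensus = self.consensus()
        return pd.DataFrame({
            "column": np.arange(1, self.width + 1),
            "consensus": list(consensus),
            "fraction": np.where(self.all_gap, np.nan,
                                 self.consensus_fractions),
        })


def column_frequencies(aligned: list[str]) -> ConservationProfile:
    """Per-column residue frequencies of an aligned domain set.

    Gap characters ('-' or '.') are excluded from the denominator of every
    column.  All sequences must share the model width.
    """
    if len(aligned) == 0:
        raise ValueError("need at least one sequence")
    width = len(aligned[0])
    if any(len(s) != width for s in aligned):
        raise ValueError("sequences differ in aligned length")
    counts = np.zeros((width, len(AMINO_ACIDS)))
    for seq in aligned:
        for col, aa in enumerate(seq):
            if aa in ("-", "."):
                continue
            idx = AA_INDEX.get(aa.upper())
            if idx is not None:
                counts[col, idx] += 1
    totals = counts.sum(axis=1)
    all_gap = totals == 0
    freqs = np.divide(counts, np.where(all_gap, 1.0, totals)[:, None])
    return ConservationProfile(frequencies=freqs, n_sequences=len(aligned),
                               all_gap=all_gap)
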