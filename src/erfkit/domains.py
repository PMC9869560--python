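"""AP2/B3 domain hits: InterProScan TSV ingestion, PSSM scanning, filtering.

Two routes produce :class:`DomainHit` records: parsing InterProScan-style
tab-separated files (Pfam accessions PF00847 = AP2, PF02362 = B3) or a
self-contained position-specific scoring scan against the bundled domain
models.  :func:`filter_hits` then applies the cleanup rules: drop hits with
e-value > 1e-5 and, among overlapping hits, keep the best-supported one, so
each gene ends with a non-overlapping, sorted domain architecture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .profiles import (
    AA_INDEX,
    AMINO_ACIDS,
    AP2_MODEL_CONSENSUS,
    B3_DOMAIN_CONSENSUS,
    position_frequency_matrix,
)

EVALUE_CUTOFF = 1e-5

_PFAM_TO_KIND = {"PF00847": "AP2", "PF02362": "B3"}


class ParseError(ValueError):
    """Malformed InterProScan TSV row."""


@dataclass(frozen=True, order=True)
class DomainHit:
    """One detected AP2 or B3 domain on a protein.

    Coordinates are 1-based inclusive protein positions.  ``evalue`` is
    ``None`` for hits from the PSSM route, which reports bit scores only.
    """

    gene: str
    kind: str  # "AP2" | "B3"
    start: int
    end: int
    evalue: float | None = None
    score: float | None = None

    def __post_init__(self):
        if self.kind not in ("AP2", "B3"):
            raise ValueError(f"unknown domain kind {self.kind!r}")
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad coordinates {self.start}..{self.end}")
        if self.evalue is not None and self.evalue < 0:
            raise ValueError("negative e-value")

    def overlaps(self, other: "DomainHit") -> bool:
        """True when the two hits share at least one residue."""
        return not (self.end < other.start or other.end < self.start)


@dataclass(frozen=True)
class Architecture:
    """Clean per-gene domain architecture: sorted, non-overlapping hits."""

    gene: str
    hits: tuple[DomainHit, ...]

    @property
    def n_ap2(self) -> int:
        return sum(1 for h in self.hits if h.kind == "AP2")

    @property
    def has_b3(self) -> bool:
        return any(h.kind == "B3" for h in self.hits)

    @property
    def is_family(self) -> bool:
        return len(self.hits) > 0


def parse_interproscan_tsv(path: str | Path) -> list[DomainHit]:
    """Read AP2/B3 hits from an InterProScan ``-f tsv`` style file.

    Rows with other signature accessions are ignored.  Coordinates are taken
    verbatim (1-based inclusive); an e-value of "-" is recorded as missing.
    Malformed rows raise :class:`ParseError` naming the line number.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"line {lineno}: expected >= 9 tab-separated "
                                 f"columns, got {len(fields)}")
            accession = fields[4]
            kind = _PFAM_TO_KIND.get(accession)
            if kind is None:
                continue
            try:
                start = int(fields[6])
                stop = int(fields[7])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer coordinates "
                                 f"{fields[6]!r}..{fields[7]!r}") from exc
            if start > stop or start < 1:
                raise ParseError(f"line {lineno}: bad interval {start}..{stop}")
            raw_e = fields[8]
            if raw_e in ("-", ""):
                evalue = None
            else:
                try:
                    evalue = float(raw_e)
                except ValueError as exc:
                    raise ParseError(f"line {lineno}: bad e-value {raw_e!r}") from exc
            hits.append(DomainHit(gene=fields[0], kind=kind, start=start,
                                  end=stop, evalue=evalue))
    return hits


@dataclass(frozen=True)
class PSSMModel:
    """Log-odds window model over the 20 amino acids (uniform background)."""

    kind: str
    log_odds: np.ndarray  # (width, 20), bits
    threshold: float = 15.0

    @property
    def width(self) -> int:
        return self.log_odds.shape[0]

    @classmethod
    def from_consensus(cls, kind: str, consensus: str,
                       conservation: float = 0.9,
                       threshold: float = 15.0) -> "PSSMModel":
        pfm = position_frequency_matrix(consensus, conservation)
        background = 1.0 / len(AMINO_ACIDS)
        return cls(kind=kind, log_odds=np.log2(pfm / background),
                   threshold=threshold)


def default_models() -> dict[str, PSSMModel]:
    return {
        "AP2": PSSMModel.from_consensus("AP2", AP2_MODEL_CONSENSUS),
        "B3": PSSMModel.from_consensus("B3", B3_DOMAIN_CONSENSUS),
    }


#: Score for residues outside the 20-letter alphabet (X, gaps, ...).
_UNKNOWN_PENALTY = -4.0


def scan_pssm(gene: str, sequence: str, model: PSSMModel) -> list[DomainHit]:
    """Slide the log-odds window; report greedily non-overlapping hits.

    Windows scoring at least ``model.threshold`` bits are kept in descending
    score order (ties: lower start), discarding any window overlapping an
    already kept one.  Sequences shorter than the model yield an empty list.
    """
    width = model.width
    if len(sequence) < width:
        return []
    idx = np.array([AA_INDEX.get(aa, -1) for aa in sequence])
    # Vectorized window scores: score[i] = sum_j M[j, idx[i+j]].
    n_windows = len(sequence) - width + 1
    windows = np.lib.stride_tricks.sliding_window_view(idx, width)
    safe = np.clip(windows, 0, 19)
    scores = model.log_odds[np.arange(width)[None, :], safe]
    scores = np.where(windows >= 0, scores, _UNKNOWN_PENALTY).sum(axis=1)
    order = sorted(range(n_windows), key=lambda i: (-scores[i], i))
    hits: list[DomainHit] = []
    for i in order:
        if scores[i] < model.threshold:
            break
        candidate = DomainHit(gene=gene, kind=model.kind, start=i + 1,
                              end=i + width, score=float(scores[i]))
        if not any(candidate.overlaps(h) for h in hits):
            hits.append(candidate)
    return sorted(hits, key=lambda h: h.start)


def _evalue_rank(hit: DomainHit) -> tuple:
    # Missing e-values (PSSM route, "-" in TSV) rank below any numeric one.
    if hit.evalue is None:
        return (1, math.inf, hit.start, -(hit.end - hit.start))
    return (0, hit.evalue, hit.start, -(hit.end - hit.start))


def filter_hits(hits: Sequence[DomainHit]) -> Architecture:
    """Apply the e-value and overlap rules to one gene's hits.

    Hits with e-value > 1e-5 are dropped (hits without e-values are kept).
    Among overlapping hits the one with the lowest e-value wins (ties:
    lowest start, then longest).  The result is sorted and non-overlapping;
    the operation is idempotent.
    """
    if not hits:
        return Architecture(gene="", hits=())
    genes = {h.gene for h in hits}
    if len(genes) != 1:
        raise ValueError(f"hits span multiple genes: {sorted(genes)}")
    gene = genes.pop()
    passing = [h for h in hits if h.evalue is None or h.evalue <= EVALUE_CUTOFF]
    retained: list[DomainHit] = []
    for hit in sorted(passing, key=_evalue_rank):
        if not any(hit.overlaps(kept) for kept in retained):
            retained.append(hit)
    return Architecture(gene=gene,
                        hits=tuple(sorted(retained, key=lambda h: h.start)))


def architectures_from_hits(hits: Iterable[DomainHit]) -> dict[str, Architecture]:
    """Group hits by gene and filter each gene independently."""
    by_gene: dict[str, list[DomainHit]] = {}
    for hit in hits:
        by_gene.setdefault(hit.gene, []).append(hit)
    return {gene: filter_hits(group) for gene, group in by_gene.items()}
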