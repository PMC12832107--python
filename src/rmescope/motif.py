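"""PWM log-odds scanning of paired allele promoter sequences.

Allele-specific transcription-factor binding is assessed by scanning the
~500 b promoter sequence of each parental allele with a position weight
matrix and comparing the best log-odds hits: a positive score delta
(129 minus CAST) predicts stronger binding on the 129 promoter, i.e. a
SNP that strengthens the motif on that allele.  Both strands are scanned;
windows containing N are skipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO, motifs as bio_motifs

__all__ = [
    "PWM",
    "AllelePair",
    "ScanHit",
    "ScanResult",
    "AlleleDelta",
    "log_odds_matrix",
    "scan",
    "allele_delta",
    "read_pwm",
    "read_allele_pairs",
]

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT_INDEX = np.array([3, 2, 1, 0])  # A<->T, C<->G in ACGT order


@dataclass
class PWM:
    """Position weight matrix over A, C, G, T.

    ``probabilities`` is a width x 4 row-stochastic matrix; ``pseudocount``
    is added per cell (then renormalized) before log-odds conversion so
    zero probabilities stay finite; ``background`` defaults to uniform.
    """

    probabilities: np.ndarray
    pseudocount: float = 0.01
    background: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.ndim != 2 or self.probabilities.shape[1] != 4:
            raise ValueError("PWM probabilities must be a width x 4 matrix")
        if self.probabilities.shape[0] < 1:
            raise ValueError("PWM width must be >= 1")
        if (self.probabilities < 0).any():
            raise ValueError("PWM probabilities must be non-negative")
        rs = self.probabilities.sum(axis=1)
        if not np.allclose(rs, 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1 (pass counts to PWM.from_counts)")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.background is None:
            self.background = np.full(4, 0.25)
        else:
            self.background = np.asarray(self.background, dtype=float)
            if self.background.shape != (4,) or not math.isclose(
                float(self.background.sum()), 1.0, abs_tol=1e-9
            ):
                raise ValueError("background must be a 4-vector summing to 1")
            if (self.background <= 0).any():
                raise ValueError("background frequencies must be strictly positive")

    @property
    def width(self) -> int:
        return self.probabilities.shape[0]

    @classmethod
    def from_counts(cls, counts: np.ndarray, pseudocount: float = 0.01,
                    background: np.ndarray | None = None) -> "PWM":
        """Build from a width x 4 count (or unnormalized weight) matrix."""
        counts = np.asarray(counts, dtype=float)
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        rs = counts.sum(axis=1, keepdims=True)
        if (rs == 0).any():
            raise ValueError("PWM has an all-zero position")
        return cls(counts / rs, pseudocount=pseudocount, background=background)


@dataclass(frozen=True)
class AllelePair:
    """Promoter sequences of the two alleles of one gene."""

    gene: str
    seq_129: str
    seq_cast: str

    def __post_init__(self) -> None:
        for name, seq in (("seq_129", self.seq_129), ("seq_cast", self.seq_cast)):
            if not seq:
                raise ValueError(f"{name} is empty for gene {self.gene!r}")
            bad = set(seq.upper()) - set(ALPHABET + "N")
            if bad:
                raise ValueError(f"{name} for {self.gene!r} has invalid bases {sorted(bad)}")


@dataclass(frozen=True)
class ScanHit:
    score: float
    start: int  # 0-based, on the forward sequence
    strand: str  # "+" | "-"


@dataclass(frozen=True)
class ScanResult:
    best: ScanHit
    forward_scores: np.ndarray  # NaN where the window contains N
    reverse_scores: np.ndarray  # indexed by forward start of the window


@dataclass(frozen=True)
class AlleleDelta:
    gene: str
    best_129: ScanHit
    best_cast: ScanHit
    delta: float  # best_129.score - best_cast.score


def log_odds_matrix(pwm: PWM) -> np.ndarray:
    """width x 4 matrix of log2((p + pseudocount, renormalized) / background)."""
    if (pwm.background <= 0).any():
        raise ValueError("background frequencies must be strictly positive")
    p = (pwm.probabilities + pwm.pseudocount) / (1.0 + 4.0 * pwm.pseudocount)
    with np.errstate(divide="ignore"):
        return np.log2(p / pwm.background)


def _encode(seq: str) -> np.ndarray:
    """Map a sequence to indices 0..3; N (or other IUPAC) -> -1."""
    return np.array([_BASE_INDEX.get(b, -1) for b in seq.upper()], dtype=int)


def _window_scores(codes: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Summed log-odds per window start; NaN where any base is ambiguous."""
    w = lom.shape[0]
    n_win = codes.size - w + 1
    scores = np.zeros(n_win)
    valid = np.ones(n_win, dtype=bool)
    safe = np.where(codes < 0, 0, codes)
    for i in range(w):
        col = safe[i : i + n_win]
        scores += lom[i, col]
        valid &= codes[i : i + n_win] >= 0
    scores[~valid] = np.nan
    return scores


def scan(seq: str, pwm: PWM) -> ScanResult:
    """Best PWM hit over both strands plus all per-position scores.

    Positions are 0-based forward-strand window starts.  Ties break to the
    smallest start, forward strand first.  Raises if the sequence is
    shorter than the motif or no window is free of ambiguous bases.
    """
    codes = _encode(seq)
    w = pwm.width
    if codes.size < w:
        raise ValueError(f"sequence length {codes.size} < motif width {w}")
    lom = log_odds_matrix(pwm)
    fwd = _window_scores(codes, lom)
    # a reverse-strand hit at forward start i scores the reverse complement
    # of the window; equivalently score the complemented, reversed codes
    # and flip the position axis back to forward coordinates.
    rc_codes = _COMPLEMENT_INDEX[np.where(codes < 0, 0, codes)][::-1]
    rc_codes[np.asarray(codes[::-1] < 0)] = -1
    rev = _window_scores(rc_codes, lom)[::-1]

    # forward strand first, ascending starts; strict > keeps the earliest
    # hit on ties (smallest start, forward before reverse).
    best: ScanHit | None = None
    for strand, scores in (("+", fwd), ("-", rev)):
        for i, s in enumerate(scores):
            if math.isnan(s):
                continue
            if best is None or s > best.score:
                best = ScanHit(score=float(s), start=i, strand=strand)
    if best is None:
        raise ValueError("no scannable window (all windows contain ambiguous bases)")
    return ScanResult(best=best, forward_scores=fwd, reverse_scores=rev)


def allele_delta(pair: AllelePair, pwm: PWM) -> AlleleDelta:
    """Best hits on both alleles and the 129-minus-CAST score difference.

    Positive delta predicts stronger binding on the 129 allele.
    """
    best_129 = scan(pair.seq_129, pwm).best
    best_cast = scan(pair.seq_cast, pwm).best
    return AlleleDelta(
        gene=pair.gene,
        best_129=best_129,
        best_cast=best_cast,
        delta=best_129.score - best_cast.score,
    )


def read_pwm(path: str | Path, pseudocount: float = 0.01,
             background: np.ndarray | None = None) -> PWM:
    """Read a JASPAR-style plain matrix (with or without header/brackets).

    Accepts the JASPAR format (``>ID name`` header, ``A [ ... ]`` rows) and
    the bare four-row A/C/G/T matrix of counts or probabilities.
    """
    path = Path(path)
    text = path.read_text()
    fmt = "jaspar" if text.lstrip().startswith(">") or any(
        line.strip()[:1] in "ACGT" and "[" in line for line in text.splitlines()
    ) else "pfm"
    with open(path) as fh:
        motif = bio_motifs.read(fh, fmt)
    counts = np.array(
        [[motif.counts[b][i] for b in ALPHABET] for i in range(motif.length)]
    )
    return PWM.from_counts(counts, pseudocount=pseudocount, background=background)


def read_allele_pairs(path: str | Path) -> list[AllelePair]:
    """Read paired allele sequences from FASTA (record IDs ``<gene>_129`` /
    ``<gene>_CAST``); raises on unpaired or unlabeled records."""
    by_gene: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if rid.upper().endswith("_129"):
            gene, allele = rid[: -len("_129")], "129"
        elif rid.upper().endswith("_CAST"):
            gene, allele = rid[: -len("_CAST")], "CAST"
        else:
            raise ValueError(f"record {rid!r} lacks an _129/_CAST allele suffix")
        by_gene.setdefault(gene, {})[allele] = str(rec.seq)
    pairs = []
    for gene, seqs in by_gene.items():
        missing = {"129", "CAST"} - set(seqs)
        if missing:
            raise ValueError(f"gene {gene!r} missing allele sequence(s): {sorted(missing)}")
        pairs.append(AllelePair(gene=gene, seq_129=seqs["129"], seq_cast=seqs["CAST"]))
    return pairs
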