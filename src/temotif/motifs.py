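"""PWM scanning against a zero-order background with exact score p-values.

The scanner mirrors the classic motif-occurrence model: a position weight
matrix (PWM) is turned into a log-odds score matrix against a zero-order
(mononucleotide) background, per-position scores are discretized to
integers, and the exact distribution of the total integer score under the
background is obtained by dynamic programming. The p-value of a window is
the tail probability of its integer score; every reported p-value is
therefore exact up to one discretization bin. Both strands are scanned and,
by default, only the better-scoring strand at a given start is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from temotif.intervals import GenomicInterval

logger = logging.getLogger(__name__)

BASES = "ACGT"
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTacgtN", "TGCAtgcaN")


def encode(seq: str) -> np.ndarray:
    """Encode a sequence to int8 codes A=0 C=1 G=2 T=3, anything else 4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Per-position base-probability model of a TF's binding preference."""

    motif_id: str
    tf_name: str
    matrix: np.ndarray  # shape (width, 4), rows sum to 1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or self.matrix.shape[0] < 1:
            raise ValueError(f"{self.motif_id}: PWM matrix must be (w>=1, 4)")
        if (self.matrix < 0).any():
            raise ValueError(f"{self.motif_id}: negative probability")
        sums = self.matrix.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-6:
            raise ValueError(f"{self.motif_id}: rows do not sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]


@dataclass
class BackgroundModel:
    """Zero-order Markov (mononucleotide) background frequencies."""

    freqs: np.ndarray  # (A, C, G, T)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (4,):
            raise ValueError("background needs exactly 4 frequencies")
        if (self.freqs <= 0).any():
            raise ValueError("background frequencies must be positive")
        if abs(self.freqs.sum() - 1.0) > 1e-6:
            raise ValueError("background frequencies must sum to 1")

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls(np.full(4, 0.25))


def background_from_fasta(
    genome: Mapping[str, str],
    include_rc: bool = True,
    smoothing: float = 1.0,
) -> BackgroundModel:
    """Estimate the zero-order background from genome sequences.

    By default counts are pooled over both strands (a base and its
    complement contribute together), so freq(A)=freq(T) and freq(C)=freq(G);
    ambiguous bases are ignored, and add-one style smoothing keeps every
    frequency positive.
    """
    counts = np.zeros(4, dtype=np.int64)
    for chrom in sorted(genome):
        codes = encode(genome[chrom])
        counts += np.bincount(codes[codes < 4], minlength=4)
    if counts.sum() == 0:
        raise ValueError("no unambiguous bases in genome")
    counts_f = counts.astype(float) + smoothing
    if include_rc:
        counts_f = counts_f + counts_f[::-1]  # complement of code c is 3-c
    return BackgroundModel(counts_f / counts_f.sum())


@dataclass
class MotifHit:
    """One scored motif occurrence, later annotated with TE/chromatin context."""

    motif_id: str
    tf_name: str
    interval: GenomicInterval
    score: float
    pvalue: float
    te_type: Optional[str] = None
    te_family: Optional[str] = None
    ambiguous_te: bool = False

    @property
    def strand(self) -> str:
        return self.interval.strand


class ScoreMatrix:
    """Log-odds scores for a PWM plus the exact score-to-p-value table.

    ``score(i, b) = log2(((p_ib + c*bg_b) / (1 + c)) / bg_b)`` with
    pseudocount ``c`` distributed proportionally to the background. Scores
    are kept both as exact reals (reported per hit) and as a discretized
    integer copy used for the p-value dynamic program, so a window's
    p-value is exact for its integer score.
    """

    def __init__(
        self,
        pwm: PWM,
        bg: BackgroundModel,
        pseudocount: float = 0.1,
        bins: int = 1000,
    ) -> None:
        if pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if bins < 2:
            raise ValueError("need at least 2 discretization bins")
        self.motif_id = pwm.motif_id
        self.tf_name = pwm.tf_name
        self.pwm = pwm
        self.bg = bg
        self.pseudocount = float(pseudocount)
        self.bins = int(bins)
        probs = (pwm.matrix + pseudocount * bg.freqs) / (1.0 + pseudocount)
        with np.errstate(divide="ignore"):
            self.scores = np.log2(probs / bg.freqs)
        # zero-probability cells (possible only with pseudocount=0) score
        # -inf; for the integer grid they are clamped to the lowest bin
        finite = np.where(np.isfinite(self.scores), self.scores, np.nan)
        if np.isnan(finite).all():
            raise ValueError(f"{pwm.motif_id}: no finite log-odds scores")
        fmin, fmax = np.nanmin(finite), np.nanmax(finite)
        clamp = fmin - max(fmax - fmin, 1.0)
        clamped = np.where(np.isfinite(self.scores), self.scores, clamp)
        mins = clamped.min(axis=1, keepdims=True)
        ranges = clamped.max(axis=1) - mins.ravel()
        max_range = float(ranges.max())
        self.scale = (bins - 1) / max_range if max_range > 0 else 1.0
        self.int_scores = np.rint((clamped - mins) * self.scale).astype(np.int64)
        self.score_offset = float(mins.sum())  # real score of integer 0 (approx.)
        self._tail: Optional[np.ndarray] = None

    @property
    def width(self) -> int:
        return self.pwm.width

    @property
    def max_int_score(self) -> int:
        return int(self.int_scores.max(axis=1).sum())

    # -- exact p-value table ------------------------------------------------

    def build_pvalue_table(self) -> np.ndarray:
        """Exact tail distribution of the integer score under the background.

        ``tail[t]`` is the probability that ``width`` independent background
        bases produce an integer score >= t. Computed by dynamic programming
        over per-position integer score contributions.
        """
        if self._tail is not None:
            return self._tail
        pmf = np.ones(1)
        for i in range(self.width):
            new = np.zeros(len(pmf) + int(self.int_scores[i].max()))
            for b in range(4):
                off = int(self.int_scores[i, b])
                new[off : off + len(pmf)] += pmf * self.bg.freqs[b]
            pmf = new
        tail = np.minimum(np.cumsum(pmf[::-1])[::-1], 1.0)
        self._tail = tail
        return tail

    @property
    def tail(self) -> np.ndarray:
        return self.build_pvalue_table()

    def pvalue_of_int(self, t) -> np.ndarray:
        tail = self.tail
        t = np.asarray(t, dtype=np.int64)
        return np.where(t < 0, 1.0, tail[np.minimum(t, len(tail) - 1)])

    def int_score_of(self, score: float) -> int:
        """Map a real log-odds score onto the integer grid."""
        return int(np.rint((score - self.score_offset) * self.scale))

    def pvalue_of_score(self, score: float) -> float:
        return float(self.pvalue_of_int(self.int_score_of(score)))

    def cutoff_for_pvalue(self, p_threshold: float) -> Tuple[int, float]:
        """Smallest integer score with tail <= p_threshold and its tail.

        Returns ``(len(tail), 0.0)`` when no score reaches the threshold.
        """
        if not (0.0 < p_threshold < 1.0):
            raise ValueError("p_threshold must be in (0, 1)")
        tail = self.tail
        idx = int(np.searchsorted(-tail, -p_threshold, side="left"))
        attained = float(tail[idx]) if idx < len(tail) else 0.0
        return idx, attained

    def score_words(self, codes: np.ndarray) -> np.ndarray:
        """Integer scores of words given as an (n, width) code array."""
        cols = np.arange(self.width)
        return self.int_scores[cols, codes].sum(axis=1)

    def real_score_words(self, codes: np.ndarray) -> np.ndarray:
        cols = np.arange(self.width)
        return self.scores[cols, codes].sum(axis=1)


def log_odds(pwm: PWM, bg: BackgroundModel, pseudocount: float = 0.1, bins: int = 1000) -> ScoreMatrix:
    """Build the log-odds score matrix for a PWM against a background."""
    return ScoreMatrix(pwm, bg, pseudocount=pseudocount, bins=bins)


def score_pvalue_table(sm: ScoreMatrix) -> np.ndarray:
    """Build (and return) the exact integer-score tail-probability table."""
    return sm.build_pvalue_table()


# ---------------------------------------------------------------------------
# Genome scanning
# ---------------------------------------------------------------------------


def _window_int_scores(codes: np.ndarray, int_scores: np.ndarray) -> np.ndarray:
    """Total integer score of every window; N columns contribute 0."""
    w = int_scores.shape[0]
    padded = np.hstack([int_scores, np.zeros((w, 1), dtype=np.int64)])
    n_win = len(codes) - w + 1
    total = np.zeros(n_win, dtype=np.int64)
    for i in range(w):
        total += padded[i][codes[i : i + n_win]]
    return total


def scan_genome(
    genome: Mapping[str, str],
    sm: ScoreMatrix,
    p_threshold: float = 1e-4,
    max_strand: bool = True,
) -> List[MotifHit]:
    """Scan every chromosome on both strands for motif occurrences.

    Windows containing ambiguous bases are skipped. The reverse strand is
    scored with the position-reversed, base-complemented matrix (identical
    to scoring the reverse complement of the window) and shares the forward
    p-value table. With ``max_strand``, when both strands pass at the same
    start only the better-scoring strand is kept (ties keep ``+``).
    """
    cutoff, _ = sm.cutoff_for_pvalue(p_threshold)
    w = sm.width
    rc_int = sm.int_scores[::-1, ::-1]
    rc_real = sm.scores[::-1, ::-1]
    hits: List[MotifHit] = []
    for chrom in sorted(genome):
        seq = genome[chrom]
        if len(seq) < w:
            logger.info("skipping %s: shorter than motif width %d", chrom, w)
            continue
        codes = encode(seq)
        n_win = len(codes) - w + 1
        is_n = (codes >= 4).astype(np.int64)
        cn = np.concatenate([[0], np.cumsum(is_n)])
        valid = (cn[w:] - cn[:-w]) == 0
        s_f = _window_int_scores(codes, sm.int_scores)
        s_r = _window_int_scores(codes, rc_int)
        pass_f = valid & (s_f >= cutoff)
        pass_r = valid & (s_r >= cutoff)
        if max_strand:
            both = pass_f & pass_r
            pass_r = pass_r & ~(both & (s_f >= s_r))
            pass_f = pass_f & ~(both & (s_r > s_f))
        for strand, mask, ints, real in (
            ("+", pass_f, s_f, sm.scores),
            ("-", pass_r, s_r, rc_real),
        ):
            starts = np.nonzero(mask)[0]
            if len(starts) == 0:
                continue
            wins = codes[starts[:, None] + np.arange(w)]
            real_scores = real[np.arange(w), wins].sum(axis=1)
            pvals = sm.pvalue_of_int(ints[starts])
            for pos, sc, pv in zip(starts, real_scores, pvals):
                hits.append(
                    MotifHit(
                        motif_id=sm.motif_id,
                        tf_name=sm.tf_name,
                        interval=GenomicInterval(chrom, int(pos), int(pos) + w, strand),
                        score=float(sc),
                        pvalue=float(pv),
                    )
                )
    hits.sort(key=lambda h: (h.interval.chrom, h.interval.start, h.interval.strand))
    return hits


def sample_high_scoring_word(
    pwm: PWM,
    sm: ScoreMatrix,
    rng: np.random.Generator,
    max_p: float = 1e-6,
    max_tries: int = 100000,
) -> str:
    """Sample a word from the PWM until its scan p-value is <= ``max_p``.

    Rejection sampling from the motif's own distribution; used to plant
    recoverable occurrences in synthetic genomes. Because the best word's
    tail probability under the background bounds the smallest attainable
    p-value (1/4^w under a uniform background), the threshold is floored
    there for short motifs.
    """
    best_p = float(sm.pvalue_of_int(sm.max_int_score))
    max_p = max(max_p, best_p)
    cum = np.cumsum(pwm.matrix, axis=1)
    for _ in range(max_tries):
        u = rng.random(pwm.width)
        codes = (u[:, None] > cum).sum(axis=1).astype(np.int64)
        t = int(sm.score_words(codes[None, :])[0])
        if float(sm.pvalue_of_int(t)) <= max_p:
            return "".join(BASES[c] for c in codes)
    raise RuntimeError(
        f"{pwm.motif_id}: could not sample a word with p <= {max_p}; "
        "motif information content too low"
    )
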