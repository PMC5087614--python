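"""PWM promoter-motif machinery: model construction, exact score p-values,
strand-aware promoter-window extraction, scanning and enrichment.

Scores are base-2 log-odds against a background model, quantized to a fixed
lattice (``granularity`` bits).  The score -> p-value map is exact under the
background: the distribution of the total score of a random background
sequence is computed by positional convolution (dynamic programming) on the
lattice, so for short motifs it coincides with full enumeration to machine
precision.  The scanner works on the same lattice, so table lookups are exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .utils import encode_sequence, reverse_complement, CODE_TO_BASE

logger = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_PROB_FLOOR = 1e-9  # keeps log-odds finite for zero-pseudocount models


class MotifParseError(ValueError):
    pass


@dataclass
class PWMModel:
    """Position weight matrix with background model and exact p-value table.

    ``probs``: (length x 4) per-position probabilities over A,C,G,T.
    ``background``: length-4 background letter probabilities.
    """

    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.0
    granularity: float = 1e-3  # bits; lattice step of quantized scores
    name: str = "motif"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be (length, 4)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("per-position probabilities must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")
        if self.granularity <= 0:
            raise ValueError("granularity must be > 0")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @cached_property
    def log_odds(self) -> np.ndarray:
        """Base-2 log-odds, floored so impossible letters score finitely."""
        p = np.maximum(self.probs, _PROB_FLOOR)
        return np.log2(p / self.background)

    @cached_property
    def lo_int(self) -> np.ndarray:
        """Quantized log-odds in lattice units (int64)."""
        return np.round(self.log_odds / self.granularity).astype(np.int64)

    @cached_property
    def lo_int5(self) -> np.ndarray:
        """lo_int with a fifth zero column: N bases contribute background odds."""
        return np.hstack([self.lo_int, np.zeros((self.length, 1), dtype=np.int64)])

    @cached_property
    def _tail(self) -> tuple[int, np.ndarray]:
        return _score_tail_distribution(self.lo_int, self.background)

    def pvalue_table(self) -> pd.DataFrame:
        """All achievable lattice scores (in bits) and P(score >= s) under background."""
        min_int, tail = self._tail
        scores = (np.arange(len(tail)) + min_int) * self.granularity
        return pd.DataFrame({"score": scores, "p_value": tail})

    def pvalue_int(self, score_int: np.ndarray | int) -> np.ndarray | float:
        """Exact tail p-value for quantized scores (lattice units)."""
        min_int, tail = self._tail
        idx = np.clip(np.asarray(score_int) - min_int, 0, len(tail) - 1)
        out = tail[idx]
        out = np.where(np.asarray(score_int) > min_int + len(tail) - 1, 0.0, out)
        out = np.where(np.asarray(score_int) < min_int, 1.0, out)
        return float(out) if np.isscalar(score_int) else out

    def pvalue(self, score: float) -> float:
        return float(self.pvalue_int(int(round(score / self.granularity))))

    def score_threshold_int(self, p_threshold: float) -> int:
        """Smallest lattice score whose tail p-value is <= p_threshold."""
        min_int, tail = self._tail
        idx = np.nonzero(tail <= p_threshold)[0]
        if len(idx) == 0:
            return min_int + len(tail)  # unreachable: no score passes
        return min_int + int(idx[0])

    def sample(self, rng: np.random.Generator) -> str:
        """Draw one motif instance from the per-position probabilities."""
        letters = [rng.choice(4, p=self.probs[k] / self.probs[k].sum())
                   for k in range(self.length)]
        return "".join(CODE_TO_BASE[a] for a in letters)

    def reverse_complement(self) -> "PWMModel":
        return PWMModel(
            probs=self.probs[::-1, ::-1].copy(),
            background=self.background.copy(),
            pseudocount=self.pseudocount,
            granularity=self.granularity,
            name=self.name + "_rc",
        )


def _score_tail_distribution(lo_int: np.ndarray, background: np.ndarray) -> tuple[int, np.ndarray]:
    """DP convolution of the lattice score distribution of a random background
    sequence; returns (minimum achievable total, upper-tail array)."""
    dist = np.array([1.0])
    cur_min = 0
    for k in range(lo_int.shape[0]):
        row = lo_int[k]
        lo, hi = int(row.min()), int(row.max())
        new = np.zeros(len(dist) + hi - lo)
        for a in range(4):
            off = int(row[a]) - lo
            new[off: off + len(dist)] += background[a] * dist
        dist = new
        cur_min += lo
    tail = np.cumsum(dist[::-1])[::-1]
    return cur_min, np.minimum(tail, 1.0)


def build_pwm(
    source,
    pseudocount: float = 0.0,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    granularity: float = 1e-3,
    name: Optional[str] = None,
) -> PWMModel:
    """Build a PWM from an IUPAC consensus string, a site alignment (list of
    equal-length sequences), or a minimal-MEME file path.

    Probabilities are letter frequencies plus ``pseudocount``; IUPAC degeneracy
    codes expand to uniform mass over their letter sets.
    """
    bg = np.asarray(background, dtype=float)
    if isinstance(source, (str, bytes)) and "\n" not in str(source) and str(source).endswith((".meme", ".txt")):
        from .io import read_meme_motif

        return read_meme_motif(source, granularity=granularity)
    if isinstance(source, str):
        rows = [source.upper()]
    else:
        rows = [s.upper() for s in source]
        if len({len(r) for r in rows}) != 1:
            raise MotifParseError("alignment rows must have equal length")
    length = len(rows[0])
    counts = np.zeros((length, 4))
    code = {b: i for i, b in enumerate("ACGT")}
    for row in rows:
        for k, letter in enumerate(row):
            letters = IUPAC.get(letter)
            if letters is None:
                raise MotifParseError(f"invalid IUPAC letter {letter!r} at position {k}")
            for b in letters:
                counts[k, code[b]] += 1.0 / len(letters)
    probs = (counts + pseudocount) / (counts.sum(axis=1, keepdims=True) + 4 * pseudocount)
    return PWMModel(probs=probs, background=bg, pseudocount=pseudocount,
                    granularity=granularity, name=name or "consensus")


def score_pvalue_table(pwm: PWMModel, granularity: Optional[float] = None) -> pd.DataFrame:
    """Exact score -> p-value table (see :meth:`PWMModel.pvalue_table`)."""
    if granularity is not None and granularity != pwm.granularity:
        pwm = PWMModel(pwm.probs, pwm.background, pwm.pseudocount, granularity, pwm.name)
    return pwm.pvalue_table()


@dataclass
class PromoterWindow:
    """A strand-aware promoter interval around a TSS/TFE anchor, with its
    sequence reported 5'->3' (reverse-complemented for minus-strand anchors)."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start:
            raise ValueError(f"window {self.id}: sequence length mismatch")


@dataclass
class MotifHit:
    window_id: str
    offset: int  # 0-based offset within the window's 5'->3' sequence
    strand: str  # strand of the match relative to the window sequence
    score: float  # log-odds, bits
    p_value: float


def extract_promoters(
    anchors: Iterable,
    genome,
    upstream: int = 2000,
    downstream: int = 500,
) -> list[PromoterWindow]:
    """Extract -upstream/+downstream windows around anchors.

    ``anchors``: TFERecords (anchored at the peak) or (id, chrom, pos, strand)
    tuples.  ``genome``: mapping chrom -> sequence (str or pyfaidx record).
    Plus-strand anchor at t gives [t-upstream, t+downstream); minus-strand
    gives [t-downstream+1, t+upstream+1) reported as reverse complement.
    Windows are clipped at contig edges with a logged warning.
    """
    windows = []
    for anchor in anchors:
        if hasattr(anchor, "peak"):
            aid, chrom, pos, strand = anchor.id, anchor.chrom, anchor.peak, anchor.strand
        else:
            aid, chrom, pos, strand = anchor
        if chrom not in genome:
            raise KeyError(f"anchor {aid}: contig {chrom!r} not in genome")
        contig = genome[chrom]
        clen = len(contig)
        if strand == "+":
            start, end = pos - upstream, pos + downstream
        elif strand == "-":
            start, end = pos - downstream + 1, pos + upstream + 1
        else:
            raise ValueError(f"anchor {aid}: bad strand {strand!r}")
        cstart, cend = max(0, start), min(clen, end)
        if (cstart, cend) != (start, end):
            logger.warning(
                "promoter window for %s clipped to [%d, %d) at contig edge", aid, cstart, cend
            )
        seq = str(contig[cstart:cend]).upper()
        if strand == "-":
            seq = reverse_complement(seq)
        windows.append(PromoterWindow(aid, chrom, cstart, cend, strand, seq))
    return windows


def _window_scores(codes: np.ndarray, lo5: np.ndarray) -> np.ndarray:
    """Quantized sliding-window scores at every offset of an encoded sequence."""
    m = lo5.shape[0]
    w = len(codes) - m + 1
    if w <= 0:
        return np.empty(0, dtype=np.int64)
    scores = np.zeros(w, dtype=np.int64)
    for k in range(m):
        scores += lo5[k][codes[k: k + w]]
    return scores


def scan_window(
    window: PromoterWindow | str,
    pwm: PWMModel,
    p_threshold: float = 1e-4,
) -> list[MotifHit]:
    """Scan both strands of a window at every offset; a hit is any position
    whose exact score p-value is <= ``p_threshold``.  Ambiguous bases score
    as background (zero log-odds contribution).  A window shorter than the
    motif yields no hits."""
    if isinstance(window, str):
        window = PromoterWindow("window", "na", 0, len(window), "+", window)
    codes = encode_sequence(window.sequence)
    thr = pwm.score_threshold_int(p_threshold)
    rc = pwm.reverse_complement()
    hits = []
    for strand, model in (("+", pwm), ("-", rc)):
        scores = _window_scores(codes, model.lo_int5)
        for off in np.nonzero(scores >= thr)[0]:
            s_int = int(scores[off])
            hits.append(
                MotifHit(
                    window_id=window.id,
                    offset=int(off),
                    strand=strand,
                    score=s_int * pwm.granularity,
                    p_value=float(pwm.pvalue_int(s_int)),
                )
            )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


@dataclass
class EnrichmentReport:
    n_windows: int
    target_hits: int
    control_hits: int
    target_windows_with_hit: int
    control_windows_with_hit: int
    chi2_stat: float
    p_value: float
    hit_rate_ratio: float
    sweep: pd.DataFrame  # cumulative windows-with-hit and hit counts per threshold
    second_control: Optional["EnrichmentReport"] = None

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "n_windows", "target_hits", "control_hits",
                "target_windows_with_hit", "control_windows_with_hit",
                "chi2_stat", "p_value", "hit_rate_ratio",
            )
        }
        if self.second_control is not None:
            d["second_control"] = self.second_control.to_dict()
        return d


def _best_scores(windows: Sequence[PromoterWindow], pwm: PWMModel) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-window arrays of both-strand scores and the per-window maximum."""
    rc = pwm.reverse_complement()
    all_scores, best = [], []
    for w in windows:
        codes = encode_sequence(w.sequence if not isinstance(w, str) else w)
        s = np.concatenate([_window_scores(codes, pwm.lo_int5),
                            _window_scores(codes, rc.lo_int5)])
        all_scores.append(s)
        best.append(s.max() if len(s) else np.iinfo(np.int64).min)
    return all_scores, np.asarray(best)


def motif_enrichment(
    target_windows: Sequence[PromoterWindow],
    control_windows: Sequence[PromoterWindow],
    pwm: PWMModel,
    p_threshold: float = 1e-4,
    seed: int = 0,
    sweep_thresholds: Sequence[float] = tuple(np.logspace(-8, -2, 13)),
    second_control: Optional[Sequence[PromoterWindow]] = None,
) -> EnrichmentReport:
    """Motif enrichment in target promoters versus an equal-size control set.

    Sizes are equalized by seeded down-sampling of the larger set (mirroring
    the use of "an equal number" of control start sites).  The primary test is
    chi-squared (1 df, no continuity correction) on the windows-with->=1-hit
    2x2 table; raw hit totals and a threshold sweep of cumulative counts are
    reported descriptively.
    """
    if len(control_windows) == 0:
        raise ValueError("empty control window set")
    if len(target_windows) == 0:
        raise ValueError("empty target window set")
    rng = np.random.default_rng(seed)
    targets, controls = list(target_windows), list(control_windows)
    n = min(len(targets), len(controls))
    if len(targets) > n:
        targets = [targets[i] for i in sorted(rng.choice(len(targets), n, replace=False))]
    if len(controls) > n:
        controls = [controls[i] for i in sorted(rng.choice(len(controls), n, replace=False))]

    t_scores, t_best = _best_scores(targets, pwm)
    c_scores, c_best = _best_scores(controls, pwm)
    thr = pwm.score_threshold_int(p_threshold)

    t_hits = int(sum((s >= thr).sum() for s in t_scores))
    c_hits = int(sum((s >= thr).sum() for s in c_scores))
    t_with = int((t_best >= thr).sum())
    c_with = int((c_best >= thr).sum())

    table = np.array([[t_with, n - t_with], [c_with, n - c_with]], dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    exp = row * col / table.sum()
    if (exp == 0).any():
        stat, p = 0.0, 1.0
    else:
        stat = float(((table - exp) ** 2 / exp).sum())
        p = float(chi2.sf(stat, df=1))

    sweep_rows = []
    for pt in sorted(sweep_thresholds):
        th = pwm.score_threshold_int(pt)
        sweep_rows.append(
            {
                "p_threshold": pt,
                "target_hits": int(sum((s >= th).sum() for s in t_scores)),
                "control_hits": int(sum((s >= th).sum() for s in c_scores)),
                "target_windows_with_hit": int((t_best >= th).sum()),
                "control_windows_with_hit": int((c_best >= th).sum()),
            }
        )
    report = EnrichmentReport(
        n_windows=n,
        target_hits=t_hits,
        control_hits=c_hits,
        target_windows_with_hit=t_with,
        control_windows_with_hit=c_with,
        chi2_stat=stat,
        p_value=p,
        hit_rate_ratio=(t_hits / c_hits) if c_hits else float("inf"),
        sweep=pd.DataFrame(sweep_rows),
    )
    if second_control is not None:
        report.second_control = motif_enrichment(
            target_windows, second_control, pwm, p_threshold=p_threshold, seed=seed + 1,
            sweep_thresholds=sweep_thresholds,
        )
    return report
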