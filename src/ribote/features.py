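"""Per-gene 5'-UTR and start-codon features correlated with delta-TE.

Windows are in transcript coordinates (0-based half-open). A PARS window
statistic is missing whenever the window is not fully contained in its
allowed region or contains any missing value. The start-codon context
covers nt -6..+4 around the AUG (the A of AUG is +1); the context score
sums log2-odds over the seven non-AUG positions.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import AnnotationSet, TranscriptModel

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
CONTEXT_UPSTREAM = 6   # nt -6..-1
CONTEXT_DOWNSTREAM = 4  # nt +1..+4 (AUG + one)
CONTEXT_WIDTH = CONTEXT_UPSTREAM + CONTEXT_DOWNSTREAM
_AUG_POSITIONS = (6, 7, 8)  # indices of the AUG inside the 10-nt window

PARS_WINDOWS = ("utr_all", "first30", "start30", "plus30", "max30")
WINDOW_NT = 30


# ---------------------------------------------------------------------------
# PARS window statistics


def _window_mean(track: np.ndarray, start: int, end: int, limit: int) -> float:
    """Mean of track[start:end]; missing unless [start, end) fits in [0, limit)
    and contains no missing value."""
    if start < 0 or end > limit or end <= start:
        return np.nan
    window = track[start:end]
    if np.isnan(window).any():
        return np.nan
    return float(window.mean())


def pars_window_stat(track: np.ndarray, model: TranscriptModel, window: str,
                     start30_offset: int = WINDOW_NT // 2) -> float:
    """One of the five PARS window statistics for a transcript.

    - ``utr_all``: mean over the whole TL ``[0, tl)``
    - ``first30``: mean over the first 30 nt of the TL
    - ``start30``: mean over 30 nt centered on the start codon,
      ``[cds_start - offset, cds_start - offset + 30)`` (offset 15 by default)
    - ``plus30``: the 30 nt immediately downstream of the start30 window
    - ``max30``: max over every 30-nt window fully inside the TL, step 1 nt
    """
    track = np.asarray(track, dtype=float)
    if len(track) != model.transcript_length:
        raise ValueError(
            f"{model.transcript_id}: track length {len(track)} != "
            f"transcript length {model.transcript_length}"
        )
    tl = model.tl_length
    n = model.transcript_length
    if window == "utr_all":
        return _window_mean(track, 0, tl, tl)
    if window == "first30":
        return _window_mean(track, 0, WINDOW_NT, tl)
    if window == "start30":
        start = model.cds_start - start30_offset
        return _window_mean(track, start, start + WINDOW_NT, n)
    if window == "plus30":
        start = model.cds_start - start30_offset + WINDOW_NT
        return _window_mean(track, start, start + WINDOW_NT, n)
    if window == "max30":
        if tl < WINDOW_NT:
            return np.nan
        utr = track[:tl]
        if np.isnan(utr).all():
            return np.nan
        # sliding means; windows containing NaN are excluded individually
        views = np.lib.stride_tricks.sliding_window_view(utr, WINDOW_NT)
        means = np.where(np.isnan(views).any(axis=1), np.nan, views.mean(axis=1))
        if np.isnan(means).all():
            return np.nan
        return float(np.nanmax(means))
    raise ValueError(f"unknown window {window!r}; choose from {PARS_WINDOWS}")


# ---------------------------------------------------------------------------
# Start-codon (Kozak) context


def extract_context_window(sequence: str, model: TranscriptModel) -> str | None:
    """The -6..+4 window around the start codon, or None if the TL is
    shorter than 6 nt or the window runs off the transcript."""
    if model.tl_length < CONTEXT_UPSTREAM:
        return None
    start = model.cds_start - CONTEXT_UPSTREAM
    end = model.cds_start + CONTEXT_DOWNSTREAM
    if end > len(sequence):
        return None
    return sequence[start:end].upper().replace("U", "T")


@dataclass(frozen=True)
class ContextPwm:
    """Log2-odds position weight matrix over the 10-nt context window.

    ``log_odds[j, b]`` scores base ``BASES[b]`` at window position ``j``;
    AUG core positions score 0 by construction. Background frequencies are
    the pooled base composition of the input windows' -6..-1 positions.
    """

    log_odds: np.ndarray            # (10, 4)
    probabilities: np.ndarray       # (10, 4), columns sum to 1
    background: np.ndarray          # (4,)
    n_sequences: int

    def score(self, window: str) -> float:
        """Sum of per-position log2-odds, skipping the AUG core."""
        if len(window) != CONTEXT_WIDTH:
            raise ValueError(f"context window must be {CONTEXT_WIDTH} nt")
        total = 0.0
        for j, base in enumerate(window.upper().replace("U", "T")):
            if j in _AUG_POSITIONS:
                continue
            if base not in _BASE_INDEX:
                return np.nan
            total += self.log_odds[j, _BASE_INDEX[base]]
        return total


def build_context_pwm(windows: list[str]) -> ContextPwm:
    """Pseudocounted log2-odds PWM from a set of -6..+4 windows.

    Windows whose +1..+3 core is not AUG are rejected (logged). Counts get
    a pseudocount of 1 per base per position; the background is the pooled
    base composition of the accepted windows' upstream (-6..-1) positions.
    """
    counts = np.zeros((CONTEXT_WIDTH, 4))
    n_used = 0
    for w in windows:
        w = w.upper().replace("U", "T")
        if len(w) != CONTEXT_WIDTH:
            logger.warning("context window %r rejected: wrong length", w)
            continue
        if w[6:9] != "ATG":
            logger.warning("context window %r rejected: core is not AUG", w)
            continue
        if any(b not in _BASE_INDEX for b in w):
            logger.warning("context window %r rejected: non-ACGT base", w)
            continue
        for j, base in enumerate(w):
            counts[j, _BASE_INDEX[base]] += 1
        n_used += 1
    if n_used == 0:
        raise ValueError("no valid context windows to build a PWM from")

    prob = (counts + 1.0) / (counts.sum(axis=1, keepdims=True) + 4.0)
    upstream = counts[:CONTEXT_UPSTREAM].sum(axis=0)
    background = (upstream + 1.0) / (upstream.sum() + 4.0)
    log_odds = np.log2(prob / background)
    log_odds[list(_AUG_POSITIONS)] = 0.0
    return ContextPwm(log_odds=log_odds, probabilities=prob,
                      background=background, n_sequences=n_used)


def context_score(sequence: str, model: TranscriptModel, pwm: ContextPwm) -> float:
    """PWM score of a transcript's start-codon context; NaN when the TL is
    shorter than 6 nt."""
    if len(sequence) != model.transcript_length:
        raise ValueError(
            f"{model.transcript_id}: sequence length {len(sequence)} != "
            f"annotated transcript length {model.transcript_length}"
        )
    window = extract_context_window(sequence, model)
    if window is None:
        return np.nan
    return pwm.score(window)


def sequence_logo_matrix(windows: list[str]) -> pd.DataFrame:
    """Per-position base frequencies and information content (bits).

    IC_j = 2 + sum_b p_bj log2 p_bj, with raw frequencies (no pseudocount,
    no small-sample correction); zero frequencies contribute zero entropy.
    """
    if not windows:
        raise ValueError("sequence_logo_matrix: empty window set")
    counts = np.zeros((CONTEXT_WIDTH, 4))
    for w in windows:
        w = w.upper().replace("U", "T")
        if len(w) != CONTEXT_WIDTH:
            raise ValueError(f"window {w!r} is not {CONTEXT_WIDTH} nt")
        for j, base in enumerate(w):
            if base in _BASE_INDEX:
                counts[j, _BASE_INDEX[base]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValueError("a position has no countable bases")
    freq = counts / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    out = pd.DataFrame(freq, columns=list(BASES))
    out["information_bits"] = ic
    out.index = list(range(-CONTEXT_UPSTREAM, 0)) + list(range(1, CONTEXT_DOWNSTREAM + 1))
    out.index.name = "position"
    return out


# ---------------------------------------------------------------------------
# uORFs and the assembled feature table


def uorf_cap_distance(model: TranscriptModel) -> list[tuple[str, int]]:
    """(uorf_id, distance from the transcript 5' end) per uORF, in
    annotation order."""
    return [(u.uorf_id, u.start) for u in model.uorfs]


def build_feature_table(ann: AnnotationSet,
                        sequences: dict[str, str],
                        pars: dict[str, np.ndarray] | None = None,
                        dominant_tl: dict[str, int | None] | None = None,
                        closed_loop: dict[str, int] | None = None,
                        pwm: ContextPwm | None = None,
                        start30_offset: int = WINDOW_NT // 2) -> pd.DataFrame:
    """Assemble the per-gene feature table.

    ``tl_length`` comes from the dominant-isoform map when given (missing
    for genes without a dominant isoform); otherwise from the annotation.
    The context PWM defaults to one built from this annotation set's own
    context windows.
    """
    if pwm is None:
        windows = []
        for t in ann:
            seq = sequences.get(t.transcript_id)
            if seq is None:
                continue
            w = extract_context_window(seq, t)
            if w is not None:
                windows.append(w)
        pwm = build_context_pwm(windows)

    rows = []
    for t in ann:
        gene = t.gene_id
        if dominant_tl is not None:
            tl = dominant_tl.get(gene)
            tl_length = float(tl) if tl is not None else np.nan
        else:
            tl_length = float(t.tl_length)
        row = {
            "gene_id": gene,
            "tl_length": tl_length,
            "cds_length": t.cds_length,
            "transcript_length": t.transcript_length,
            "n_uorfs": len(t.uorfs),
            "first_uorf_cap_distance": (t.uorfs[0].start if t.uorfs else np.nan),
        }
        seq = sequences.get(t.transcript_id)
        row["context_score"] = (context_score(seq, t, pwm)
                                if seq is not None else np.nan)
        if pars is not None and t.transcript_id in pars:
            track = pars[t.transcript_id]
            for window in PARS_WINDOWS:
                row[f"pars_{window}"] = pars_window_stat(
                    track, t, window, start30_offset=start30_offset)
        else:
            for window in PARS_WINDOWS:
                row[f"pars_{window}"] = np.nan
        row["closed_loop_group"] = (closed_loop.get(gene, np.nan)
                                    if closed_loop is not None else np.nan)
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id").sort_index()
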