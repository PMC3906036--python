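"""Degradation diagnostics for 3'-biased arrays.

Two complementary views of RNA degradation:

* :func:`degradation_profile` — the classic RNA-degradation plot: probe
  intensities averaged by position within the vendor probeset (5'->3'),
  one line per array.  Fragmented RNA loses 5' signal, so the steeper the
  line the more degraded the sample; FFPE arrays are expected to be much
  steeper than matched frozen arrays.
* :func:`correlation_vs_distance` — the probe-level frozen-FFPE
  correlation as a function of the probe's distance from the transcript
  3' end.  Decay makes distant probes unreliable on FFPE material, so the
  curve falls with distance and flattens once probes are essentially all
  background (around twice the decay scale).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cdf import ChipDescription, ProbeHit
from .errors import ValidationError


@dataclass
class DegradationProfile:
    """Mean log2 intensity by within-probeset probe rank (5'->3'), per sample."""

    rank_means: pd.DataFrame  # rank (1-based) x sample
    slopes: pd.Series  # per-sample least-squares slope over rank
    probe_count: int
    n_probesets: int


@dataclass
class DistanceCorrelationCurve:
    """Frozen-FFPE Pearson r by 3'-distance bin."""

    bin_edges: np.ndarray
    r: np.ndarray  # NaN where a bin is empty
    counts: np.ndarray
    pooling: str

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "r": self.r,
                "count": self.counts,
            }
        )


def degradation_profile(
    intensities: pd.DataFrame, standard_cd: ChipDescription
) -> DegradationProfile:
    """RNA-degradation plot data from a vendor chip description.

    Only probesets sharing the most common probe count contribute (others
    are skipped with a warning), so ranks are comparable across probesets.
    """
    counts = Counter(len(m) for m in standard_cd.probesets.values())
    if not counts:
        raise ValidationError("chip description has no probesets")
    common = max(counts, key=lambda c: (counts[c], c))
    skipped = sum(v for c, v in counts.items() if c != common)
    if skipped:
        warnings.warn(
            f"{skipped} probesets without the common probe count ({common}) skipped"
        )
    used = [m for m in standard_cd.probesets.values() if len(m) == common]
    if not used:
        raise ValidationError("no probeset with the common probe count")
    for members in used:
        missing = [p for p in members if p not in intensities.index]
        if missing:
            raise ValidationError(f"probe {missing[0]!r} missing from intensity matrix")

    logged = np.log2(intensities.to_numpy(dtype=float))
    pos = {p: i for i, p in enumerate(intensities.index)}
    stack = np.stack([logged[[pos[p] for p in members], :] for members in used])
    rank_means = stack.mean(axis=0)  # rank x sample
    ranks = np.arange(1, common + 1)
    slopes = np.polyfit(ranks, rank_means, deg=1)[0]
    return DegradationProfile(
        rank_means=pd.DataFrame(
            rank_means, index=pd.Index(ranks, name="rank"), columns=intensities.columns
        ),
        slopes=pd.Series(slopes, index=intensities.columns, name="slope"),
        probe_count=common,
        n_probesets=len(used),
    )


def fit_decay_scale(
    frozen: pd.DataFrame,
    ffpe: pd.DataFrame,
    hits: Sequence[ProbeHit],
    pairs: Sequence[tuple[str, str]],
    max_distance: int = 300,
    background_correct: bool = True,
) -> float:
    """Estimate the exponential 3'-decay scale (bp) from matched arrays.

    Under multiplicative decay ``exp(-d / lambda)`` the mean per-probe
    log2 frozen/FFPE ratio grows linearly in the 3' distance ``d`` with
    slope ``log2(e) / lambda``.  Probes beyond ``max_distance`` are
    excluded (they sit near the optical background, which flattens the
    ratio), and both matrices are background-corrected first by default
    for the same reason.
    """
    from .normalization import rma_background_correct  # local: avoid cycle

    f_cols = [f for f, _ in pairs]
    p_cols = [p for _, p in pairs]
    usable = [h for h in hits if h.three_prime_distance <= max_distance]
    if len(usable) < 3:
        raise ValidationError("need at least 3 probes within max_distance")
    F = frozen.loc[[h.probe_id for h in usable], f_cols].to_numpy(dtype=float)
    P = ffpe.loc[[h.probe_id for h in usable], p_cols].to_numpy(dtype=float)
    if background_correct:
        F = np.column_stack([rma_background_correct(F[:, j]) for j in range(F.shape[1])])
        P = np.column_stack([rma_background_correct(P[:, j]) for j in range(P.shape[1])])
    ratio = (np.log2(F) - np.log2(P)).mean(axis=1)
    d = np.array([h.three_prime_distance for h in usable], dtype=float)
    slope = float(np.polyfit(d, ratio, 1)[0])
    if slope <= 0:
        raise ValidationError("no positive decay trend; cannot estimate a decay scale")
    return float(np.log2(np.e) / slope)


def correlation_vs_distance(
    frozen: pd.DataFrame,
    ffpe: pd.DataFrame,
    hits: Sequence[ProbeHit],
    pairs: Sequence[tuple[str, str]],
    bin_edges: np.ndarray | None = None,
    pooling: str = "probes",
) -> DistanceCorrelationCurve:
    """Frozen-FFPE probe-level correlation as a function of 3' distance.

    ``pairs`` lists (frozen sample, FFPE sample) matched columns.  With
    the default ``pooling='probes'`` each probe's r is computed across the
    matched pairs and probe r values are averaged within a distance bin —
    robust to probe-affinity differences.  ``pooling='probesxpairs'``
    pools all (probe, pair) points in a bin into one correlation.
    """
    if pooling not in {"probes", "probesxpairs"}:
        raise ValidationError(f"unknown pooling {pooling!r}")
    if bin_edges is None:
        bin_edges = np.arange(0, 625, 25)
    bin_edges = np.asarray(bin_edges, dtype=float)
    f_cols = [f for f, _ in pairs]
    p_cols = [p for _, p in pairs]
    usable = [h for h in hits if h.probe_id in frozen.index and h.probe_id in ffpe.index]
    if not usable:
        raise ValidationError("no hit probe present in both matrices")

    F = np.log2(frozen.loc[[h.probe_id for h in usable], f_cols].to_numpy(dtype=float))
    P = np.log2(ffpe.loc[[h.probe_id for h in usable], p_cols].to_numpy(dtype=float))
    d = np.array([h.three_prime_distance for h in usable], dtype=float)

    nbins = len(bin_edges) - 1
    r_out = np.full(nbins, np.nan)
    counts = np.zeros(nbins, dtype=int)
    which = np.digitize(d, bin_edges) - 1  # right-open bins

    if pooling == "probes":
        # per-probe correlation across pairs, then bin averages
        fc = F - F.mean(axis=1, keepdims=True)
        pc = P - P.mean(axis=1, keepdims=True)
        denom = np.sqrt((fc**2).sum(axis=1) * (pc**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            probe_r = (fc * pc).sum(axis=1) / denom
        for b in range(nbins):
            mask = (which == b) & np.isfinite(probe_r)
            counts[b] = int(np.sum(which == b))
            if mask.any():
                r_out[b] = float(np.mean(probe_r[mask]))
    else:
        for b in range(nbins):
            mask = which == b
            counts[b] = int(mask.sum())
            if counts[b] == 0:
                continue
            x = F[mask].ravel()
            y = P[mask].ravel()
            if x.size >= 2 and np.std(x) > 0 and np.std(y) > 0:
                r_out[b] = float(np.corrcoef(x, y)[0, 1])
    return DistanceCorrelationCurve(bin_edges, r_out, counts, pooling)
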