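"""Low-depth CNV calling: a 3-state HMM over binned depth log-ratios.

Used for low-coverage verification cohorts where allelic information is too
sparse for the joint model: bins are median-centered and segmented into
DEL / NEUT / AMP by a Gaussian-emission HMM with a shared, data-estimated sd.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genome import BinDepth
from .hmm import forward_backward, structured_transition, viterbi

CALLS = ("DEL", "NEUT", "AMP")
DEFAULT_MEANS = (-0.5, 0.0, 0.35)
#: Viterbi tie preference: NEUT first (conservative), then DEL, then AMP
_PREF = np.array([1, 0, 2])


@dataclass
class CnvSegment:
    chrom: str
    start: int
    end: int
    call: str
    median_log_ratio: float
    n_bins: int


@dataclass
class DepthHmmResult:
    path: np.ndarray         # per-bin state index into CALLS
    posteriors: np.ndarray   # (n_bins, 3), rows sum to 1
    log_likelihood: float
    state_means: tuple[float, float, float]
    state_sd: float
    self_transition: float


def normalize_depth(bins: list[BinDepth]) -> list[BinDepth]:
    """Median-center the log-ratio track (output median exactly 0)."""
    if not bins:
        raise ValueError("no bins to normalize")
    med = float(np.median([b.log_ratio for b in bins]))
    return [b._replace(log_ratio=b.log_ratio - med) for b in bins]


def estimate_sd(values: np.ndarray, floor: float = 0.01) -> float:
    """Robust emission sd from the central 50% of bins (IQR / 1.349)."""
    q75, q25 = np.percentile(values, [75, 25])
    return max((q75 - q25) / 1.349, floor)


def _group_by_chrom(bins: list[BinDepth]) -> list[tuple[int, int]]:
    ranges = []
    start = 0
    for i in range(1, len(bins) + 1):
        if i == len(bins) or bins[i].chrom != bins[start].chrom:
            ranges.append((start, i))
            start = i
    return ranges


def fit_depth_hmm(
    bins: list[BinDepth],
    self_transition: float = 0.995,
    state_means: tuple[float, float, float] = DEFAULT_MEANS,
    state_sd: float | None = None,
) -> DepthHmmResult:
    """Posterior state probabilities and Viterbi path per chromosome.

    ``state_means`` must be strictly increasing (DEL < NEUT < AMP); the shared
    emission sd defaults to a method-of-moments estimate from the central 50%
    of bins.  Chromosomes are independent chains; a chromosome with a single
    bin gets a single-state call with no transition contribution.
    """
    if not 0.0 < self_transition < 1.0:
        raise ValueError("self_transition must be in (0, 1)")
    means = np.asarray(state_means, float)
    if not (means[0] < means[1] < means[2]):
        raise ValueError("state means must be strictly increasing (DEL < NEUT < AMP)")
    x = np.array([b.log_ratio for b in bins], float)
    sd = float(state_sd) if state_sd is not None else estimate_sd(x[np.isfinite(x)])

    log_emit = np.zeros((len(x), 3))
    finite = np.isfinite(x)
    log_emit[finite] = (
        -0.5 * ((x[finite, None] - means[None, :]) / sd) ** 2
        - math.log(sd * math.sqrt(2 * math.pi))
    )
    trans = structured_transition(3, self_transition)
    path = np.empty(len(x), dtype=np.int32)
    post = np.empty((len(x), 3))
    ll = 0.0
    for lo, hi in _group_by_chrom(bins):
        post[lo:hi], l = forward_backward(log_emit[lo:hi], trans)
        path[lo:hi], _ = viterbi(log_emit[lo:hi], trans, pref=_PREF)
        ll += l
    return DepthHmmResult(path, post, float(ll), tuple(means), sd, self_transition)


def segments_from_path(path: np.ndarray, bins: list[BinDepth]) -> list[CnvSegment]:
    """Maximal same-call runs per chromosome (run-length encoding)."""
    if len(path) != len(bins):
        raise ValueError("path length must equal bin count")
    segs: list[CnvSegment] = []
    for lo, hi in _group_by_chrom(bins):
        b = lo
        while b < hi:
            e = b
            while e + 1 < hi and path[e + 1] == path[b]:
                e += 1
            values = [bins[i].log_ratio for i in range(b, e + 1)]
            segs.append(
                CnvSegment(
                    chrom=bins[b].chrom,
                    start=bins[b].start,
                    end=bins[e].end,
                    call=CALLS[int(path[b])],
                    median_log_ratio=float(np.median(values)),
                    n_bins=e - b + 1,
                )
            )
            b = e + 1
    return segs


def call_cnv(bins: list[BinDepth], **hmm_kwargs) -> list[CnvSegment]:
    """Convenience pipeline: median-center, fit the HMM, segment."""
    normed = normalize_depth(bins)
    result = fit_depth_hmm(normed, **hmm_kwargs)
    return segments_from_path(result.path, normed)
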