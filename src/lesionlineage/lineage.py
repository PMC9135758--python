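"""Cross-lesion lineage deconstruction.

Two complementary lines of evidence decide whether paired lesions share a
cancer-initiating clone:

1. genome-wide Pearson correlation of the per-bin copy-number profiles
   (the > 0.8 pattern of parallel pairs), and
2. same-locus / same-type sharing of subclonal CNV/LOH features between
   every cluster pair of the two lesions.

The decision rule is disjunctive — a pair is called ``parallel`` when either
the correlation exceeds its threshold or the best cluster pair's shared
fraction does — because a pair can lack global CNV similarity yet share a
founder's features in one small subclone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .clonal_inference import TypedSegment
from .genome import GenomeLayout


class UndefinedCorrelationError(ValueError):
    """Raised when a profile has zero variance (correlation undefined)."""


def cnv_correlation(profile_a: np.ndarray, profile_b: np.ndarray) -> float:
    """Pearson product-moment correlation of two equal-length per-bin profiles."""
    a = np.asarray(profile_a, float)
    b = np.asarray(profile_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("profiles must be equal-length 1-D arrays")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError("constant profile: correlation undefined")
    return float(stats.pearsonr(a, b).statistic)


def copy_number_profile(
    segments: list[TypedSegment], layout: GenomeLayout
) -> np.ndarray:
    """Per-bin MAP total copy number from typed segments (2 where uncovered)."""
    prof = np.full(layout.n_bins, 2.0)
    for seg in segments:
        lo = layout.bin_index(seg.chrom, seg.start)
        hi = layout.bin_index(seg.chrom, seg.end - 1) + 1
        prof[lo:hi] = seg.genotype.c
    return prof


def _rasterize(segments: list[TypedSegment], layout: GenomeLayout):
    labels = np.full(layout.n_bins, "HET", dtype=object)
    clusters = np.zeros(layout.n_bins, dtype=np.int64)
    for seg in segments:
        lo = layout.bin_index(seg.chrom, seg.start)
        hi = layout.bin_index(seg.chrom, seg.end - 1) + 1
        labels[lo:hi] = seg.genotype.loh_label
        clusters[lo:hi] = seg.cluster
    return labels, clusters


@dataclass
class PairShare:
    cluster_a: int
    cluster_b: int
    n_shared: int
    n_unique_a: int
    n_unique_b: int

    @property
    def shared_fraction(self) -> float:
        total = self.n_shared + self.n_unique_a + self.n_unique_b
        return self.n_shared / total if total else 0.0


@dataclass
class SharedFeatureReport:
    """Per cluster-pair counts of same-locus / same-type altered bins."""

    pairs: list[PairShare]
    top_pair: PairShare | None
    empty: bool = False

    @property
    def top_shared_fraction(self) -> float:
        return self.top_pair.shared_fraction if self.top_pair else 0.0


def shared_feature_analysis(
    segments_a: list[TypedSegment],
    segments_b: list[TypedSegment],
    layout: GenomeLayout,
) -> SharedFeatureReport:
    """Count bins where both lesions carry the same non-HET LOH-type label.

    For cluster pair ``(i, j)``: a bin is *shared* when lesion A assigns it a
    non-HET label in cluster ``i`` and lesion B assigns the SAME label in
    cluster ``j``; each lesion's remaining altered bins for that pair are its
    unique counts.  Diploid-heterozygous bins are uninformative about common
    ancestry and never counted.  Swapping A and B transposes the pair matrix
    and preserves every shared count.
    """
    lab_a, clu_a = _rasterize(segments_a, layout)
    lab_b, clu_b = _rasterize(segments_b, layout)
    alt_a = lab_a != "HET"
    alt_b = lab_b != "HET"
    ids_a = sorted(set(clu_a[alt_a]))
    ids_b = sorted(set(clu_b[alt_b]))
    if not ids_a and not ids_b:
        return SharedFeatureReport(pairs=[], top_pair=None, empty=True)
    same = alt_a & alt_b & (lab_a == lab_b)
    pairs = []
    for i in ids_a:
        in_i = alt_a & (clu_a == i)
        for j in ids_b:
            in_j = alt_b & (clu_b == j)
            shared = int(np.sum(same & in_i & in_j))
            pairs.append(
                PairShare(
                    cluster_a=i,
                    cluster_b=j,
                    n_shared=shared,
                    n_unique_a=int(np.sum(in_i)) - shared,
                    n_unique_b=int(np.sum(in_j)) - shared,
                )
            )
    top = max(
        pairs,
        key=lambda p: (p.shared_fraction, p.n_shared, -p.cluster_a, -p.cluster_b),
        default=None,
    )
    return SharedFeatureReport(pairs=pairs, top_pair=top)


@dataclass
class LineageCall:
    verdict: str  # "parallel" | "independent"
    r: float | None
    top_shared_fraction: float
    r_threshold: float
    share_threshold: float
    notes: list[str] = field(default_factory=list)


def call_lineage(
    r: float | None,
    report: SharedFeatureReport,
    r_threshold: float = 0.8,
    share_threshold: float = 0.5,
) -> LineageCall:
    """Disjunctive rule: parallel iff r > r_threshold OR top shared fraction
    >= share_threshold; both evidence values are carried in the call."""
    if r is None and (report is None or report.empty):
        raise ValueError(
            "correlation undefined and no shared features: manual review required"
        )
    notes = []
    top = report.top_shared_fraction if report is not None else 0.0
    by_r = r is not None and r > r_threshold
    by_share = top >= share_threshold
    if by_r:
        notes.append(f"genome-wide CNV correlation r={r:.3f} > {r_threshold}")
    if by_share:
        p = report.top_pair
        notes.append(
            f"cluster pair ({p.cluster_a},{p.cluster_b}) shares "
            f"{p.n_shared} bins (fraction {top:.3f} >= {share_threshold})"
        )
    verdict = "parallel" if (by_r or by_share) else "independent"
    if not notes:
        notes.append("no evidence of a shared founder clone")
    return LineageCall(
        verdict=verdict,
        r=r,
        top_shared_fraction=top,
        r_threshold=r_threshold,
        share_threshold=share_threshold,
        notes=notes,
    )


def compare_lesions(
    segments_a: list[TypedSegment],
    segments_b: list[TypedSegment],
    layout: GenomeLayout,
    log_ratio_a: np.ndarray | None = None,
    log_ratio_b: np.ndarray | None = None,
    r_threshold: float = 0.8,
    share_threshold: float = 0.5,
) -> LineageCall:
    """Full comparison: profile correlation + shared features -> lineage call.

    Correlation uses MAP copy-number profiles; when those are constant (no
    alterations called in a lesion) it falls back to the raw log-ratio tracks
    if provided, else the correlation is left undefined.
    """
    report = shared_feature_analysis(segments_a, segments_b, layout)
    r: float | None
    try:
        r = cnv_correlation(
            copy_number_profile(segments_a, layout),
            copy_number_profile(segments_b, layout),
        )
    except UndefinedCorrelationError:
        if log_ratio_a is not None and log_ratio_b is not None:
            r = cnv_correlation(log_ratio_a, log_ratio_b)
        else:
            r = None
    return call_lineage(r, report, r_threshold, share_threshold)
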