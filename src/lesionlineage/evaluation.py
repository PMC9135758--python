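"""Simulation-based recovery studies at the default study conditions.

Each function here builds seeded synthetic datasets with the generator's
default desk-scale conditions (2 chromosomes x 50 Mb, 10 kb bins, 5,000 het
sites at mean depth 30, log-ratio sd 0.15, 30% normal contamination), runs
the inference end to end, and measures how well the known truth is recovered.
They back both the acceptance test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from .clonal_inference import build_locus_grid, fit_em, typed_segments
from .lineage import (
    call_lineage,
    cnv_correlation,
    copy_number_profile,
    shared_feature_analysis,
)
from .states import GenotypeState
from .synthetic_data import CNV_EVENT_STATES, SimConfig, simulate_pair

GAIN_STATES = (GenotypeState(3, 1), GenotypeState(3, 2))


def _seed(base: int, i: int) -> int:
    return (base * 1_000_003 + i) % (2**31 - 1)


def contamination_recovery(
    n_seeds: int = 10, seed: int = 1, normal_fraction: float = 0.30
) -> list[float]:
    """Estimated normal fraction per seed for two-subclone lesions.

    Truth: prevalences {1.0, 0.5}, 12 private events split over the two
    subclones, contamination ``normal_fraction``; Z=2 fits.
    """
    cfg = SimConfig(
        normal_fraction=normal_fraction,
        prevalences_A=(1.0, 0.5),
        n_shared_events=0,
        n_private_events=12,
        event_len_bins=(80, 160),
    )
    out = []
    for i in range(n_seeds):
        truth, obs = simulate_pair("parallel", _seed(seed, i), cfg)
        bins, sites = obs["A"]
        data = build_locus_grid(bins, sites, truth.layout)
        model = fit_em(data, n_clusters=2)
        out.append(model.normal_fraction)
    return out


def minor_prevalence_recovery(
    minor_prevalence: float, n_seeds: int = 10, seed: int = 1
) -> list[float]:
    """Estimated minor-subclone prevalence per seed.

    Truth: major clone at prevalence 1.0 (7 events of mixed type), nested
    minor subclone at ``minor_prevalence`` carrying one-copy GAIN events over
    well more than 500 loci; 30% contamination; Z=2 fits.  Returns the fitted
    prevalence of the smaller cluster.
    """
    cfg = SimConfig(
        prevalences_A=(1.0, minor_prevalence),
        n_shared_events=0,
        n_private_events=13,  # round-robin: 7 major + 6 minor events
        event_len_bins=(100, 200),
    )
    out = []
    for i in range(n_seeds):
        truth, obs = simulate_pair(
            "parallel", _seed(seed, i), cfg,
            carrier_state_pools={2: GAIN_STATES},
        )
        bins, sites = obs["A"]
        data = build_locus_grid(bins, sites, truth.layout)
        model = fit_em(data, n_clusters=2)
        out.append(model.clusters[-1][1])
    return out


def parallel_pair_correlation(n_seeds: int = 5, seed: int = 1) -> list[float]:
    """Genome-wide Pearson r of MAP copy-number profiles for parallel pairs.

    The founder clone (prevalence 1.0) carries 25 copy-number-changing events
    of 120-200 bins (>= 30% of the 10,000 bins; copy-neutral LOH is excluded
    because it is invisible on a copy-number profile) shared by both lesions,
    plus a small private set of 3 events of 30-60 bins per lesion.
    """
    cfg = SimConfig(
        prevalences_A=(1.0,),
        prevalences_B=(1.0,),
        n_shared_events=25,
        n_private_events=3,
        event_len_bins=(120, 200),
    )
    out = []
    for i in range(n_seeds):
        truth, obs = simulate_pair(
            "parallel", _seed(seed, i), cfg,
            shared_state_pool=CNV_EVENT_STATES,
            private_len_bins=(30, 60),
        )
        profiles = []
        for label in ("A", "B"):
            bins, sites = obs[label]
            data = build_locus_grid(bins, sites, truth.layout)
            model = fit_em(data, n_clusters=1)
            profiles.append(
                copy_number_profile(typed_segments(model, truth.layout), truth.layout)
            )
        out.append(cnv_correlation(profiles[0], profiles[1]))
    return out


def classify_pair(truth, obs, r_threshold: float = 0.8, share_threshold: float = 0.5):
    """Infer both lesions (Z=2) and return the lineage call."""
    segs = {}
    for label in truth.lesions:
        bins, sites = obs[label]
        data = build_locus_grid(bins, sites, truth.layout)
        model = fit_em(data, n_clusters=2)
        segs[label] = typed_segments(model, truth.layout)
    a, b = truth.lesions
    report = shared_feature_analysis(segs[a], segs[b], truth.layout)
    r = cnv_correlation(
        copy_number_profile(segs[a], truth.layout),
        copy_number_profile(segs[b], truth.layout),
    )
    return call_lineage(r, report, r_threshold, share_threshold)


def lineage_classification_accuracy(
    n_sims: int = 20, seed: int = 1
) -> tuple[float, list[tuple[str, str]]]:
    """End-to-end verdict accuracy over half parallel / half independent pairs.

    Returns (accuracy, [(true_scenario, verdict), ...]).
    """
    results = []
    for i in range(n_sims):
        scenario = "parallel" if i < n_sims // 2 else "independent"
        truth, obs = simulate_pair(scenario, _seed(seed, 100 + i))
        call = classify_pair(truth, obs)
        results.append((scenario, call.verdict))
    acc = float(np.mean([t == v for t, v in results]))
    return acc, results
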