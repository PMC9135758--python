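"""Paired-lesion simulator with known clonal structure.

Generates the observable tracks of a two-lesion experiment — binned depth
log-ratios and germline-het allele counts — from an explicit clonal truth,
under two evolutionary scenarios:

``parallel``
    Both lesions descend from a single founder clone and share the founder's
    CNV/LOH events; each lesion adds private events.
``independent``
    The two lesions arise from distinct initiating clones; their event sets
    are drawn to be genomically disjoint.

Subclones within a lesion form a nested chain (each later subclone is a
subpopulation of the previous one), so cellular prevalences must be
non-increasing; the first entry is usually 1.0 (clonal).  Normal-cell
contamination dilutes all tumor signal.  Emission noise is Gaussian on the
log-ratio track (sd ``sigma``) and binomial on allele counts at
Poisson-distributed depths, matching the inference model's emission
expectations exactly in the mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .genome import BinDepth, GenomeLayout, HetSite, make_genome
from .states import (
    GenotypeState,
    HET_STATE,
    LOH_CATALOG,
    enumerate_states,
    expected_logratio,
    expected_reffraction,
)

logger = logging.getLogger(__name__)

#: states eligible for simulated events: every non-diploid-het genotype
EVENT_STATES: tuple[GenotypeState, ...] = tuple(
    s for s in enumerate_states(4) if (s.c, s.a) != (2, 1)
)

#: copy-number-changing events only (excludes copy-neutral LOH, which is
#: invisible on a depth/copy-number track)
CNV_EVENT_STATES: tuple[GenotypeState, ...] = tuple(
    s for s in EVENT_STATES if s.c != 2
)


@dataclass(frozen=True)
class CnvEvent:
    """One CNV/LOH event: a half-open genomic interval in a genotype state,
    carried by a single subclone."""

    chrom: str
    start: int
    end: int
    state: GenotypeState
    carrier: int

    def key(self) -> tuple:
        """Identity for cross-lesion comparison: interval plus state."""
        return (self.chrom, self.start, self.end, self.state.c, self.state.a)


@dataclass(frozen=True)
class Subclone:
    id: int
    prevalence: float
    parent: int | None


@dataclass
class CloneTree:
    """Nested subclones of one lesion with their events."""

    subclones: list[Subclone]
    scenario: str
    events: list[CnvEvent] = field(default_factory=list)
    shared_events: list[CnvEvent] = field(default_factory=list)

    def prevalence_of(self, subclone_id: int) -> float:
        for sc in self.subclones:
            if sc.id == subclone_id:
                return sc.prevalence
        raise KeyError(subclone_id)


@dataclass
class SimulationTruth:
    """Generative parameters of one paired-lesion simulation."""

    normal_fraction: float
    trees: dict[str, CloneTree]
    sigma: float
    het_depth: float
    seed: int
    layout: GenomeLayout

    @property
    def lesions(self) -> list[str]:
        return list(self.trees)


def _validate_prevalences(prev: list[float], label: str) -> None:
    if not prev:
        raise ValueError(f"{label}: prevalence list must be non-empty")
    for p in prev:
        if not 0.0 < p <= 1.0:
            raise ValueError(f"{label}: prevalence {p} outside (0, 1]")
    if any(b > a for a, b in zip(prev, prev[1:])):
        raise ValueError(
            f"{label}: nested subclone prevalences must be non-increasing, got {prev}"
        )


def _make_chain(prev: list[float], scenario: str) -> CloneTree:
    subs = [
        Subclone(i + 1, p, None if i == 0 else i) for i, p in enumerate(prev)
    ]
    return CloneTree(subclones=subs, scenario=scenario)


def _draw_event(
    rng: np.random.Generator,
    layout: GenomeLayout,
    occupied: np.ndarray,
    forbidden: np.ndarray | None,
    len_range: tuple[int, int],
    state_pool: tuple[GenotypeState, ...],
    carrier: int,
    max_tries: int = 2000,
) -> CnvEvent:
    """Uniform placement over bins, rejection-sampled against overlap."""
    names = layout.chrom_names
    for _ in range(max_tries):
        n_len = int(rng.integers(len_range[0], len_range[1] + 1))
        start_bin = int(rng.integers(0, layout.n_bins))
        ci = layout.bin_chrom_idx[start_bin]
        sl = layout.chrom_slices[names[ci]]
        end_bin = min(start_bin + n_len, sl.stop)
        span = np.arange(start_bin, end_bin)
        if occupied[span].any():
            continue
        if forbidden is not None and forbidden[span].any():
            continue
        occupied[span] = True
        state = state_pool[int(rng.integers(0, len(state_pool)))]
        return CnvEvent(
            chrom=names[ci],
            start=int(layout.bin_start[start_bin]),
            end=int(layout.bin_end[end_bin - 1]),
            state=state,
            carrier=carrier,
        )
    raise RuntimeError("could not place event without overlap; genome too full")


def simulate_clone_trees(
    scenario: str,
    prevalences_A: list[float],
    prevalences_B: list[float],
    n_shared_events: int,
    n_private_events: int,
    seed: int,
    layout: GenomeLayout,
    event_len_bins: tuple[int, int] = (50, 200),
    private_len_bins: tuple[int, int] | None = None,
    shared_carrier: str = "minor",
    state_pool: tuple[GenotypeState, ...] = EVENT_STATES,
    shared_state_pool: tuple[GenotypeState, ...] | None = None,
    carrier_state_pools: dict[int, tuple[GenotypeState, ...]] | None = None,
) -> tuple[CloneTree, CloneTree]:
    """Draw the clonal structure and event maps of a lesion pair.

    In the ``parallel`` scenario ``n_shared_events`` founder events are placed
    once and copied into both lesions, carried by the subclone selected by
    ``shared_carrier`` (``"minor"``: smallest prevalence, the pattern seen in
    shared-feature tracks of paired nodules; ``"major"``: the top clone).
    ``n_private_events`` additional events per lesion are distributed
    round-robin over that lesion's subclones, with lengths drawn from
    ``private_len_bins`` (defaults to ``event_len_bins``); founder events may
    use their own ``shared_state_pool``.  In the ``independent`` scenario
    each lesion draws its own events and the two event maps are kept
    genomically disjoint; ``n_shared_events`` must be 0.

    ``carrier_state_pools`` optionally restricts the genotype states available
    to a given carrier subclone id (e.g. GAIN-only minor subclones).
    """
    if scenario not in ("parallel", "independent"):
        raise ValueError(f"unknown scenario {scenario!r}")
    if scenario == "independent" and n_shared_events != 0:
        raise ValueError("independent scenario takes n_shared_events == 0")
    _validate_prevalences(prevalences_A, "lesion A")
    _validate_prevalences(prevalences_B, "lesion B")

    rng = np.random.default_rng(seed)
    tree_a = _make_chain(prevalences_A, scenario)
    tree_b = _make_chain(prevalences_B, scenario)
    occ_a = np.zeros(layout.n_bins, dtype=bool)
    occ_b = np.zeros(layout.n_bins, dtype=bool)

    def pool_for(carrier: int) -> tuple[GenotypeState, ...]:
        if carrier_state_pools and carrier in carrier_state_pools:
            return tuple(carrier_state_pools[carrier])
        return tuple(state_pool)

    if scenario == "parallel":
        car_a = (
            min(tree_a.subclones, key=lambda s: s.prevalence).id
            if shared_carrier == "minor"
            else tree_a.subclones[0].id
        )
        car_b = (
            min(tree_b.subclones, key=lambda s: s.prevalence).id
            if shared_carrier == "minor"
            else tree_b.subclones[0].id
        )
        for _ in range(n_shared_events):
            ev = _draw_event(
                rng, layout, occ_a, None, event_len_bins,
                shared_state_pool or pool_for(car_a), car_a,
            )
            span = slice(
                layout.bin_index(ev.chrom, ev.start),
                layout.bin_index(ev.chrom, ev.end - 1) + 1,
            )
            occ_b[span] = True
            tree_a.events.append(ev)
            tree_a.shared_events.append(ev)
            ev_b = replace(ev, carrier=car_b)
            tree_b.events.append(ev_b)
            tree_b.shared_events.append(ev_b)

    for tree, occ, other_occ in ((tree_a, occ_a, None), (tree_b, occ_b, None)):
        forbidden = None
        if scenario == "independent" and tree is tree_b:
            forbidden = occ_a  # keep the lesions' event maps disjoint
        ids = [s.id for s in tree.subclones]
        priv_len = private_len_bins or event_len_bins
        for k in range(n_private_events):
            carrier = ids[k % len(ids)]
            tree.events.append(
                _draw_event(
                    rng, layout, occ, forbidden, priv_len, pool_for(carrier), carrier
                )
            )
    return tree_a, tree_b


def bin_state_map(
    tree: CloneTree, layout: GenomeLayout
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-bin ``(state_index, prevalence, carrier)`` truth arrays.

    ``state_index`` indexes :func:`lesionlineage.states.enumerate_states`\\ (4);
    bins outside any event are diploid HET with prevalence 1 and carrier 0.
    """
    states = enumerate_states(4)
    idx_of = {(s.c, s.a): i for i, s in enumerate(states)}
    state_idx = np.full(layout.n_bins, idx_of[(2, 1)], dtype=np.int32)
    prevalence = np.ones(layout.n_bins)
    carrier = np.zeros(layout.n_bins, dtype=np.int32)
    for ev in tree.events:
        lo = layout.bin_index(ev.chrom, ev.start)
        hi = layout.bin_index(ev.chrom, ev.end - 1) + 1
        state_idx[lo:hi] = idx_of[(ev.state.c, ev.state.a)]
        prevalence[lo:hi] = tree.prevalence_of(ev.carrier)
        carrier[lo:hi] = ev.carrier
    return state_idx, prevalence, carrier


def emit_observations(
    truth: SimulationTruth,
    layout: GenomeLayout,
    n_het_sites: int,
    seed: int,
) -> dict[str, tuple[list[BinDepth], list[HetSite]]]:
    """Draw the observable tracks of every lesion in ``truth``.

    Per bin: ``log_ratio ~ Normal(expected_logratio(state, s, n), sigma^2)``.
    Per het site: ``ref_count ~ Binomial(depth, expected_reffraction)`` with
    ``depth ~ Poisson(het_depth)`` (minimum 1).  Het sites landing in a region
    of zero total copies would be unobservable and are excluded with a logged
    warning (cannot occur with the built-in state catalog, where c >= 1).

    Identical ``truth``/``seed`` give bit-identical output.
    """
    if n_het_sites <= 0:
        raise ValueError("n_het_sites must be positive")
    states = enumerate_states(4)
    n = truth.normal_fraction
    out: dict[str, tuple[list[BinDepth], list[HetSite]]] = {}
    for li, label in enumerate(truth.lesions):
        rng = np.random.default_rng([seed, li])
        tree = truth.trees[label]
        state_idx, prev, _ = bin_state_map(tree, layout)

        mu = np.array(
            [expected_logratio(states[g], s, n) for g, s in zip(state_idx, prev)]
        )
        lr = rng.normal(mu, truth.sigma) if truth.sigma > 0 else mu
        names = layout.chrom_names
        bins = [
            BinDepth(names[ci], int(s), int(e), float(v))
            for ci, s, e, v in zip(
                layout.bin_chrom_idx, layout.bin_start, layout.bin_end, lr
            )
        ]

        # het-site positions uniform over the genome, deduplicated
        total = layout.total_length
        offs = np.unique(rng.integers(0, total, size=int(n_het_sites * 1.2) + 16))
        offs = offs[rng.permutation(len(offs))[:n_het_sites]]
        offs.sort()
        bounds = np.cumsum([0] + [l for _, l in layout.chromosomes])
        sites: list[HetSite] = []
        n_excluded = 0
        for off in offs:
            ci = int(np.searchsorted(bounds, off, side="right") - 1)
            chrom = names[ci]
            pos0 = int(off - bounds[ci])
            b = layout.bin_index(chrom, pos0)
            st = states[state_idx[b]]
            if st.c == 0:  # zero total copies: site unobservable
                n_excluded += 1
                continue
            p = expected_reffraction(st, float(prev[b]), n)
            depth = max(1, int(rng.poisson(truth.het_depth)))
            ref = int(rng.binomial(depth, p))
            sites.append(HetSite(chrom, pos0 + 1, ref, depth))
        if n_excluded:
            logger.warning(
                "%s: excluded %d het sites in zero-copy regions", label, n_excluded
            )
        out[label] = (bins, sites)
    return out


@dataclass
class SimConfig:
    """Default desk-scale study conditions for the paired-lesion simulator."""

    n_chrom: int = 2
    chrom_len: int = 50_000_000
    bin_size: int = 10_000
    n_het_sites: int = 5_000
    het_depth: float = 30.0
    sigma: float = 0.15
    normal_fraction: float = 0.30
    prevalences_A: tuple[float, ...] = (1.0, 0.5)
    prevalences_B: tuple[float, ...] = (1.0, 0.5)
    n_shared_events: int = 12
    n_private_events: int = 6
    event_len_bins: tuple[int, int] = (50, 200)

    def layout(self) -> GenomeLayout:
        return make_genome(self.n_chrom, self.chrom_len, self.bin_size)


def simulate_pair(
    scenario: str,
    seed: int,
    config: SimConfig | None = None,
    **tree_kwargs,
) -> tuple[SimulationTruth, dict[str, tuple[list[BinDepth], list[HetSite]]]]:
    """One-call generator: clone trees + observations for a lesion pair."""
    cfg = config or SimConfig()
    layout = cfg.layout()
    n_shared = cfg.n_shared_events if scenario == "parallel" else 0
    tree_a, tree_b = simulate_clone_trees(
        scenario,
        list(cfg.prevalences_A),
        list(cfg.prevalences_B),
        n_shared,
        cfg.n_private_events,
        seed,
        layout,
        event_len_bins=cfg.event_len_bins,
        **tree_kwargs,
    )
    truth = SimulationTruth(
        normal_fraction=cfg.normal_fraction,
        trees={"A": tree_a, "B": tree_b},
        sigma=cfg.sigma,
        het_depth=cfg.het_depth,
        seed=seed,
        layout=layout,
    )
    obs = emit_observations(truth, layout, cfg.n_het_sites, seed)
    return truth, obs


def event_jaccard(tree_a: CloneTree, tree_b: CloneTree) -> float:
    """Jaccard index of the two lesions' event sets (interval + state identity)."""
    ka = {e.key() for e in tree_a.events}
    kb = {e.key() for e in tree_b.events}
    union = ka | kb
    if not union:
        return 0.0
    return len(ka & kb) / len(union)


def write_fixture(truth: SimulationTruth, observations, out_dir) -> str:
    """Write VCF/WIG tracks, a truth TSV and a YAML manifest; returns the
    manifest path.  Deterministic byte-for-byte for identical inputs."""
    from . import io as llio  # late import: io depends on clonal_inference

    return llio.write_fixture(truth, observations, out_dir)
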