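"""Joint CNV/LOH subclonal inference.

A hidden Markov model over the product space (genotype state x subclone
cluster) with Gaussian depth-ratio emissions and binomial allelic-ratio
emissions, fitted by EM.  Each cluster ``z`` has an aberrant-cell fraction
``phi_z`` (the fraction of *all* cells in the sample carrying that cluster's
events); the fitted ``phi`` vector is decomposed under the clonal-dominance
convention into a normal-contamination fraction ``n = 1 - max(phi)`` and
cellular prevalences ``s_z = phi_z / max(phi)`` (fractions of tumor cells),
because the emission expectations determine ``(n, s_z)`` only through
``phi_z = (1 - n) * s_z``.

Observations live on a common locus grid: every het SNP is a locus carrying
both its binomial allele counts and the depth log-ratio of its containing
bin; bins without het sites contribute depth-only loci.  Chromosomes are
independent chains.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from .genome import BinDepth, GenomeLayout, HetSite
from .hmm import forward_backward, structured_transition, viterbi
from .states import (
    GenotypeState,
    enumerate_states,
    expected_logratio,
    expected_reffraction,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeState",
    "enumerate_states",
    "expected_logratio",
    "expected_reffraction",
    "LocusData",
    "EMParams",
    "ClonalModel",
    "TypedSegment",
    "build_locus_grid",
    "e_step",
    "m_step",
    "fit_em",
    "select_n_clusters",
    "typed_segments",
]

PHI_BOUNDS = (0.01, 0.99)
SIGMA_FLOOR = 0.02
_P_EPS = 1e-9
#: Per-locus log prior penalty per copy away from diploid.  Genotype (4, a+1)
#: at aberrant fraction phi/2 is emission-identical to (3, a) at phi, so the
#: likelihood alone cannot choose between them; this weak parsimony prior
#: breaks the degeneracy toward the lower copy number, consistently across
#: samples.  Small enough to be overwhelmed by one locus's worth of real
#: evidence.
STATE_PENALTY = 0.05


@dataclass
class LocusData:
    """Aligned per-locus observation arrays (see module docstring).

    ``log_ratio`` is NaN for loci whose bin had no depth value; ``depth`` is 0
    for depth-only loci (no het site).
    """

    chrom: np.ndarray       # chromosome index per locus
    position: np.ndarray    # bp, 0-based (bin start for depth-only loci)
    bin_index: np.ndarray   # global bin index per locus
    log_ratio: np.ndarray
    ref_count: np.ndarray
    depth: np.ndarray
    chrom_ranges: list[tuple[int, int]]
    log_binom_const: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        d, b = self.depth.astype(float), self.ref_count.astype(float)
        with np.errstate(invalid="ignore"):
            self.log_binom_const = np.where(
                self.depth > 0,
                gammaln(d + 1) - gammaln(b + 1) - gammaln(d - b + 1),
                0.0,
            )

    @property
    def n_loci(self) -> int:
        return len(self.position)


def build_locus_grid(
    bins: list[BinDepth], het_sites: list[HetSite], layout: GenomeLayout
) -> LocusData:
    """Merge depth bins and het sites into one ordered locus grid."""
    lr = layout.log_ratio_vector(bins)
    per_bin_sites: dict[int, list[HetSite]] = {}
    for site in het_sites:
        per_bin_sites.setdefault(layout.bin_index(site.chrom, site.pos - 1), []).append(site)

    chrom, pos, bidx, x, ref, dep = [], [], [], [], [], []
    for b in range(layout.n_bins):
        sites = per_bin_sites.get(b)
        if sites:
            for s in sorted(sites, key=lambda s: s.pos):
                chrom.append(layout.bin_chrom_idx[b])
                pos.append(s.pos - 1)
                bidx.append(b)
                x.append(lr[b])
                ref.append(s.ref_count)
                dep.append(s.depth)
        elif np.isfinite(lr[b]):
            chrom.append(layout.bin_chrom_idx[b])
            pos.append(layout.bin_start[b])
            bidx.append(b)
            x.append(lr[b])
            ref.append(0)
            dep.append(0)
    chrom = np.asarray(chrom, np.int32)
    ranges = []
    for ci in range(len(layout.chromosomes)):
        idx = np.nonzero(chrom == ci)[0]
        if len(idx):
            ranges.append((int(idx[0]), int(idx[-1] + 1)))
    return LocusData(
        chrom=chrom,
        position=np.asarray(pos, np.int64),
        bin_index=np.asarray(bidx, np.int64),
        log_ratio=np.asarray(x, float),
        ref_count=np.asarray(ref, np.int64),
        depth=np.asarray(dep, np.int64),
        chrom_ranges=ranges,
    )


@dataclass
class EMParams:
    """Model parameters: per-cluster aberrant fractions, depth sd, transitions."""

    phi: np.ndarray
    sigma: float
    rho: float = 0.999

    @property
    def n_clusters(self) -> int:
        return len(self.phi)

    def decompose(self) -> tuple[float, np.ndarray]:
        """(normal fraction, prevalences) under clonal dominance of max(phi)."""
        top = float(np.max(self.phi))
        return 1.0 - top, np.asarray(self.phi) / top

    @classmethod
    def from_n_s(cls, n: float, s, sigma: float, rho: float = 0.999) -> "EMParams":
        s = np.asarray(s, float)
        return cls(phi=(1.0 - n) * s, sigma=sigma, rho=rho)


def _state_arrays(states: list[GenotypeState]) -> tuple[np.ndarray, np.ndarray]:
    return (
        np.array([s.c for s in states], float),
        np.array([s.a for s in states], float),
    )


def _mu_p(c: np.ndarray, a: np.ndarray, phi: float) -> tuple[np.ndarray, np.ndarray]:
    cbar = 2.0 + phi * (c - 2.0)
    mu = np.log2(cbar / 2.0)
    p = np.clip((1.0 + phi * (a - 1.0)) / cbar, _P_EPS, 1.0 - _P_EPS)
    return mu, p


def emission_log_matrix(
    data: LocusData, params: EMParams, states: list[GenotypeState]
) -> np.ndarray:
    """(T, K) log emission likelihoods, K = n_states * n_clusters (cluster-major).

    Includes the per-locus parsimony prior ``-STATE_PENALTY * |c - 2|`` (see
    that constant's note on the amplification degeneracy).
    """
    c, a = _state_arrays(states)
    G = len(states)
    T = data.n_loci
    out = np.zeros((T, G * params.n_clusters))
    mask_d = np.isfinite(data.log_ratio)
    mask_b = data.depth > 0
    xd = data.log_ratio[mask_d]
    bb = data.ref_count[mask_b].astype(float)
    dd = data.depth[mask_b].astype(float)
    const = data.log_binom_const[mask_b]
    gauss_norm = math.log(params.sigma * math.sqrt(2.0 * math.pi))
    prior = -STATE_PENALTY * np.abs(c - 2.0)
    for z in range(params.n_clusters):
        mu, p = _mu_p(c, a, float(params.phi[z]))
        cols = slice(z * G, (z + 1) * G)
        out[:, cols] = prior[None, :]
        out[np.ix_(mask_d, range(cols.start, cols.stop))] += (
            -0.5 * ((xd[:, None] - mu[None, :]) / params.sigma) ** 2 - gauss_norm
        )
        out[np.ix_(mask_b, range(cols.start, cols.stop))] += (
            bb[:, None] * np.log(p)[None, :]
            + (dd - bb)[:, None] * np.log1p(-p)[None, :]
            + const[:, None]
        )
    return out


def e_step(
    data: LocusData, params: EMParams, states: list[GenotypeState] | None = None
) -> tuple[np.ndarray, float]:
    """Forward-backward posteriors over the joint space and the data log-likelihood.

    Chromosomes are independent chains with a shared structured transition
    matrix (self-transition ``rho``).  Posterior rows sum to 1; scaling keeps
    everything finite regardless of emission sharpness.
    """
    states = states or enumerate_states(4)
    K = len(states) * params.n_clusters
    trans = structured_transition(K, params.rho)
    log_emit = emission_log_matrix(data, params, states)
    gamma = np.empty((data.n_loci, K))
    ll = 0.0
    for lo, hi in data.chrom_ranges:
        g, l = forward_backward(log_emit[lo:hi], trans)
        gamma[lo:hi] = g
        ll += l
    return gamma, ll


def _sufficient_stats(data: LocusData, gamma: np.ndarray, n_clusters: int, n_states: int):
    mask_d = np.isfinite(data.log_ratio)
    mask_b = data.depth > 0
    Gd = gamma[mask_d]
    xd = data.log_ratio[mask_d]
    S0 = Gd.sum(axis=0)
    S1 = Gd.T @ xd
    S2 = Gd.T @ (xd * xd)
    Gb = gamma[mask_b]
    B = Gb.T @ data.ref_count[mask_b].astype(float)
    D = Gb.T @ data.depth[mask_b].astype(float)
    shape = (n_clusters, n_states)
    return (S0.reshape(shape), S1.reshape(shape), S2.reshape(shape),
            B.reshape(shape), D.reshape(shape))


def m_step(
    data: LocusData,
    responsibilities: np.ndarray,
    params: EMParams,
    states: list[GenotypeState] | None = None,
) -> EMParams:
    """Generalized M-step: coordinate ascent on the expected complete-data
    log-likelihood.

    Each cluster's ``phi_z`` is updated by bounded 1-D maximization in
    ``[0.01, 0.99]`` (accepted only if it does not decrease the objective, so
    the EM likelihood trace is monotone); ``sigma`` by the weighted residual
    SD.  The optimization uses closed-form sufficient statistics, so each
    candidate ``phi`` costs O(n_states).

    A cluster whose total responsibility falls below 1e-6 is dropped with a
    warning.  A cluster with no aberrant-state responsibility carries no
    information about ``phi`` and keeps its current value (warned once).
    """
    states = states or enumerate_states(4)
    G = len(states)
    Z = params.n_clusters
    c, a = _state_arrays(states)
    S0, S1, S2, B, D = _sufficient_stats(data, responsibilities, Z, G)

    resp_total = S0.sum(axis=1) + D.sum(axis=1)
    keep = resp_total >= 1e-6
    if not keep.all():
        logger.warning(
            "dropping %d empty cluster(s) (total responsibility < 1e-6)",
            int((~keep).sum()),
        )
        S0, S1, S2, B, D = S0[keep], S1[keep], S2[keep], B[keep], D[keep]
        params = EMParams(phi=params.phi[keep], sigma=params.sigma, rho=params.rho)
        Z = params.n_clusters

    het = (c == 2) & (a == 1)
    inv2s2 = 1.0 / (2.0 * params.sigma**2)
    new_phi = params.phi.astype(float).copy()
    for z in range(Z):
        aberrant = (S0[z][~het].sum() + D[z][~het].sum())
        if aberrant < 1e-6:
            logger.warning("cluster %d: no aberrant signal, phi unidentifiable; kept", z)
            continue

        s0, s1, s2, bz, dz = S0[z], S1[z], S2[z], B[z], D[z]

        def q(phi: float) -> float:
            mu, p = _mu_p(c, a, phi)
            gauss = -inv2s2 * float(np.sum(s2 - 2.0 * mu * s1 + mu * mu * s0))
            binom = float(np.sum(bz * np.log(p) + (dz - bz) * np.log1p(-p)))
            return gauss + binom

        res = minimize_scalar(
            lambda f: -q(f), bounds=PHI_BOUNDS, method="bounded",
            options={"xatol": 1e-5},
        )
        if q(float(res.x)) >= q(float(new_phi[z])):
            new_phi[z] = float(res.x)

    # weighted residual SD of the depth emissions at the new phi
    resid = 0.0
    weight = 0.0
    for z in range(Z):
        mu, _ = _mu_p(c, a, float(new_phi[z]))
        resid += float(np.sum(S2[z] - 2.0 * mu * S1[z] + mu * mu * S0[z]))
        weight += float(S0[z].sum())
    sigma = max(math.sqrt(max(resid, 0.0) / weight), SIGMA_FLOOR) if weight > 0 else params.sigma
    return EMParams(phi=new_phi, sigma=sigma, rho=params.rho)


@dataclass
class TypedSegment:
    """A genomic run of constant (genotype state, subclone cluster)."""

    chrom: str
    start: int
    end: int
    genotype: GenotypeState
    cluster: int
    mean_log_ratio: float
    mean_allelic_ratio: float  # NaN if the segment holds no het sites
    n_loci: int


@dataclass
class ClonalModel:
    """A fitted joint CNV/LOH model for one lesion."""

    normal_fraction: float
    clusters: list[tuple[int, float]]  # (id, prevalence), prevalence decreasing
    phi: np.ndarray
    sigma: float
    rho: float
    map_state: np.ndarray      # per-locus genotype index into `states`
    map_cluster: np.ndarray    # per-locus cluster id (1-based)
    states: list[GenotypeState]
    log_likelihood: float
    ll_trace: list[float]
    n_iterations: int
    converged: bool
    data: LocusData
    bic: float | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def prevalence_of(self, cluster_id: int) -> float:
        return dict(self.clusters)[cluster_id]


def _default_starts(n_clusters: int, sigma0: float, rho: float) -> list[EMParams]:
    s_grid = np.array([1.0 - (z / n_clusters) for z in range(n_clusters)])
    return [EMParams.from_n_s(n0, s_grid, sigma0, rho) for n0 in (0.1, 0.3, 0.5)]


def _em_run(
    data: LocusData,
    params: EMParams,
    states: list[GenotypeState],
    max_iter: int,
    tol: float,
) -> tuple[EMParams, np.ndarray, list[float], bool]:
    trace: list[float] = []
    gamma = None
    converged = False
    for _ in range(max_iter):
        gamma, ll = e_step(data, params, states)
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        params = m_step(data, gamma, params, states)
    return params, gamma, trace, converged


def fit_em(
    data: LocusData,
    n_clusters: int,
    init: EMParams | dict | None = None,
    max_iter: int = 60,
    tol: float = 1e-2,
    seed: int = 0,
    rho: float = 0.999,
    c_max: int = 4,
) -> ClonalModel:
    """Fit the joint model by EM.

    Without an explicit ``init``, a deterministic multi-start is used: normal
    fraction in {0.1, 0.3, 0.5} with equally spaced prevalences, a short burn
    of 6 iterations each, and the best run continued to convergence
    (``|delta logL| < tol`` or ``max_iter``).  ``seed`` is accepted for
    interface symmetry; the procedure is deterministic.

    Returns a :class:`ClonalModel` with the MAP (Viterbi) per-locus
    assignment, clusters sorted by decreasing prevalence and the full
    likelihood trace.  ``converged`` is False when ``max_iter`` is exhausted.
    """
    del seed  # deterministic initialization
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    states = enumerate_states(c_max)
    xd = data.log_ratio[np.isfinite(data.log_ratio)]
    q75, q25 = np.percentile(xd, [75, 25]) if len(xd) else (0.1, -0.1)
    sigma0 = max((q75 - q25) / 1.349, SIGMA_FLOOR)

    if init is not None:
        if isinstance(init, dict):
            init = EMParams.from_n_s(init["n"], init["s"], init.get("sigma", sigma0), rho)
        params, gamma, trace, converged = _em_run(data, init, states, max_iter, tol)
    else:
        burn = []
        for start in _default_starts(n_clusters, sigma0, rho):
            p, g, t, _ = _em_run(data, start, states, max_iter=6, tol=0.0)
            burn.append((t[-1], p, t))
        _, best_params, burn_trace = max(burn, key=lambda r: r[0])
        params, gamma, trace, converged = _em_run(
            data, best_params, states, max_iter, tol
        )
        trace = burn_trace + trace

    # Viterbi MAP over the joint space; ties prefer diploid-HET, then lower
    # copy number, then lower cluster.
    G = len(states)
    K = G * params.n_clusters
    trans = structured_transition(K, params.rho)
    log_emit = emission_log_matrix(data, params, states)
    pref_g = np.array([0 if (s.c, s.a) == (2, 1) else s.c for s in states])
    pref = np.concatenate([pref_g + 100 * z for z in range(params.n_clusters)])
    joint_path = np.empty(data.n_loci, dtype=np.int32)
    for lo, hi in data.chrom_ranges:
        joint_path[lo:hi], _ = viterbi(log_emit[lo:hi], trans, pref=pref)

    order = np.argsort(-params.phi, kind="stable")
    phi_sorted = params.phi[order]
    n_hat, s_hat = EMParams(phi_sorted, params.sigma, params.rho).decompose()
    old_to_new = np.empty(len(order), dtype=np.int64)
    old_to_new[order] = np.arange(len(order))
    return ClonalModel(
        normal_fraction=float(n_hat),
        clusters=[(z + 1, float(s_hat[z])) for z in range(len(s_hat))],
        phi=phi_sorted,
        sigma=params.sigma,
        rho=params.rho,
        map_state=(joint_path % G).astype(np.int32),
        map_cluster=(old_to_new[joint_path // G] + 1).astype(np.int32),
        states=states,
        log_likelihood=trace[-1],
        ll_trace=trace,
        n_iterations=len(trace),
        converged=converged,
        data=data,
    )


def select_n_clusters(
    data: LocusData,
    z_max: int = 5,
    seed: int = 0,
    **fit_kwargs,
) -> ClonalModel:
    """Fit Z = 1..z_max and return the BIC minimizer (ties -> smaller Z).

    BIC = -2 logL + k ln(N) with k = Z + 1 free parameters (phi_1..Z, sigma).
    """
    if z_max < 1:
        raise ValueError("z_max must be >= 1")
    best = None
    for z in range(1, z_max + 1):
        model = fit_em(data, z, seed=seed, **fit_kwargs)
        k = model.n_clusters + 1
        model.bic = -2.0 * model.log_likelihood + k * math.log(max(data.n_loci, 1))
        if best is None or model.bic < best.bic:
            best = model
    return best


def typed_segments(model: ClonalModel, layout: GenomeLayout) -> list[TypedSegment]:
    """Run-length encode the MAP assignment into genomic segments.

    Loci are collapsed to their bins first (majority vote within a bin, first
    locus on ties); bins without loci inherit the previous bin's assignment.
    Segments are maximal runs of constant (genotype, cluster) per chromosome:
    sorted, non-overlapping, adjacent segments differ.
    """
    data = model.data
    n_bins = layout.n_bins
    bin_state = np.full(n_bins, -1, dtype=np.int64)
    bin_cluster = np.zeros(n_bins, dtype=np.int64)
    # loci are ordered by bin; find each bin's locus block
    starts = np.searchsorted(data.bin_index, np.arange(n_bins), side="left")
    ends = np.searchsorted(data.bin_index, np.arange(n_bins), side="right")
    for b in range(n_bins):
        lo, hi = starts[b], ends[b]
        if lo == hi:
            continue
        pairs, counts = np.unique(
            np.stack([model.map_state[lo:hi], model.map_cluster[lo:hi]]),
            axis=1, return_counts=True,
        )
        g, cl = pairs[:, int(np.argmax(counts))]
        bin_state[b] = g
        bin_cluster[b] = cl
    # forward/backward fill bins without loci
    filled = np.nonzero(bin_state >= 0)[0]
    if len(filled) == 0:
        return []
    for b in range(n_bins):
        if bin_state[b] < 0:
            prev = filled[filled < b]
            src = prev[-1] if len(prev) else filled[0]
            bin_state[b] = bin_state[src]
            bin_cluster[b] = bin_cluster[src]

    segs: list[TypedSegment] = []
    names = layout.chrom_names
    for name in names:
        sl = layout.chrom_slices[name]
        b = sl.start
        while b < sl.stop:
            g, cl = bin_state[b], bin_cluster[b]
            e = b
            while e + 1 < sl.stop and bin_state[e + 1] == g and bin_cluster[e + 1] == cl:
                e += 1
            lo, hi = starts[b], ends[e]
            seg_lr = data.log_ratio[lo:hi]
            seg_lr = seg_lr[np.isfinite(seg_lr)]
            het = data.depth[lo:hi] > 0
            if het.any():
                ratio = float(
                    np.mean(data.ref_count[lo:hi][het] / data.depth[lo:hi][het])
                )
            else:
                ratio = float("nan")
            segs.append(
                TypedSegment(
                    chrom=name,
                    start=int(layout.bin_start[b]),
                    end=int(layout.bin_end[e]),
                    genotype=model.states[int(g)],
                    cluster=int(cl),
                    mean_log_ratio=float(seg_lr.mean()) if len(seg_lr) else float("nan"),
                    mean_allelic_ratio=ratio,
                    n_loci=int(hi - lo),
                )
            )
            b = e + 1
    return segs
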