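# Methods

This note documents the models, parameter choices and numerical decisions
behind `lesionlineage`, and what the synthetic-data experiments do and do not
demonstrate.

## Genotype states and emission expectations

The joint model's state space is every pair $(c, a)$ with total copy number
$1 \le c \le 4$ and reference-allele copies $0 \le a \le c$ — 14 states. Each
pair carries exactly one LOH-type label and one CNV-class label:

| $(c,a)$ | LOH label | CNV label | note |
|---|---|---|---|
| (1,0), (1,1) | DLOH | HEMD | hemizygous deletion |
| (2,1) | HET | NEUT | diploid heterozygous (the null state) |
| (2,0), (2,2) | NLOH | NEUT | copy-neutral LOH |
| (3,1), (3,2) | GAIN | AMP | one-copy gain; ASCNA on the amplification track |
| (3,0), (3,3) | ALOH | AMP | amplification with LOH |
| (4,2) | BCNA | AMP | balanced amplification |
| (4,1), (4,3) | UBCNA | AMP | unbalanced amplification |
| (4,0), (4,4) | ALOH | AMP | amplification with complete allele loss |

(4,0)/(4,4) are labelled ALOH by analogy with (3,0)/(3,3); the catalog is one
table in `states.py` so the mapping can be swapped.

A sample is a mixture of normal cells (fraction $n$, diploid heterozygous
everywhere) and tumor cells, of which fraction $s_z$ carry cluster $z$'s
events. All emission expectations depend on $(n, s_z)$ only through the
aberrant-cell fraction $\phi_z = (1-n) s_z$:
mean copies $\bar c = 2 + \phi_z(c-2)$, expected depth log-ratio
$\log_2(\bar c/2)$, expected reference-read fraction
$(1 + \phi_z(a-1))/\bar c$.

## Identifiability and the clonal-dominance decomposition

Because only the $\phi_z$ enter the likelihood, $n$ and the $s_z$ are not
separately identifiable. EM therefore estimates the $\phi_z$ directly
(bounded in $[0.01, 0.99]$) and decomposes afterwards under the convention
that the most prevalent cluster is clonal: $n = 1 - \max_z \phi_z$ and
$s_z = \phi_z / \max_z \phi_z$. This is the standard resolution in
allele-specific copy-number callers (purity is defined by the dominant
clone); it is exact when the lesion truly contains a clonal cluster, and
overestimates contamination when even the top cluster is subclonal. A lesion
with no aberrant loci at all leaves $\phi$ unidentifiable; the M-step then
keeps the current value and logs a warning.

A second exact degeneracy is specific to amplifications: state $(3,a)$ at
fraction $\phi$ produces identical emissions to $(4,a{+}1)$ at $\phi/2$. The
likelihood cannot distinguish them, and two lesions of a pair could adopt
different representations of the same founder event, corrupting cross-lesion
comparison. A weak per-locus parsimony prior on genotype states,
$-0.05\,|c-2|$ log units (`STATE_PENALTY`), breaks the tie toward the lower
copy number consistently in every sample. The prior is part of the HMM's
emission matrix, so EM monotonicity and the forward–backward contracts are
unaffected; it is two orders of magnitude smaller than a typical locus's
emission information and has no measurable effect on parameter recovery.

## EM details

- **E step**: scaled forward–backward per chromosome over the
  (14 × Z)-state chain; transition matrix has self-transition $\rho = 0.999$
  with the remainder uniform. Scaling plus per-locus emission shifts keep
  arbitrarily sharp emissions finite.
- **M step**: generalized (coordinate-ascent) M-step. Each $\phi_z$ is
  updated by bounded Brent maximization of the expected complete-data
  log-likelihood, computed from closed-form sufficient statistics (the
  Gaussian part is quadratic in the state means; the binomial part needs only
  responsibility-weighted ref/total counts), and a candidate is accepted only
  if it does not decrease the objective — so the likelihood trace is monotone
  by construction. $\sigma$ is the responsibility-weighted residual SD,
  floored at 0.02 to avoid collapse on noiseless input. Clusters with total
  responsibility below 1e-6 are dropped with a warning.
- **Initialization**: deterministic multi-start over $n_0 \in
  \{0.1, 0.3, 0.5\}$ with equally spaced prevalences, 6 burn-in iterations
  each, best likelihood continued to convergence
  ($|\Delta \log L| < 10^{-2}$ by default, `max_iter` 60).
- **MAP assignment**: Viterbi over the joint space; exact score ties prefer
  diploid-HET, then lower copy number, then lower cluster id.
- **Model selection**: $Z = 1..z_\text{max}$ fitted and compared by
  $\mathrm{BIC} = -2\log L + (Z+1)\ln N$; ties go to the smaller $Z$. BIC
  separates cluster counts reliably from a few thousand loci upward; at a few
  hundred loci the boundary-noise gain of an extra cluster can be of the same
  order as the penalty.

The locus grid interleaves both tracks: every het SNP carries its binomial
counts plus the containing bin's log-ratio; bins without het sites contribute
depth-only loci. Bins with several het sites are counted once per site on the
depth track, a deliberate simplification.

## Low-depth CNV caller

For low-coverage cohorts a 3-state Gaussian HMM (DEL/NEUT/AMP) over
median-centered log-ratios stands in for the joint model. State means default
to $(-0.5, 0, +0.35)$ log2 units — roughly one-copy loss and gain at high
purity; the shared SD is estimated from the central 50% of bins (IQR/1.349),
robust to the altered minority. Viterbi ties break toward NEUT (conservative
calling). Self-transition defaults to 0.995. No GC or mappability correction
is applied (the simulator generates none); `normalize_depth` is the hook
where such a correction would slot in for real data.

## Lineage deconstruction

Profile correlation is plain Pearson on per-bin MAP total copy number
(fallback: raw log-ratios when no clonal model is available); a zero-variance
profile raises rather than silently returning 0. Feature sharing rasterizes
the typed segments to bins and counts, for every cluster pair, bins where
both lesions carry the *same* non-HET LOH label; diploid agreement is
uninformative about ancestry and never counted. The verdict is disjunctive —
parallel iff $r > 0.8$ *or* top shared fraction $\ge 0.5$ — because a pair
can lack global CNV similarity while a small subclone pair still shares the
founder's features. The 0.8 correlation rule mirrors the value used
descriptively for parallel pairs; the 0.5 share threshold quantifies "more
common than unique" and is exposed as configuration, echoed in every output.

## Synthetic data: what it emulates and what it does not

The generator emulates: fixed-width binning of a diploid genome, nested
subclones (non-increasing prevalences; each subclone a subpopulation of its
parent), CNV/LOH events of all catalog types placed uniformly at random
without overlap, ~30% normal contamination, Gaussian log-ratio noise
($\sigma = 0.15$, typical low-depth WGS bin scatter) and binomial allele
counts at Poisson(30) depths. Default scale is 2 chromosomes × 50 Mb at
10 kb bins with 5,000 het sites — minutes on one CPU, enough loci for stable
EM. In the parallel scenario founder events default to the smallest subclone
of each lesion, matching the observed pattern where ancestral aberrations
persist in a minor descendant while the dominant clone accrues private
events; in the independent scenario the two lesions' event maps are kept
genomically disjoint.

Not emulated: read-level noise, GC/mappability bias, replication timing,
overdispersed (beta-binomial) allele counts, whole-genome doubling, SNVs,
and within-event switching of which parental haplotype is lost (each event
fixes its reference-allele count $a$ across all its sites). Passing recovery
tests therefore demonstrates correctness of the inference machinery under
the model's own assumptions, not robustness to real-data artifacts.

## Problem sizes used in the recovery studies

Contamination recovery uses two subclones (1.0/0.5) with 12 events of 80–160
bins; minor-prevalence recovery uses a major clone with 7 mixed-type events
and a minor subclone carrying 6 one-copy-gain events of 100–200 bins (well
over 500 supporting loci); the correlation study gives the founder 25
copy-number-changing events of 120–200 bins (≥30% of bins; copy-neutral LOH
is excluded there because it is invisible on a copy-number track) and each
lesion 3 small private events; classification uses 20 pairs at the default
conditions, half parallel and half independent, with Z=2 fits throughout.

## Known limitations

- Purity/prevalence estimates inherit the clonal-dominance assumption.
- The binomial allelic model underestimates real allele-count dispersion; a
  beta-binomial hook is the natural extension.
- Baseline ploidy is fixed at 2; whole-genome-doubled tumors would be
  misinterpreted.
- Feature sharing counts bins, not breakpoints, so one long shared event
  weighs as much as many short ones.
- No significance assessment (e.g. permutation p-value) accompanies the
  share fraction; the thresholds are decision rules, not tests.
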