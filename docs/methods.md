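# Methods

## Synthesis packing

### Distance and clustering

Parts are compared by unit-cost Levenshtein distance on the full flanked
sequence (computed with edlib; the test suite keeps an independent
dynamic-programming oracle). Affinity propagation runs on the negated
distance matrix as similarity, with the preference at the median similarity,
damping 0.5, up to 500 iterations and a 15-iteration convergence window —
the standard conventions for exemplar-based clustering when the number of
clusters should emerge from the data. Two degenerate inputs are handled
outside the message-passing loop: a single part is its own cluster, and an
all-zero distance matrix (identical sequences) collapses to one cluster,
since affinity propagation is undefined on a constant similarity matrix. If
message passing fails to converge, the assignment falls back to one cluster
per part and is flagged `converged=False`; grouping still proceeds.

### Grouping

Groups take at most three members because only three unloading enzymes
(BsmBI, BbsI, BspMI) exist in the scheme. Each group is filled greedily from
the clusters with the most remaining members (ties broken by exemplar name,
members taken in name order), so members of one group always come from
distinct clusters and the procedure is deterministic. Aggressive mode
concatenates the leftover singleton groups with each other, chunked into
runs of at most three; merged groups may then contain same-cluster members —
the caller has explicitly traded repeat-risk for fewer bases.

### Enzyme geometry and rewriting

The enzymes are modeled as recognition site + spacer + 4-nt 5′ overhang:
BsmBI CGTCTC(N1), BbsI GAAGAC(N2), BspMI ACCTGC(N4). Rewriting replaces the
recognition sequence and adjusts the spacer with neutral filler (A/T
preferred, full alphabet as fallback) so that the overhang released by
digestion is byte-identical to what BsmBI would have released from the
original part — overhang identity is what Golden Gate fidelity rests on.
Site scanning always covers both strands, since type-IIS sites are
directional. After concatenation the whole fragment is re-scanned: each
assigned enzyme must occur exactly twice and unassigned ones never; an
incidental site (created by a junction or already present in a core) raises
a rewrite error rather than silently producing an uncloneable order. The
round-trip invariant — in-silico digestion of the rewritten group with a
member's enzyme reproduces the BsmBI digest of the original part, overhangs
included — is asserted in tests for every member of every group formed.

### Baselines and cost

The naive baseline pads each part with random filler to the provider
minimum (default 300 bases, exposed as `--min-length` since providers
differ); filler draws reject any base that would complete a recognition
site. The random baseline shuffles parts with the seed and chunks them into
threes. Cost is reported as total synthesized bases — currency depends on
provider price tables and is out of scope. For part sets entirely below the
minimum length, clustered totals can never exceed naive totals: each group
of g parts costs max(sum of lengths + spacer filler, minimum) ≤ g × minimum.

## Cytometry preprocessing

### Density gating

The 2-D density estimate is a 128×128 histogram on log-transformed
forward-scatter area and height. Bins are ranked by occupancy (stable sort,
so ties are deterministic) and whole bins are retained, densest first, until
the requested fraction (default 0.95) is reached; stopping at the first bin
that crosses the target means the achieved fraction can overshoot by less
than one bin's worth — under one percentage point at realistic event counts.
Retaining whole bins also makes gates nested: a lower retain fraction keeps
a subset of a higher one. Events with non-positive scatter values cannot be
log-transformed; they are dropped (never retained) with a logged count.
Gating refuses inputs below 100 events or with a constant scatter channel,
where a density ranking is meaningless.

### Replicate QC and pooling

Two rules, applied to gated events: every replicate needs ≥ 1000 events, and
every pairwise ratio of replicate median fluorescences (larger/smaller) must
be ≤ 8. The event-count rule drops replicates individually; if fewer than
two remain the condition is discarded. The ratio rule is then evaluated on
the survivors, and one violation discards the condition outright — dropping
only the outlier would bias the retained medians, whereas the dose–response
curvature can be recovered from neighboring conditions. Checking counts
before ratios is the one point where the two rules interact; the order
chosen means an outlier median confined to an undersized replicate cannot
sink an otherwise-consistent condition. The decision is invariant to
replicate order. Pooling concatenates the kept replicates' events, so counts
and value multisets are preserved exactly.

### RPU conversion

γ is computed per sample from that sample's median, so the rescaled sample
median always equals ([GFP] − [GFP]₀)/([GFP]_RPU − [GFP]₀): the reference
sample maps to 1 RPU and an autofluorescence-level sample to 0 by
construction. The conversion is invariant to a common rescaling of all raw
intensities. Calibration requires [GFP]_RPU > [GFP]₀ and a positive sample
median; violations raise instead of returning negative or infinite γ.

## Hill calibration

### Models and posterior

Both Hill forms share θ = (y_max, y_min, n, k), all strictly positive;
y_min/y_max are RPU, k is in inducer units for sensors and input RPU for
gates, n is dimensionless. All comparisons are made in natural-log space:
outputs span orders of magnitude, so log-domain residuals weight deviations
by relative size. The likelihood is the factorized proportional form
−Σᵢ(log f(xᵢ) − log yᵢ)², i.e. unit noise scale in log space; this affects
posterior sharpness but not the location of the likelihood maximum. The
prior places flat-top bands on log y_max over [ŷ_max, 2ŷ_max] and log y_min
over [0.5ŷ_min, ŷ_min] (ŷ = observed extremes), with squared distance to
the nearest band edge outside; n and k are flat. Because flat improper
priors make a sampler ill-posed, proposals are rejected outside
n ∈ (10⁻², 10²) and k ∈ (10⁻⁶, 10⁶) — bounds far beyond any plausible
biology. y_max ≥ y_min is *not* enforced during sampling; it is checked on
θ̂ and a diagnostic warning is set if violated.

The numerically sensitive step, x^n/(k^n + x^n), is evaluated as a logistic
in n·(log x − log k) so neither x^n nor k^n overflows; x = 0 maps exactly to
the limiting values of both forms.

### Sampler

Each walker owns a geometric temperature ladder from T=1 to T=50 with
`chains` rungs. Proposals are isotropic Gaussians on
(log y_max, log y_min, log n, log k) with standard deviation 0.05·√T, so hot
chains roam while the cold chain refines; after each Metropolis sweep a swap
is proposed between every adjacent rung with the standard tempered exchange
ratio exp((β_c − β_h)(lp_h − lp_c)), which preserves detailed balance (unit
tested against hand-computed probabilities). θ̂ is the best configuration
among *every* posterior evaluation at any temperature, accepted or not, and
the true evaluation count (one per proposal per chain per walker, plus the
initial batch) is reported. The initial configuration is
θ₀ = (ŷ_max, ŷ_max, 2, k₀) with k₀ = 1 for sensors and 0.01 for gates. A
run is fully determined by its seed; 1000 consecutive steps without a single
cold-chain acceptance set a stagnation warning in the diagnostics.

Defaults are 10 walkers × 10 chains × 10,000 steps (10⁶ evaluations, a few
seconds per dataset with the vectorized posterior). The test and acceptance
suites run the sampler at 10 walkers × 5 chains × 2000 steps, which already
places the MAP within grid-oracle resolution on the fixtures used; parameter
recovery is assessed over 20 seeded 12-point datasets with σ = 0.1
log-normal noise.

## Synthetic data

The flow generator mixes log-normal fluorescence populations over bivariate
log-normal scatter channels with correlation 0.9 (singlet-like events);
debris, when requested, is a diffuse uniform cloud in log-scatter space with
dim fluorescence. This gives density gating genuine structure to find —
tests assert debris depletion against the hidden labels — but deliberately
omits instrument noise floors, compensation artifacts, doublets and
multimodal expression; passing tests therefore demonstrate algorithmic
correctness, not robustness to every real cytometer pathology. Dose–response
noise is multiplicative log-normal (y = f(x)·exp(σz)), matching the
log-domain likelihood; σ = 0 reproduces the curve exactly, which anchors the
end-to-end noiseless calibration test. Default inducer grids are the
standard 12-point IPTG (0–1000 μM), arabinose (0–5000 μM) and aTc
(0–2000 pg/μL) series. DNA parts are random cores inside fixed BsmBI entry
flanks; rejection sampling guarantees exactly two BsmBI sites and no
BbsI/BspMI sites per part. A family generator derives near-duplicate parts
from shared templates by point mutations, providing ground-truth labels for
clustering tests.

## Known limitations

- Event IO is CSV-only; binary FCS files must be exported to CSV upstream.
- Affinity propagation's preference is a blunt knob: on small heterogeneous
  part sets it can leave many singletons, making non-aggressive clustering
  no cheaper than naive padding until aggressive merging is enabled.
- The sampler reports a point estimate (MAP) plus diagnostics; credible
  intervals are not computed.
- The grouping heuristic is greedy, not optimal bin packing; it trades a few
  bases for determinism and cluster-distinctness guarantees.
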