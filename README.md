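# synchar

A toolkit for the computational side of genetic logic-gate characterization
in *E. coli*: packing short DNA parts into cost-efficient synthesis orders,
preprocessing flow-cytometry data into relative promoter units (RPU), and
calibrating Hill dose–response models for chemically inducible promoters
(input sensors) and repressor-based NOT gates.

## Who it is for

Synthetic biologists building Golden Gate / MoClo part collections who need
to (a) order many sub-300-bp parts from synthesis providers without paying
for filler DNA, (b) turn raw cytometer event tables into clean median-RPU
dose–response points, and (c) summarize each promoter or gate with a fitted
transfer function.

## What it computes

**Synthesis packing** (`synchar.seqcluster`). Parts carrying BsmBI entry
flanks are compared by Levenshtein distance, clustered with affinity
propagation, and packed into orders of up to three members drawn from
*distinct* clusters (concatenating similar sequences invites synthesis
failures from repeats). Within an order, member 1 keeps its BsmBI flanks
while members 2 and 3 have theirs rewritten to BbsI and BspMI, preserving
the 4-nt overhangs — so any member can later be released selectively by
digesting with its own enzyme. Naive (pad each part to the provider minimum)
and random groupings are built in as baselines; costs are reported in total
synthesized bases.

**Cytometry preprocessing** (`synchar.flowproc`). Density gating on
log forward-scatter area × height retains the densest 95% of events;
replicates pool only if every pairwise ratio of their median fluorescences
is ≤ 8 and each holds ≥ 1000 gated events (a ratio violation discards the
whole condition); fluorescence is converted to RPU with

    γ = ([GFP] − [GFP]₀) / ([GFP] · ([GFP]_RPU − [GFP]₀))

where [GFP] is the sample median, [GFP]₀ the autofluorescence control and
[GFP]_RPU the reference-promoter (J23101) control.

**Hill calibration** (`synchar.hillfit`). Median dose–response data
D = {(xᵢ, yᵢ)} are fit with the activatory Hill equation
y = y_min + (y_max − y_min)·xⁿ/(kⁿ + xⁿ) for sensors, or the inhibitory form
y = y_min + (y_max − y_min)·kⁿ/(kⁿ + xⁿ) for gates. The posterior combines a
log-domain factorized likelihood ∝ Πᵢ exp(−(log f(xᵢ) − log yᵢ)²) with
flat-top band priors on y_max and y_min; the maximum a posteriori estimate
θ̂ = (y_max, y_min, n, k) is found by parallel tempering (by default 10
walkers × 10 tempered chains × 10,000 steps, Metropolis moves in
log-parameter space with adjacent-temperature swaps).

**Synthetic data** (`synchar.synthdata`). Seeded generators for log-normal
cytometry clouds with correlated scatter, Hill-curve dose–response tables on
the standard 12-point IPTG / arabinose / aTc grids, and BsmBI-flanked random
parts — every analysis here runs without any measured data.

## Worked example

```sh
$ synchar simulate --kind parts --out parts.fasta --seed 4 --n 9
wrote 9 parts to parts.fasta
$ synchar cluster --input parts.fasta --output orders.csv --seed 1
9 parts -> 5 orders, 1689 bases (249 filler); naive baseline 2700 bases
```

Nine random parts (each under 300 bp) pack into five orders totalling 1689
bases versus 2700 for naive per-part padding — a 37% saving in synthesized
DNA. `orders.csv` lists each order's members, their unloading enzymes and
the final sequence.

```sh
$ synchar simulate --kind dose --out dose.csv --seed 3
wrote 12 points to dose.csv (truth: HillParams(y_max=3.0, y_min=0.01, n=2.0, k=40.0))
$ synchar fit --input dose.csv --mode sensor --seed 1 --walkers 10 --chains 5 --steps 2000
theta_hat: y_max=3.316 y_min=0.01162 n=2.005 k=46.47 (log posterior -0.2412, 100050 evaluations)
```

A 12-point synthetic sensor curve generated from θ* = (3.0, 0.01, 2.0, 40)
with 10% log-normal noise is recovered as θ̂ = (3.32, 0.0116, 2.01, 46.5):
the dynamic range within ~11%, the Hill coefficient almost exactly, and the
transition point within the spacing of the concentration grid.

```sh
$ synchar simulate --kind flow --out events.csv --seed 2 --n 100000
$ synchar gate --input events.csv --output gated.csv
retained 95010/100000 events (95.01%)
```

## Layout

- `src/synchar/seqcluster.py` — distances, clustering, grouping, enzyme-site
  rewriting, in-silico digestion, padding baselines, benchmarking
- `src/synchar/flowproc.py` — event IO, density gating, replicate QC,
  pooling, RPU conversion
- `src/synchar/hillfit.py` — Hill models, prior/likelihood/posterior,
  parallel tempering, calibration
- `src/synchar/synthdata.py` — seeded synthetic fixtures
- `src/synchar/cli.py` — `synchar` command (`cluster`, `gate`, `qc`, `rpu`,
  `fit`, `simulate`)
- `docs/methods.md` — models, assumptions, numerical choices, limitations
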