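# eoa — Ensemble Outcome Agreement for multi-model ensembles

`eoa` computes a confidence index for hypotheses tested against multi-model
ensemble (MME) outputs, and maps it over climate-perturbation response
surfaces. It was built for crop-model ensembles — "does this adaptation
option raise yield by more than X% under a given temperature/precipitation
change?" — but works for any ensemble of scalar outcomes.

The problem it addresses: ensemble studies usually report a single
aggregated value (the ensemble median), which hides how much the answer
depends on *which* models happened to be available. The EOA index makes
that dependence explicit by examining **every possible sub-ensemble** that
could have been formed from the N available members.

## The index

Given a hypothesis H (the aggregated outcome strictly exceeds a threshold)
and an aggregation method (median by default), define

- **ES** — the minimum ensemble size for which *all* C(N, ES) member
  combinations of that size fulfil H (undefined if even the full ensemble
  fails, in which case EOA = 0);
- **AF** ∈ [0, 1] — an adjustment factor separating ensembles with equal ES
  but different spread of sub-ensemble aggregates about the threshold:

  AF = max( 1 − (ES−1) / Σ<sub>i=1..ES−1</sub> my<sub>i</sub>/mn<sub>i</sub> , 0 )

  where my<sub>i</sub> (mn<sub>i</sub>) is the mean absolute
  distance-to-threshold of fulfilling (non-fulfilling) subset aggregates at
  size i. Then

  EOA = [ 1 − (ES − AF)/(N+1) ] / [ 1 − 1/(N+1) ]  ∈ [0, 1].

EOA = 1 when every single member fulfils H (ES = 1); 0.5 when agreement
first holds at half the members plus one; 0 when the full ensemble itself
fails. Values are classified Low [0, 0.25), Medium [0.25, 0.5), High
[0.5, 0.75), Very high [0.75, 1), Maximum = 1.

For N = 17 members full enumeration covers Σ C(17,i) = 131071 subsets and
runs in well under a second per cell; a seeded Monte-Carlo estimator
(`estimate_eoa_sampled`) covers larger ensembles.

## Worked example

A 7-member ensemble where two members dissent strongly (−10) and five agree
(+5), hypothesis "median > 0":

```
$ eoa compute --values "-10,-10,5,5,5,5,5" --threshold 0
{
  "n_members": 7,
  "es": 5,
  "af": 0.125,
  "eoa": 0.44642857142857145,
  "eoa_class": "Medium",
  "aggregate_method": "median",
  "exhaustive": true
}
```

Every subset of size 5 has a majority of consenters, so ES = 5 (any
smaller size admits a dissent-dominated subset). The dissenters sit twice
as far from the threshold as the consenters, so the agreement/disagreement
distance ratios are small and AF only nudges the index up, to 0.446:
"Medium" agreement — the ensemble median (+5) supports the hypothesis, but
the support is sensitive to ensemble composition.

The full pipeline on synthetic data — 17 models, a +10% injected adaptation
effect, inter-model spread of 6% — over the default 72-cell grid
(ΔT −1..+7 °C × ΔP −40..+30%):

```
$ eoa simulate --out runs.csv --n-models 17 --sigma-model 0.06 --sigma-resid 0.01 --seed 1
$ eoa surface --input runs.csv --output-dir out --threshold 0 --threshold 10 --option adapt1
$ head -4 out/adapt1__adaptation__thr10__shallow__447.csv
dT,dP,n_members,median_response,ES,AF,EOA,EOA_class
-1,-40,17,10.4898,16,0.669828,0.157049,Low
-1,-30,17,10.8415,12,0.747984,0.39694,Medium
-1,-20,17,12.7492,9,0.558433,0.562261,High
```

Each row is one perturbation cell: the ensemble-median adaptation value
(% yield change vs the unadapted run) and the agreement that it exceeds
10%. Although the median clears 10% in all three cells shown, the
agreement ranges from Low (ES = 16: near-unanimity required before all
subsets agree) to High. A recommendation report filters cells by class:

```python
from eoa import read_surface, recommendation_report
surf = read_surface("out/adapt1__adaptation__thr10__shallow__447.csv")
rep = recommendation_report(surf, min_class="High")
print(rep.n_cells, rep.dT_range, rep.dP_range)   # 6 (-1.0, 5.0) (-30.0, 30.0)
```

so only 6 of 72 cells support "adaptation gains more than 10%" with High
confidence, even though the median exceeds 10% far more widely — exactly
the narrowing of recommendation ranges the index was designed to expose.

## Library layout

- `eoa.core` — the index: subset enumeration, ES, AF, EOA, classification,
  and the seeded sampling estimator.
- `eoa.metrics` — adaptation value (adapted vs unadapted, same
  perturbation) and recovery value (adapted+perturbed vs unperturbed
  baseline), per-member, per-cell.
- `eoa.surfaces` — perturbation grids, median/EOA surfaces, recommendation
  reports, CSV+JSON I/O.
- `eoa.synthetic` — generators with analytically known agreement structure
  (two-level ensembles with closed-form ES; full synthetic run tables).
- `eoa.io` / `eoa.cli` — validated table I/O, run configuration, and the
  `eoa` command (`compute`, `classify`, `surface`, `simulate`).

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.

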