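# odit — online multivariate anomaly detection and localization

`odit` monitors a high-dimensional data stream and raises an alarm as soon as
the stream's distribution departs persistently from nominal behavior — without
assuming any parametric model and without ever seeing anomalous training
data. It is aimed at sequential monitoring problems such as physiological
signal surveillance (e.g. multichannel recordings around a seizure onset),
network traffic monitoring, and quality control, where both the detection
delay and the false alarm rate matter and where practitioners also need to
know *which* variables carry the anomaly.

## Method

Training on N nominal observations splits them into a ranked part X₁ and a
reference part X₂ and ranks each x ∈ X₁ by its kNN total distance to X₂,

&nbsp;&nbsp;&nbsp;&nbsp;L = Σₙ₌ₖ₋ₛ₊₁..ₖ gₙ(x)^γ,

keeping the K = ⌊N₁(1−α)⌋ smallest totals as a minimum-volume-set estimate of
the nominal distribution, summarized by the borderline total distance L₍K₎.
At test time each observation xₜ contributes the anomaly evidence

&nbsp;&nbsp;&nbsp;&nbsp;Dₜ = d (log Lₜ − log L₍K₎),

which a reflected accumulation Δₜ = max(Δₜ₋₁ + Dₜ, 0) turns into a stopping
rule T = min{t : Δₜ ≥ h}. Since the inverse kNN distance tracks the nominal
likelihood, Dₜ approximates a log-likelihood ratio and the procedure inherits
the delay/false-alarm behavior of the classical cumulative-sum test while
remaining fully data-driven. After an alarm, the onset estimate
τ̂ = max{t < T : Δₜ = 0} and a one-sided Student-t test on per-dimension
squared-distance contributions over S post-onset samples flag the anomalous
dimensions. An optional priority-search k-means tree answers kNN queries
approximately within a candidate budget B, never under-estimating a distance.

## Worked example

Generate a 50-dimensional simulation whose mean shifts by 3 standard
deviations in 5 random dimensions at t = 200, fit on 4000 nominal rows, then
detect and localize:

```
$ odit simulate --design mean --out sim --seed 7 --n-trials 1 --n-train 4000
$ odit fit --train sim/train.csv --alpha 0.05 --n1-frac 0.38 --seed 7 --out model
[odit] fit: N1=1520 N2=2480 K=1444 L_K=7.87382 -> model

$ odit detect --model model --stream sim/stream_000.csv --h 30 | tail -4
202     6.056527848     15.00099355     0
203     9.118993945     24.11998749     0
204     5.557114616     29.67710211     0
205     6.394969587     36.0720717      1
```

The evidence D turns positive right after the change point and the statistic
Δ crosses h = 30 five samples later: the alarm fires at T = 205 (column 4
marks the alarmed row). Localization then tests each dimension's post-onset
contribution against its nominal mean:

```
$ odit localize --model model --stream sim/stream_000.csv --h 30 --s-samples 10
dimension  t_statistic  flagged
...
22      3.979784493     1
24      2.200199192     1
25      2.428585305     1
33      3.557269715     1
...
{"T": 205, "tau_hat": 200, "S": 10, "theta": 1.833112932656237}
```

The onset estimate τ̂ = 200 is exact, and the flagged set contains all five
planted dimensions {22, 25, 33, 40, 41} plus two borderline false positives
(24, 36) — the expected behavior of a per-dimension test at level β = 0.05.
The same pipeline is available as library calls (`fit_nominal`, `run_stream`,
`localize_stream`) returning structured reports, and `calibrate_threshold`
picks h to satisfy a false-alarm budget on nominal validation streams.

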