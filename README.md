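# cascadeflow

Detection and characterization of **disruption cascades** in irregularly
timed event streams.

Surgical safety researchers record *flow disruptions* — timestamped,
typed deviations from the normal progression of a procedure — by direct
observation in the operating room. Sustained periods of elevated
disruption rate ("cascades") are associated with adverse outcomes, so a
central analysis question is: *when do cascades happen, what triggers
them, and which disruption types are over-represented inside them?*
The same machinery applies to any longitudinal event log (epidemic case
reports, seismic catalogs, system incident streams).

`cascadeflow` implements the full analysis chain as a library plus CLI:

1. **Ingestion** (`cascadeflow.io`) — tabular CSV/TSV events with a
   mandatory time column (numeric minutes or datetime strings), optional
   case and event-type columns; derives `RelativeTime` (minutes since
   the first event of the case) and the constant indicator `AnyEvent`.
2. **Filtering** (`cascadeflow.filters`) — a small expression language
   (`Case > 10 and RelativeTime < 380`) applied after derivation.
3. **Regularization** (`cascadeflow.regularize`) — counts events in
   fixed half-open bins so changepoint methods apply to irregular data.
4. **Changepoint detection** (`cascadeflow.changepoint`) — penalized
   change-in-mean segmentation, written from first principles: AMOC,
   binary segmentation, exact optimal partitioning, and PELT.
5. **Cascade identification** (`cascadeflow.cascade`) — high-rate
   segments merged and filtered by the rate/duration rule; per-cascade
   trigger attribution (type of the earliest in-cascade event).
6. **Enrichment** (`cascadeflow.enrichment`) — per-type conditional
   probabilities of cascade membership.
7. **Synthetic generation** (`cascadeflow.synthetic`) — seeded
   piecewise-constant-rate point processes with planted cascades and
   ground truth, for end-to-end recovery testing.
8. **Plotting** (`cascadeflow.plotting`) — faceted, paginated stem
   plots with changepoint/cascade overlays.

## The model

Event times within a case are binned at width Δ (default 1 min) into a
count series; the monitored statistic is the binned event rate
y_t (events/min). Segmentation minimizes the penalized cost

F(n) = min over segmentations Σ_segments C(y_{s+1..t}) + β·m,

where C is the within-segment sum of squared deviations from the
segment mean (the Normal change-in-mean likelihood with the variance
profiled out globally as a constant — the pipeline standardizes y by a
difference-based noise-scale estimate σ̂ = sd(Δy)/√2 before applying
the penalty), m is the number of changepoints and β the per-changepoint
penalty (default BIC, β = 2·ln n). Optimal partitioning solves the
recursion F(t) = min_{0≤s<t} [F(s) + C(y_{s+1..t}) + β] exactly; PELT
prunes candidates s with F(s) + C(y_{s+1..t}) > F(t), which is safe for
this cost and leaves the solution unchanged.

A **cascade** is a maximal run of adjacent segments whose mean rate is
at least r* = 1 event/min, lasting at least w = 3 minutes. For each
event type ET the enrichment table reports

P(cascade|ET) = n_in/n, P(ET) = n/N, P(ET|cascade) = n_in/N_in,
P(ET|¬cascade) = (n−n_in)/(N−N_in),

with a pooled "Any Event" row (N_in, N, N_in/N, 1, 1, 1).

## Worked example

```python
from cascadeflow import SyntheticConfig, generate_study, analyze

study = generate_study(SyntheticConfig(n_cases=8, seed=42))
result = analyze(study.events)

print(f"{result.cascades.n_cascades} cascades across {len(result.cascades.cases)} cases")
print("cascades per case:", result.per_case["histogram"])
print("trigger tally:", result.trigger_tally)
print(result.enrichment.rounded.head(4).to_string(index=False))
```

prints

```
4 cascades across 8 cases
cascades per case: {0: 4, 1: 4}
trigger tally: {'COO': 2, 'TRN': 2}
EventType  InCascadeCount  DisruptionCount  P_cascade_given_ET  P_ET  P_ET_given_cascade  P_ET_given_notcascade
      TRN               9               66                0.14  0.16                0.23                   0.15
       PF               2               15                0.13  0.04                0.05                   0.03
       EQ              10               92                0.11  0.22                0.26                   0.21
      COO               7               77                0.09  0.18                0.18                   0.18
```

Four of the eight simulated surgeries contain a detected cascade; the
training (`TRN`) disruption type — elevated inside planted cascades by
the generator's defaults — shows the largest P(cascade|ET), and each
cascade is attributed to the type of its first event. The same chain
runs from the shell:

```bash
cascadeflow simulate --seed 42 --out sim/
cascadeflow detect --input sim/events.csv --case-col Case \
    --type-col EventType --method pelt --penalty bic --out-prefix run
cascadeflow plot --input sim/events.csv --case-col Case \
    --facet Case --page-size 6 --out plots/page0.png
```

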