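# aminobalance

Amino-acid mass balance, dialysis-adequacy kinetics, and fatigue-association
modelling for chronic hemodialysis cohorts.

Patients on chronic hemodialysis lose free amino acids into the spent
dialysate at every session, on top of any residual urinary excretion. This
package implements the complete quantitative workflow for studying that
problem in a cohort of dialysis patients and healthy controls: per-patient
solute mass balance, urea kinetic modelling, distribution-aware cohort
comparison tables, and adjusted regression models linking amino-acid status
to severe fatigue. Because patient-level data of this kind are rarely
public, a first-class synthetic-cohort generator reproduces the statistical
structure of a real study (59 dialysis patients, 33 controls), so every
stage of the analysis is runnable and testable out of the box.

It is intended for clinical researchers in nephrology and nutrition who
want a tested, reproducible implementation of these calculations rather
than ad-hoc spreadsheet arithmetic.

## The quantities computed

For a dialysis patient with spent-dialysate volume $V$ (L), dialysate
concentration $D_x$ (µmol/L) of amino acid $x$, $n$ sessions/week, and 24-h
urinary excretion $UE_x$ (µmol/24 h):

$$\text{daily loss}_x = \frac{V \cdot D_x \cdot n}{7} + UE_x
\qquad\text{(controls: } V_{urine} \cdot U_x\text{)}$$

Losses are grouped (BCAA ⊂ essential; essential + non-essential = total)
and converted to grams via free-molecule molecular masses. Protein intake
follows the Maroni urea-nitrogen-appearance estimate

$$\text{intake} = 6.25\,(0.028\,G + 0.031\,BW) + UPE,$$

with $G$ the total urea appearance (dialytic + urinary, mmol/24 h), and
dialysis adequacy the single-pool Daugirdas formula

$$Kt/V = -\ln(R - 0.008\,t) + (4 - 3.5R)\,\frac{UF}{W}.$$

Dialytic clearance is total dialysate recovery per minute over the mean of
pre- and post-session plasma concentration; fractional clearance expresses
it relative to creatinine clearance. Cohort tables use mean ± SD or
median (IQR) by distribution, t / Wilcoxon / chi-squared dispatch, and the
derived columns (proportional difference, HD:control ratio, intradialytic
proportional change). Fatigue (CIS subjective-fatigue score ≥ 35) is
modelled by logistic regression with odds ratios per SD increment or per
log2 doubling, two a-priori covariate sets, and a five-rule
sensitivity-exclusion suite.

## Worked example

```python
import aminobalance as ab
from aminobalance import io, cohort_stats as cs

cohort = ab.generate_cohort(ab.default_config(seed=7))
q = io.quantify_cohort(cohort)
hd = q[q.arm == "hd"]
print(f"HD patients: {len(hd)}")
print(f"mean Kt/V: {hd.ktv.mean():.2f}")
print(f"daily amino-acid losses: {hd.loss_total_g.mean():.1f} ± {hd.loss_total_g.std(ddof=1):.1f} g/24 h")
print(f"as % of protein intake: {hd.loss_pct_of_intake.mean():.1f} ± {hd.loss_pct_of_intake.std(ddof=1):.1f} %")
```

prints

```
HD patients: 59
mean Kt/V: 1.32
daily amino-acid losses: 3.8 ± 0.9 g/24 h
as % of protein intake: 6.9 ± 2.3 %
```

i.e. for this simulated 59-patient cohort the week-averaged dialytic plus
urinary amino-acid loss is about 3.8 g/day, roughly 7% of the estimated
dietary protein intake — an order of magnitude above the urinary losses of
healthy controls. The comparison table builder reproduces the clinical
reporting layout, including the derived columns:

```python
t2 = cs.build_table(cohort, 2)   # plasma, HD predialysis vs controls
```

```
   analyte           hd     control  proportional_difference_pct            p
citrulline  84 (63; 98) 27 (24; 30)                          208 2.356425e-15
    serine      60 ± 20     97 ± 16                          -38 3.859987e-14
   taurine 69 (38; 108) 39 (34; 43)                           80 9.013609e-05
```

The same derived-column operations applied to published central values are
exact: `cs.proportional_difference(78, 28)` → `179`.

A command-line interface wraps the same pipeline:

```sh
aminobalance simulate --seed 7 --out data/
aminobalance report --seed 7 --out results/
```

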