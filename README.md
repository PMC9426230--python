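# abxlot

Semi-automated surveillance of the **total duration of antibiotic
therapy** from electronic medical record (EMR) extracts, for hospital
antimicrobial-stewardship (ASP) teams.

Auditing whether antibiotic courses are as short as guidelines allow is
a stewardship cornerstone, but manual chart review does not scale and
usually stops at the hospital door — even though a large part of many
courses is prescribed at discharge and taken at home. When the EMR
forces prescribers to register an *indication* with every antibiotic
order, that registration can be used to reconstruct each patient's
complete treatment course automatically, including the post-discharge
part, and to grade its duration against guidelines; manual review then
shrinks to validating a small sample.

## What it computes

From two flat tables — prescription orders (patient, ATC code,
start/stop, setting, status, registered indication) and admissions
(admit/discharge, ward, age) — the pipeline:

1. cleans the extract (ATC class J01 only; cancelled and
   pre-admission-dated orders removed, every removal logged);
2. selects the cohort: adult general-ward admissions of ≥ 12 h with
   *empiric* therapy (an order active at hour 24 of admission, or at
   discharge for 12–24-h stays);
3. merges consecutive prescriptions (gap ≤ 24 h, chained) with
   discharge prescriptions and outpatient prescriptions starting ≤ 24 h
   after the last stop into one **treatment course** per patient, keeps
   only the initial episode (repeat episodes and ≤ 30-day readmissions
   are excluded), and takes the *last* indication registered during the
   admission as the definitive indication of the whole course;
4. computes the **length of therapy**

   LOT = #{calendar days d : some order interval of the course
   intersects d},

   splits it into inpatient and post-discharge days (days strictly
   after the discharge date), and classifies duration adherence as

   adherent  ⇔  min ≤ LOT ≤ max + 1,

   where [min, max] is the guideline-recommended range for the
   indication and the +1 day margin absorbs calendar-day inflation (a
   single evening dose adds a whole day);
5. aggregates per indication (n, % with post-discharge treatment,
   mean ± SD share of LOT given post-discharge, median LOT and IQR,
   % adherent, % too long), emits a selection-flow report, and draws a
   seeded stratified validation sample whose chart-review annotations
   yield LOT/indication error rates.

Courses > 21 days, indications generally needing > 21 days (e.g.
S. aureus bacteraemia), prophylaxis, and simultaneous dual-indication
registrations are excluded — guideline ranges do not apply there.

A synthetic EMR generator (`abxlot.synthetic_emr`) with per-course
ground truth stands in for the non-shareable hospital data, including
the real-world error modes (cancelled orders, pre-admission start
dates, un-captured OPAT tails, mis-registered indications, open-ended
orders); see `docs/methods.md`.

## Worked example

```bash
abxlot simulate --n-patients 400 --seed 5 --out-dir sim
# wrote 831 prescriptions, 416 admissions to sim

abxlot run --prescriptions sim/prescriptions.csv --admissions sim/admissions.csv --out-dir run
# analysed 283 treatment courses
# median LOT 7.0 d, 43% of courses continued post-discharge
```

`run/summary_by_indication.csv` then holds the per-indication table
(rows with ≥ 20 courses; this run prints):

```
      indication_code  n_courses  pct_post_discharge  mean_share_post_discharge  median_lot  q1_lot  q3_lot  pct_adherent  pct_too_long
RTI-CAP_mild_moderate         34                47.1                       63.4         6.0     5.0     7.0          29.4          47.1
                 SSTI         22                63.6                       71.9         9.5     7.2    12.8          40.9           9.1
      UTI-complicated         24                58.3                       67.8        10.5     8.0    14.0          62.5          20.8
         UTI-cystitis         38                57.9                       57.8         7.0     6.0     9.8          65.8          34.2
       intraabdominal         45                24.4                       59.6         6.0     5.0     8.0           NaN           NaN
                Total        283                42.8                       62.2         7.0     5.0    10.0           NaN           NaN
```

Reading the cystitis row: 38 analysed courses, 57.9% continued after
discharge, and for those courses on average 57.8% of the total LOT lay
after discharge; the median course was 7 days (IQR 6–9.8); 65.8% fell
inside the guideline window of 3–7+1 days and 34.2% were too long.
Adherence columns are empty where no accepted guideline range exists
(e.g. intra-abdominal infection) and for the Total row; indications
seen in < 20 courses are pooled (`excluded_pool_n` in the JSON twin).

Validation then re-enacts the manual accuracy check:

```bash
abxlot sample --run-dir run --n-per-site 50 --seed 2 --out sample.csv
# (a human reviewer fills annotations.csv from the charts)
abxlot accuracy --sample sample.csv --annotations annotations.csv
# site_a:  LOT errors 2/50 = 4.0% | indication errors 7/50 = 14.0% | transfers 0
# site_b:  LOT errors 2/50 = 4.0% | indication errors 7/50 = 14.0% | transfers 0
# Total: LOT error rate 4.0% | indication error rate 14.0% | errors affecting adherence 7.0% of 100 screened
```

i.e. the extracted LOT disagreed with the chart in 4% of screened
courses, the registered indication in 14%, and half of those
indication errors would change the adherence verdict (the registered
and actual indication have different recommended durations).

The same operations are available as a library
(`abxlot.simulate`, `abxlot.run_tables`, `abxlot.compute_lot`, …).

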