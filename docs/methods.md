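# Methods

## The surveillance procedure

`abxlot` reconstructs complete antibiotic treatment courses from two
flat EMR extracts — prescription orders (with a mandatory registered
indication selected at order entry) and hospital admissions — and
evaluates the total duration of therapy against guideline
recommendations. The unit of analysis is the *treatment course*: all
consecutively prescribed systemic antibiotics of one patient around one
admission, merged across agent switches, combination therapy, discharge
prescriptions and outpatient prescriptions that continue the course.

The stages, and the rules each applies:

1. **Cleaning.** Orders outside the configured ATC include list
   (default: class J01, systemic antibacterials) are removed, as are
   cancelled orders (never administered) and erroneous orders whose
   start calendar *date* precedes the calendar date of the admission
   they belong to. Orders without a stop timestamp are truncated at the
   dataset-extraction timestamp and flagged, not silently fixed. Every
   removal is logged once with a reason code.
2. **Cohort.** Adult (≥ 18 y) general-ward admissions of at least 12 h
   in which treatment was *empiric*: an antibiotic order active at hour
   24 of admission, or — for 12–24-h stays — active at the discharge
   instant or issued as a discharge prescription. Order activity uses
   half-open intervals `[start, stop)`.
3. **Course assembly.** Orders of one admission are merged into an
   episode when the later order starts within the gap tolerance
   (default 24 h) of the earlier one's stop, chained transitively.
   Outpatient orders starting within 24 h of the episode's (running)
   stop frontier are linked and inherit the definitive indication. When
   a patient had non-consecutive episodes, or was readmitted with
   antibiotics within 30 days (discharge-to-admission, inclusive), only
   the initial episode is analysed. The *definitive indication* is the
   one registered last during the admission (registration clock = order
   start); two different indications tied at the latest registration
   disqualify the course. Courses longer than 21 calendar days, courses
   for indications that in general require > 21 days (bone/joint
   infection, S. aureus bacteraemia, endovascular, eye infection,
   febrile neutropenia, fungal infection, mediastinitis, cyst
   infection, chronic prostatitis), and prophylaxis are excluded: their
   appropriate duration is patient-specific and guideline ranges do not
   apply.
4. **Metrics.** LOT = number of distinct calendar dates intersected by
   the union of the course's order intervals. A covered date strictly
   after the discharge date is post-discharge; the discharge day itself
   counts as inpatient. A course is duration-adherent when
   `min ≤ LOT ≤ max + 1`; courses without an accepted guideline range
   or registered under an "other" category are not assessable.
5. **Reporting & validation.** A per-stage flow report (kept counts and
   removal-reason histograms, telescoping within each unit chain), a
   per-indication summary (n, % with post-discharge treatment, mean ±
   SD share of LOT given post-discharge over those courses, median and
   IQR of LOT, % adherent / % too long), a seeded stratified validation
   sample (default 200 courses per site) and, given a chart-review
   annotation file, agreement statistics: the LOT error rate, the
   indication error rate, and the share of indication errors that
   affect adherence assessment (registered and actual indication have
   different recommended ranges).

## Parameters that matter

| parameter | default | unit | why |
|---|---|---|---|
| ATC include prefixes | `J01` | — | systemic antibacterials |
| inpatient gap tolerance | 24 | h | "consecutive" is defined explicitly only for the outpatient link (24 h); the same tolerance is reused for inpatient gaps for symmetry, and is configurable |
| outpatient link window | 24 | h | an outpatient prescription started within 24 h of the last inpatient stop continues the course |
| hospitalization minimum | 12 | h | stays shorter than this are not hospitalizations |
| empiric instant | 24 | h after admit | empiric = treatment already running at hour 24 |
| readmission window | 30 | days, discharge→admission, inclusive | a new course within it belongs to the index illness |
| maximum course length | 21 | calendar days | longer courses are patient-specific, not guideline-assessable |
| adherence margin | +1 | day, upper bound only | calendar-day counting can only inflate LOT (a single evening dose adds a whole day); it cannot deflate it, so no margin is applied below the minimum |
| minimum courses per summary row | 20 | courses | rarely selected indications are pooled |

The guideline table (`data/guidelines.csv`) encodes the Dutch
national recommendations used as defaults (cystitis 3–7 d, complicated
UTI 7–14 d, catheter-associated UTI 7–14 d, mild-moderate CAP 5 d,
severe CAP 5 d, HAP 5–7 d, aspiration pneumonia 5 d, COPD exacerbation
7 d, ENT infection 7–14 d, SSTI 10–14 d); hospitals substitute their
own file of the same shape.

## The synthetic EMR generator

Real inputs are pseudonymised hospital extracts that cannot ship with
the package, so `synthetic_emr` generates them. Generation is
**course-first**: indication, true LOT, post-discharge split and cohort
membership are drawn per patient, then fragmented into orders, then
error modes are injected — so ground truth is defined by construction
and every injection is labelled.

Defaults (in `data/indication_params.csv` and `SimConfig`): a 21-code
case mix over urinary, respiratory, abdominal, skin and other
infections with per-indication LOT medians between 4 and 13 days;
per-indication post-discharge probabilities between 0.14 and 0.83 with
post-discharge shares around 0.5–0.7 of total LOT; 10% ICU and 10%
paediatric patients; 4% prophylaxis, 3% long-treatment indications, 1%
simultaneous dual registrations; 5% 30-day readmissions; 35% of courses
fragmented into consecutive orders and 10% with simultaneous
combination therapy. Error-mode defaults: 8% cancelled orders, 5%
pre-admission starts (together matching the ~13% attrition a cleaning
stage typically removes from indication-linked prescriptions), 4.5%
un-captured post-discharge (OPAT) tails, 17% mis-registered indications
(biased toward clinically confusable pairs such as cystitis ↔
complicated UTI), 0.5% never-terminated orders.

Within-indication LOT is lognormal with σ = 0.40. This is a deliberate
compromise: σ matching the widest printed IQRs (≈ 0.7) would, through
the > 21-day exclusion, truncate long-median indications enough to bias
their recovered medians noticeably; σ = 0.40 keeps a realistic spread
while the recovered median stays within a day of the configured one.

Generator conventions chosen so injected counts reconcile exactly with
the flow report: ICU and paediatric draws are mutually exclusive;
special course categories (dual / prophylaxis / long-indication) are
mutually exclusive; dual courses carry no post-discharge tail (a later
tail registration would defeat the simultaneous-last-registration
condition); error injections only affect a patient's first admission;
the last inpatient administration runs a few minutes past the
discharge timestamp, so a course whose electronic tail is missing is
still visibly active at discharge.

What the generator does **not** model: drug choice and dosing,
microbiology, ward transfers mid-stay, hospital transfers
(`unknown_transfer` annotations are supported by the accuracy module
but not generated), seasonal or departmental case-mix structure, and
correlated prescriber behaviour. Passing tests on synthetic data show
the *procedure* is implemented correctly under the stated data model;
they say nothing about how well any real hospital's extract fits that
model — which is exactly why the validation-sampling module exists.

## Numerical choices

* Timestamps are timezone-naive local hospital time at minute
  resolution; the calendar-day boundary is midnight.
* Order intervals are half-open `[start, stop)`; a degenerate order
  (`stop == start`) covers its start date. An order stopping exactly at
  midnight does not reach into the new day.
* Quantiles (median, IQR) use linear interpolation between order
  statistics; the convention is recorded in the summary metadata.
* The post-discharge share SD is the sample SD (ddof = 1), computed
  over courses with any post-discharge treatment only.
* Merging sorts by (start, stop, order id) and sweeps with a running
  stop frontier — equivalent to the transitive closure of the pairwise
  gap condition, and deterministic under ties.
* An order attributed to no admission by containment is joined to the
  patient's next admission when it starts on the same calendar date as
  the admit; an earlier start date makes it erroneous; no later
  admission makes it an orphan. Discharge-setting orders get a 24-h
  grace window after discharge.
* When several exclusion flags apply to one course the removal is
  logged once under a fixed priority (dual > prophylaxis >
  long-treatment > over-21-days), with all flags in the detail field.
* Cohort exclusion reasons may overlap; the flow histogram counts each
  admission once under a fixed priority (ICU > paediatric >
  not-hospitalized > not-empiric) while the decisions table keeps the
  full set.

## Problem sizes used in tests

The test suite exercises the oracle comparisons on 10⁴ random
instances per primitive, the exact zero-noise round trip at 1,000
patients, parameter recovery at ~400 courses per indication, and the
validation re-enactment on a 400-record sample drawn from a
2,000-patient run; the acceptance script uses 6,000 patients. These
sizes give stable statistics at interactive runtimes.

## Known limitations

* One ward per admission: mid-stay ICU transfers cannot be represented,
  so ICU exclusion is admission-level.
* The 24-h inpatient gap tolerance is a modelling choice, not an
  empirical estimate; results should be reported with the tolerance
  used.
* "Final dosage" is approximated by the order stop timestamp;
  administration-level (eMAR) data are not in the input schema.
* Whether the one-day adherence margin should also apply below the
  guideline minimum is undecidable from aggregate data; this
  implementation applies it above only, for the stated calendar-day
  inflation reason.
* Indications re-registered unchanged (same code, later order) simply
  re-anchor the registration clock; this cannot change the definitive
  indication under the last-registration rule.
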