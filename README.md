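# npcda — nonparametric cognitive diagnosis of binary test data

`npcda` profiles *what* an examinee knows, not just *how much*.  Given a
bank of dichotomously scored items and a **Q-matrix** — an I × K binary
matrix whose entry q<sub>ik</sub> = 1 says item *i* measures attribute
*k* (a skill or knowledge subdomain) — it classifies each examinee into a
latent **knowledge state** α ∈ {0,1}<sup>K</sup> of per-attribute
mastery.  The motivating use case is fine-grained evaluation of test
takers (human students or, e.g., large language models sitting a medical
MCQ bank) whose aggregate scores hide uneven mastery across subdomains.

## The methods

Classification is by distance minimisation between the observed response
pattern **y**<sub>n</sub> and the ideal response pattern of each
candidate state:

- **NPC** — the ideal response is conjunctive (DINA-type),
  η<sup>(c)</sup><sub>li</sub> = Π<sub>k</sub> α<sub>lk</sub><sup>q<sub>ik</sub></sup>,
  and the state minimising the Hamming distance
  Σ<sub>i</sub> |y<sub>ni</sub> − η<sub>li</sub>| is assigned.
- **GNPC** — each state–item cell blends conjunctive and disjunctive
  (DINO-type) ideals,
  η<sup>(ω)</sup><sub>li</sub> = ω<sub>li</sub> η<sup>(c)</sup><sub>li</sub> + (1 − ω<sub>li</sub>) η<sup>(d)</sup><sub>li</sub>,
  with ω̂<sub>li</sub> = Σ<sub>n∈C<sub>l</sub></sub>(y<sub>ni</sub> − η<sup>(d)</sup><sub>li</sub>) / (‖C<sub>l</sub>‖(η<sup>(c)</sup><sub>li</sub> − η<sup>(d)</sup><sub>li</sub>)),
  the clamped least-squares minimiser of the within-cluster residual.
  The scheme iterates: NPC seeds the clusters C<sub>l</sub>, weights are
  re-estimated, examinees are reassigned by squared distance, until the
  partition repeats.
- **WGNPC** — the same iteration scored with the variance-weighted
  distance Σ<sub>i</sub> (y<sub>ni</sub> − η̂<sup>(ω)</sup><sub>li</sub>)² / (p̄<sub>i</sub>(1 − p̄<sub>i</sub>)),
  where p̄<sub>i</sub> is item *i*'s passing rate, clamped to
  [0.0001, 0.9999].

Around the classifiers the package provides Q-matrix validation and CSV
I/O, scoring of raw MCQ answer records against an answer key, an
attribute-coverage exclusion filter, reliability/validity metrics
(Cronbach's α, split-half retest consistency of the classifications,
mastery-level/total-score correlation), mastery-profile reporting, and a
synthetic-data generator (DINA/DINO slip–guess response models over
latent states, with realistic skewed attribute coverage).

## Worked example

A two-item test with q-vectors [1,0] and [1,1] measures two attributes,
giving four candidate states (`python examples/worked_example.py`):

```
4 candidate knowledge states

Conjunctive ideal response patterns (rows = states):
       item1  item2
state
00       0.0    0.0
10       1.0    0.0
01       0.0    0.0
11       1.0    1.0

Observed pattern [1, 0] is assigned state 10 at distance 0.0
```

State `10` (attribute 1 mastered, attribute 2 not) predicts exactly the
observed answers — correct on the single-attribute item, wrong on the
item that also needs attribute 2 — so the examinee is classified there
at distance 0.  `examples/diagnose_synthetic_cohort.py` and
`examples/reliability_metrics.py` walk through a full cohort diagnosis
and the reliability metrics; a thin CLI (`npcda diagnose / simulate /
report`) covers batch use from a shell.

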