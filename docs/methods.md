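# Methods

## The problem

Dystrophinopathies are X-linked muscle diseases caused by mutations in the
dystrophin gene (*DMD*, Xp21.2; 79 exons, the largest known human gene).
The severe form, Duchenne muscular dystrophy (DMD), loses ambulation before
16 years; the milder Becker form (BMD) remains ambulant at 16 or beyond.
Most pathogenic variants are exon-level deletions or duplications, and the
clinical question this package addresses is *early* discrimination of DMD
from BMD — years before the ambulation outcome that defines the labels —
from two cheap, stable indicators: the variant's reading-frame status and
the age at first independent walking.

## Reading-frame arithmetic (`gene_model`)

An exon-level event removes (deletion) or inserts (duplication) a block of
coding sequence of length L = Σ coding_length(exon) over the affected
range. The downstream translational frame is preserved iff L ≡ 0 (mod 3);
frame-preserving events generally yield an internally truncated but
partially functional protein (BMD), frame-shifting events a premature stop
(DMD). The computation is pure modular arithmetic over a per-exon
coding-length table.

The packaged table is the Dp427m muscle isoform (RefSeq NM_004006): 79
coding lengths summing to the 11,058 nt CDS (3,685 residues + stop), with
UTRs excluded, so exon 1 carries only its 235 coding nucleotides and exon
79 only its 10 (the stop codon included). The table is a versioned TSV
fixture with the total asserted at load time; nothing is fetched at run
time.

Events touching exon 1 or exon 79 return `indeterminate` rather than a
mod-3 guess: at the translation start the rule's premise (an intact
upstream frame) fails, and at the last exon there is no downstream frame
left to disrupt — in-frame exceptions cluster at the extreme ends of the
protein. A corollary is that no frame call ever depends on the two
derived terminal entries of the table. Deletions and duplications of the
same range shift the frame by −L and +L and therefore always receive the
same status; the test suite checks this, and checks the mod-3 call against
literal sequence surgery on a synthetic CDS, exhaustively over all 3,003
interior ranges.

Coordinates are 1-based inclusive exon indices (the clinical "del 45–47"
style); multi-interval events are not representable — score each interval
separately. Point mutations, splice variants and intronic breakpoints are
out of scope.

## Labels and prediction rules (`classify`)

**Ground truth** comes from follow-up: ambulation lost before the cutoff
(default 16 years) ⇒ DMD; still ambulant with follow-up reaching the
cutoff ⇒ BMD; still ambulant but younger ⇒ `indeterminate` (such patients
are excluded from evaluation, mirroring the study design).

**Frame rule**: out-of-frame ⇒ DMD, in-frame ⇒ BMD.

**Milestone rule**: first independent walking at ≥ 18 months ("unable to
walk alone until 18 months") ⇒ DMD, earlier ⇒ BMD. The threshold is read
inclusively; with the cohort's observed ranges (BMD walks by 14 months,
delayed DMD from 18 up) the ≥ vs > choice cannot move any count. A missing
walking age propagates as unknown — never silently "not delayed".

**Combined rule**: predict DMD if *either* rule predicts DMD (logical OR
on the DMD flags); BMD only when every defined input says BMD. The source
study does not state its combination operator; OR is the unique simple
combiner consistent with all of its published rates given its published
marginals (132 out-of-frame DMD plus 14 in-frame-but-delayed DMD gives
146/152 = 96.05% sensitivity, and since no BMD case walked late the
specificity stays at 12/17 = 70.59%). OR is algebraically guaranteed to be
at least as sensitive and at most as specific as either component;
`predict_combined` is monotone in both inputs. Both properties are tested
on random cohorts.

**Eligibility** applies, in order: males only (X-linked disease), del/dup
variants only (the frame rule needs an exon-level event), and a defined
ground-truth label. The per-filter exclusion tally reproduces a
study-profile flow chart. In the shipped manifest the three predicates
touch disjoint records, so the tallies are order-invariant.

## Evaluation (`evaluate`)

DMD is the positive class. Sensitivity = tp/(tp+fn), specificity =
tn/(tn+fp), and the *diagnostic coincidence rate* — the field's term for
overall accuracy — is (tp+tn)/n. Indeterminate pairs are excluded from the
2×2 and tallied separately; a rate with a zero denominator is reported as
missing, never 0. Raw fractions are kept on the objects; rounding (2 dp of
a percentage) happens only in report serialisation.

Two rules' coincidence rates are compared with a Pearson chi-square
(df = 1, no continuity correction) on the (correct, incorrect) × (rule A,
rule B) table, treating the two evaluations as independent samples even
though they score the same 169 patients. That is the construction used in
the clinical literature this package mirrors, and only the uncorrected
variant reproduces the reference p = 0.014 for 144/169 vs 158/169 correct
(Yates gives ≈ 0.026). Because the construction ignores pairing, a paired
exact McNemar test on the discordant pairs is provided as the orthodox
alternative (`mcnemar_paired`, CLI `--mcnemar`), clearly separated from
the replicated analysis.

Group comparisons of clinical covariates use a two-sample t-test from
summary statistics (mean, SD, n); pooled Student by default — which is
what reproduces the reference diagnosis-age p = 0.63 — with Welch behind a
flag.

## Synthetic cohorts (`simulate`)

No per-patient data accompany studies of this kind, so the generator
emulates the published cohort structure: phenotype ~ Bernoulli(152/169);
frame-status concordance P(out-of-frame | DMD) = 0.868 and
P(in-frame | BMD) = 0.706; duplications at rate 16/169, assigned to DMD
cases only (the study observed no BMD duplication); and truncated-normal
clinical variables at the published mean/SD/range per group — walking
milestone (months), onset, diagnosis and ambulation-loss ages (years), CK
(U/L; a lognormal option exists for the skew real CK shows).

Exon ranges are drawn from a hotspot mixture — 0.55 mass on ranges inside
the distal 44–55 hotspot, 0.33 inside the proximal 3–26 hotspot, the rest
across the whole interior 2–78 — with a geometric exon-count weight
(P(single exon) = 0.28, matching the observed mode; ~82% of draws span ≤ 6
exons). To realise the drawn frame status exactly, all 3,003 interior
ranges are enumerated once, weighted, partitioned into frame-preserving
and frame-shifting classes via the exon table, and sampled categorically
within the drawn class. This is distributionally identical to rejection
sampling against the frame target but constant-time and incapable of
stalling; an empty class raises `SimulationError`. By construction the
sampler and the frame arithmetic can never disagree — a property the suite
still asserts.

All randomness flows from one integer seed through a single
`numpy.random.Generator`; the same seed yields a byte-identical cohort
file.

Known infidelities, hence what passing tests do and do not show: the
published DMD milestone moments (18.03 ± 7.12 on [14, 30]) are mutually
implausible — a normal with that SD truncated to that range cannot have
that mean — so the generator treats them as location/scale parameters and
its realized truncated moments (≈ 20.6 ± 4.1) differ; recovery tests
assert the generator's own theoretical truncated moments. Consequently the
simulated milestone-rule sensitivity (~68%) sits above the study's 61.18%,
and the deterministic `fixture_cohort()` — not simulation — is what
reproduces the published table. Covariates are sampled independently
within group (no milestone–CK–onset correlation), there are no female
carriers, point-mutation cases appear only in the fixture manifest, and
hotspot weights follow the coarse published statements, not per-exon
frequencies.

## The reconstructed study cohort (`fixture_cohort` / `fixture_manifest`)

Per-patient data were never released; the published marginals, however,
pin the joint phenotype × frame × milestone table uniquely: 152 DMD = 132
out-of-frame + 20 in-frame, 93 DMD delayed of whom 14 are in-frame
(146 = round(0.9605·152) forces 14), 17 BMD = 12 in-frame + 5
out-of-frame, none delayed. `fixture_cohort()` materialises these 169
records with representative variants (del 45 / dup 52 frame-shifting,
del 45–47 frame-preserving) and group-mean continuous values — the rule
evaluations depend only on the discrete cells. `fixture_manifest()` wraps
them in the 208-registration study profile (plus 23 point-mutation and 16
under-cutoff-ambulant records). One published entry is *not* reproduced:
the milestone-rule coincidence is printed as 60.09% but equals
(93+17)/169 = 65.09% from its own counts; the package reports the value
implied by the counts.

## Numerical and interface choices

- Thresholds (18 months, 16 years) and the chi-square correction are
  parameters defaulting to the reference analysis' values.
- TSV is the canonical cohort dialect (UTF-8, empty cell = missing,
  booleans 0/1); CSV is accepted on read. Reading is all-or-nothing with
  line-numbered errors; `--skip-bad-rows` tolerates and logs.
- Report JSON has a fixed key order; percentages are rounded to 2 dp at
  serialisation only.
- CLI exit codes: 0 success, 2 input/schema error, 3 internal error.
- Problem sizes in the test suite: the frame oracle is exhaustive (3,003
  ranges), rule-dominance runs 1,000 random cohorts, and simulator
  recovery uses n = 10⁵ draws (binomial SE ≈ 0.1–1 percentage point at the
  tested tolerances); the acceptance script's simulated check uses
  n = 20,000, where the same tolerances hold comfortably.

## Limitations

The frame rule itself is knowingly imperfect biology (intronic breakpoints,
splice effects, rescue by internal ribosome entry are invisible to exon
arithmetic), and the package reproduces a single-centre retrospective
analysis: the reconstructed cohort demonstrates arithmetic fidelity to the
published counts, not external validity of the 18-month threshold or of
the OR-combination on new populations.
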