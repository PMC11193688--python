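# Methods

This note records the conventions, assumptions and design choices behind
`gclot`. It is the package's account of its own behaviour; every number it
mentions is computed by the test suite or `scripts/acceptance.py`.

## Line-of-therapy model

A patient's antitumor prescription stream is segmented into ordered lines
by a single left-to-right pass:

1. a line opens at the first unconsumed non-HER2-antibody administration;
2. an agent joins the line's combination iff its first administration is
   within `combination_window_days` (default 90) of the line start;
3. an administration of a non-member agent more than the window after the
   line start ends the line (`new_agent`) and opens the next line that day;
4. a silence longer than `line_gap_days` (default 120) between member
   administrations ends the line (`gap_elapsed`), even for the same agent;
5. trastuzumab (T-mab) and trastuzumab deruxtecan (T-DXd) never open or
   end lines.

All day comparisons are inclusive: "within N days" means
`0 ≤ difference ≤ N`. The sources for these rules state no open/closed
bounds; inclusive matching is the conservative claims convention and is
applied uniformly (entry windows, lookback windows, era intervals, the
early/late threshold and the end-of-line gap). The test suite probes every
boundary (a 120-day silence continues a line; a 121-day silence splits it;
an agent arriving on day 90 joins; on day 91 it opens a new line).

Resolution of ambiguities the rule text leaves open:

- **HER2 antibodies and the window.** The antibody exemption is read as
  exempting T-mab/T-DXd from the 90-day window — they may join a regimen at
  any time during a line — not as banning them from regimens (otherwise
  first-line "XP + T-mab" could not exist). An antibody administration
  inside a line's span attaches to that line whether it comes before or
  after day 90.
- **Orphan antibody administrations** (inside no line's span) attach to the
  preceding line when within `line_gap_days` of its last administration,
  else to the following line — mirroring the continuation semantics of the
  gap rule.
- **New-agent boundaries.** The old line's last administration date is the
  latest member administration before the new agent's date; a same-day
  member administration still belongs to the old line (deterministic,
  record-order independent), while the new agent opens the next line the
  same day. Member agents still being given may re-qualify for the new
  line's combination, with their window clock restarted at the new line's
  start.
- **Death semantics.** Duration runs from first to last administration; a
  death between the last administration and the last record cannot shorten
  a time that ends at the last administration, so death only forces the
  event indicator (any on-record death makes the final line an event).
  Censoring applies only when no death is recorded, the line was not closed
  by a new agent, and at most `line_gap_days` separate the last
  administration from the last database record.
- **Monotherapy continuation.** An agent of the current combination
  continuing alone (e.g. ramucirumab after paclitaxel stops) is the same
  line: no new agent, and no qualifying gap, ends it.

The segmenter is validated against an exhaustive brute-force oracle that
enumerates every monotone assignment of administrations to lines and keeps
the assignments satisfying the rules stated declaratively; on randomized
streams of ≤ 12 administrations over ≤ 4 agents the rule set admits exactly
one valid segmentation and the single-pass algorithm produces it (1,000
streams in the acceptance run, 1,300 more across the unit tests).

## Cohort rules

**Adjuvant cohort.** Inclusion, evaluated in order, with the first failing
rule recorded as the patient's single exclusion reason: (a) a
gastric-cancer diagnosis (the earliest such diagnosis is "initial");
(b) a GC resection within 60 days of it; (c) guideline adjuvant therapy —
see below — starting within 90 days of the last resection on or before the
therapy start; (d) age ≥ 20 at therapy start (birth month is known to
year/month only; the 15th is imputed, minimising bias); (e) start on or
after the enrollment opening. Then the ordered exclusions: concomitant
non-adjuvant agents, recurrence on/before the last adjuvant dose,
pre-surgery antitumor agents, post-surgery trial participation.

Two interacting conventions deserve note:

- **Prescription-anchored entry.** Therapy start is the first post-surgery
  administration of any catalog agent, not the start of the segmented line
  containing it. The two differ exactly when a pre-surgery administration
  merges into the post-surgery stream (a ≤ 120-day bridge), and anchoring
  on the line would silently reshape the entry date and mask the
  pre-surgery exclusion. With prescription anchoring, such a patient passes
  entry and is excluded for the pre-surgery agent — the reason a reviewer
  of the disposition diagram expects.
- **Concomitant-agent exclusion.** Under line semantics, an extra agent
  given within 90 days after surgery always joins the adjuvant line, so
  requiring an exact regimen match at entry would misattribute these
  patients to "no adjuvant therapy". Entry therefore accepts a line whose
  agent set exactly matches *or strictly contains* an adjuvant-tagged
  regimen (largest match wins); the strict-superset case, or any other
  catalog agent prescribed in the 90 days after surgery, then fires the
  concomitant-medication exclusion. A config switch
  (`exclude_any_presurgery_agent`) chooses whether any catalog agent before
  surgery excludes (default) or only agents outside every catalog regimen.

The default first era opens 2008-10-01, matching the enrollment start used
for the adjuvant cohort; all era boundaries are configuration, and regimen
`recommended_since` dates are annotation only — era-1 data legitimately
contain combinations recommended later.

**Recurrent cohort.** Adjuvant members with a recurrence record strictly
after the last adjuvant administration whose first subsequent line is an
exact catalog first-/second-line regimen starting inside the enrollment
window; members with ≤ 21 days between first and last adjuvant
administration are excluded. Early vs late recurrence is classified on the
gap from adjuvant end to first-line start (≤ threshold → early; default
180 days, sensitivity 210). The rule text also says first-line therapy
"during" adjuvant therapy can count as early recurrence, yet cohort entry
requires recurrence *after* the last adjuvant dose; the package permits
first-line start at or after adjuvant end only and flags, without
resolving, the "during" wording. HER2-antibody history (`tmab_pos`) is any
post-recurrent line whose full agent set contains T-mab/T-DXd.

Barthel ADL classification: dependent if any of the 10 items is dependent;
independent if all 10 are independent; otherwise missing. Comorbidity and
metastasis lookback flags use the 180 days up to and including the index
date (adjuvant start, or first-line start for the recurrent cohort).

## Outcome estimation and reporting

Kaplan–Meier fitting uses `lifelines`; the median is the smallest event
time with `Ŝ(t) ≤ 0.5` (inclusive at exactly one half, per the standard
product-limit convention — computed from the fitted curve rather than the
library's strict-inequality helper), and the 95% CI inverts the log–log
(exponential Greenwood) confidence band at 0.5, the dominant convention in
oncology reporting. Durations are reported in months at 12/365.25 months
per day, one decimal, rounding half-up; neither the conversion nor the CI
method is stated by the sources, so both are documented package choices.

Pattern tables report within-stratum percentages at one decimal using
largest-remainder rounding, so each stratum's percentages sum to exactly
100.0 while every entry stays within 0.1 of its exact share. Transition
rates divide next-line starters by patients with an *observed* end of the
prior line (discontinuation or death); patients censored on their final
line leave the denominator, which is why a second-line denominator is
smaller than the cohort. Sankey extraction keeps the top-k regimens per
level (ties broken alphabetically), pools the rest as "Other", and routes
patients without a further line to a terminal node, making inflow equal
outflow at every node. Both sensitivity analyses are configuration
overlays — (threshold 210, gap 120) and (threshold 180, gap 90) against the
(180, 120) base — never separate code paths.

One property worth recording: "more lines under a shorter end-of-line gap"
is *not* a theorem for arbitrary streams. A longer gap can keep a line
open just long enough for a later administration to trigger a new-agent
split that the shorter gap would have expressed as a single gap split — the
brute-force oracle found such streams. The monotonicity claim holds on
margin-safe generated histories, and that is where the suite asserts it.

## Synthetic data generator

Each simulated patient follows diagnosis → resection (7–53 days) →
adjuvant start (14–76 days after resection) → adjuvant cycles (regimen
drawn from a per-era mix emulating the published era shift: S-1 95.7% in
era 1 falling to 65.0% in era 3 with docetaxel + S-1 rising to 20.0%;
durations near the published medians, e.g. ~10.5 months for S-1 and ~5.7
for CapeOX; ~21-day cycles with ±3-day jitter) → with probability 0.30 a
recurrence whose first-line start is drawn from an early/late mixture
(early weight 0.546) → up to three palliative lines with published-looking
regimen mixes, 14-day cycles and transition probabilities (0.56, 0.36) →
death (p = 0.35 after the last administration, never before it) or
administrative censoring. About 17% of patients carry exactly one
deliberate rule violation so every exclusion rule is exercised, and
roughly 9% receive trastuzumab within their first post-recurrent line.

**Margin construction.** Every inter-administration gap and every
recurrence offset keeps at least `margin_days` (default 14) away from the
active thresholds: cycle gaps stay ≤ 106 days, between-line gaps fall in
[30, 105] (new-agent transitions, only when the next regimen shares no
agent with the current line and arrives > 104 days after its start) or
[135, 220] (gap transitions), and first-line offsets avoid [166, 194]
around the 180-day threshold. Truth labels are therefore unambiguous, and
the pipeline recovers them exactly — 100% of patients across 20 seeds at
n = 200 in the acceptance run. A separate `adversarial` mode places gaps
and offsets exactly on the thresholds to probe the inclusive-bound
convention instead.

What the generator does **not** emulate: overall survival (death here is a
bookkeeping endpoint, not a modelled hazard), dose/days-supply and
stockpiling, hospital transfers or duplicate patient streams, staging, and
real claim-code dictionaries (code maps are abstract configuration).
Passing the recovery tests therefore demonstrates that the pipeline
implements its stated rules exactly — not that those rules recover truth
in real claims, where gaps *do* land near thresholds and recording is
imperfect. Note also that the early share *among cohort members* runs
above the generator's 0.546 mixture weight, an honest selection effect of
the first-line enrollment window and the study horizon, not a bug.

## Problem sizes and numerics

The default validation sizes — 20 seeds × 200 patients for recovery, 1,000
streams for the segmentation oracle, every censoring pattern at n ≤ 8 for
the product-limit check, ~5 × 220 patients for threshold properties — were
chosen to exercise every rule and stratum at desk scale; the full suite
runs in well under a minute. Dates are calendar dates throughout (no
times); day arithmetic is exact calendar-day counting. Ties in pattern
tables order by (count desc, label asc); same-day administrations are
processed members-first, making output independent of record order.

## Known limitations

- One record stream per patient is assumed; multi-hospital duplicates are
  out of scope, as in the source data.
- Whether "record of recurrence" requires specific metastasis codes or any
  recurrence-category code is configuration (`diagnosis_code_map`), since
  the governing code lists are not public.
- Stage (pStage/TNM) stratification and survival endpoints (OS/PFS) are
  deliberately out of scope.
- The fallback label for off-catalog combinations (sorted display names
  joined by " + ") is deterministic but not clinically curated.
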