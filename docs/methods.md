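# Methods

## The model

A differential-diagnosis prediction for a note is an ordered list of
diagnoses, each carrying explanation items (evidence sentences) with
provenance (`forward` = generated by the forward pass, `supplemented` =
added by the examiner from recalled knowledge) and status (`kept` /
`discarded`). The loop over a pluggable text backend is:

1. **Forward**: note (+ optional feedback) → diagnoses + explanations,
   elicited in a fixed plain-text grammar (numbered diagnosis lines,
   dash-prefixed explanation lines) that every strategy parses into the
   same prediction type. Malformed output is retried once with a fresh
   derived seed, then recorded as a per-case parsing failure.
2. **Backward**: each predicted diagnosis → the representative
   symptoms, exam findings, and laboratory results the backend recalls
   for it. An empty recall list is a valid outcome (unknown disease).
3. **Examination**: a forward explanation is kept iff the consistency
   judge finds it consistent with the note — the verifiable patient
   record. A discarded item's reason is `contradicts-recalled` when
   non-empty recalled knowledge also fails to support it, otherwise
   `unsupported`. Absence from recall alone never discards a
   note-supported item, because recall itself can be incomplete.
   Recalled findings that are present in the note but not covered by a
   kept explanation are added as supplemented items. The support count
   is computed **after** supplementation (kept + supplemented), then
   compared with β; diagnoses below β are flagged low-confidence.
   A diagnosis missing from the recalled profile is examined against
   the note only and marked `recall_missing` in the report.
4. **Reflection**: the names (only the names) of low-confidence
   diagnoses are fed back to the forward module in a neutral phrasing
   ("previously low-confidence … reconsider on its merits") — never an
   instruction to remove, so correct diagnoses are not suppressed by
   false-negative feedback. The loop stops at convergence (no
   low-confidence diagnosis) or after λ iterations.

### Acceptance is sticky; support accumulates

Once a diagnosis reaches β supports it is treated as settled and
carried forward unchanged; kept explanations for still-pending
diagnoses are unioned across iterations (deduplicated on normalized
text), so a pending diagnosis can clear β from evidence gathered over
several draws. Two consequences we rely on in testing: the number of
verified correct diagnoses is non-decreasing in the iteration index by
construction, and the final diagnosis set is always a subset of the
union of forward proposals (the loop filters and verifies; it never
invents diagnoses).

Diagnoses still below β at the cap are emitted **flagged** rather than
dropped; the evaluation layer excludes flagged items by default
(`include_flagged=False`) but can keep them, so both the filtered and
the unfiltered differential are observable. Like-for-like comparisons
against unfiltered baselines (e.g. forward-only) should use the
unfiltered convention, since the forward-only variant has no flagging
mechanism at all.

### Parameters

| parameter | meaning | default |
|---|---|---|
| β (`beta`) | minimum supporting interpretations for confidence | 3 |
| λ (`lam`) | maximum reflection iterations | 5 |
| `temperature` | backend sampling temperature | 0.1 |
| `n_paths` | reasoning paths for self-consistency CoT | 5 |
| `use_backward` / `use_examination` / `use_reflection` | component flags | all on |

The ablation variants are pure flag settings: `fi` (forward only),
`fi_em` (+ examination, no backward recall), `fi_em_star` (`fi_em`
without reflection), `dual_inf_star` (full minus reflection),
`dual_inf` (everything). `dual_inf` with λ=1 is structurally identical
to `dual_inf_star`.

All randomness flows from one run seed, fanned out per note, module,
iteration, path, and retry attempt through a SHA-256-derived
sub-2³¹ seed; with a deterministic backend, traces replay
byte-for-byte.

## Baselines

* `cot` — one step-by-step prompt.
* `diagnosis_cot` — one staged prompt (summarize → hypothesize →
  justify).
* `self_contrast` — three differently phrased prompts; if the drafts
  disagree, the diagnoses not shared by all drafts are listed as
  disputed in a re-examination prompt whose output is final; identical
  drafts skip arbitration.
* `sc_cot` — `n_paths` sampled paths (path 0 reuses the run seed, so a
  single path reduces exactly to `cot`); a diagnosis is kept iff it
  appears, after normalization, in strictly more than `n_paths`/2
  paths. Its explanations come from the containing path with the
  highest total vote agreement, ties broken on the path's rendered
  text so the choice is order-invariant; the kept *set* is invariant
  to path order by construction. Whether self-consistency should vote
  on names only or names + explanations jointly was an open design
  choice; we vote on names only, which is reproducible and auditable.

## The consistency judge

The in-core judge is lexical: a claim is consistent with a reference
set iff the Jaccard overlap of content tokens (stopword-filtered,
lightly suffix-stemmed) with some reference is ≥ 0.5. This is a
deterministic stand-in for a chat-model judge (available through the
same interface) and is used by examination, interpretation accuracy,
and error classification. Raising the threshold can only shrink the
consistent set, so interpretation accuracy is monotone non-increasing
in judge strictness — a property the suite asserts.

## Evaluation conventions

The corpus annotation does not fix the denominators of the two
accuracy ratios, nor the diagnosis-correctness matcher, so both are
explicit, documented switches rather than buried choices:

* Diagnostic accuracy defaults to the recall-style denominator (total
  ground-truth diagnoses) because correctness is only defined against
  the annotated differential; `denominator="predicted"` gives the
  precision-style variant.
* Interpretation accuracy defaults symmetrically to total ground-truth
  explanation items, counting a truth item as correct when some kept
  predicted explanation of the matched diagnosis is judged consistent
  with it; the predicted-item denominator is available.
* Matchers: exact-normalized (default), a synonym-table matcher (small
  auditable table, extendable), or a judge-backed fuzzy matcher.
  Diagnosis-name normalization itself never stems or maps synonyms, so
  all fuzziness is confined to the matcher.

The METEOR-style scorer aligns unigrams in three stages (exact, stem,
small synonym table) and scores `F_mean × (1 − penalty)` with the
standard 9:1 recall-weighted harmonic mean and fragmentation penalty
`0.5·(chunks/m)³`; a single perfectly ordered chunk carries no penalty,
so identical sentences score exactly 1.0. Duplicate tokens are assigned
leftmost-first, a deterministic tie-break; the test suite checks the
scorer against an independent brute-force implementation that
enumerates all maximal alignments and minimizes chunks. Embedding
metrics (BERT-style token F1, sentence-embedding cosine) are deliberate
plug-ins via `register_metric`, so the core never downloads model
weights.

Error taxonomy, per case: *missing content* iff at least two
ground-truth evidence pieces lack a consistent predicted counterpart;
*factual error* iff some kept predicted line is a recognizable medical
finding (consistent with the knowledge base) that is wrong for its
diagnosis; *low relevance* iff some kept line is pertinent neither to
the ground truth nor to the note. Channels are checked in that order,
so each bad line is attributed once.

Paired comparisons use a seeded percentile bootstrap (95% CI of the
mean paired difference) and a sign-flip permutation p-value with
add-one smoothing. Distribution summaries use linear-interpolation
quartiles and the 1.5×IQR outlier rule.

## The simulated clinician

The mock backend answers the same prompts as a hosted model but from
an explicit knowledge base (72 diseases, 8 per specialty across the
nine clinical specialties, 5 representative findings each, with some
findings deliberately shared between related diseases). Its proposal
rule: propose a disease when at least 2 of its findings appear as
sentences of the note, ranked by overlap with lexicographic
tie-breaks — a single shared finding is a red herring, not a
differential. Diagnoses named in feedback are always re-proposed with
freshly drawn evidence.

Noise perturbs *evidence*, never the proposal decision: omission drops
true lines per-line in both forward evidence and backward recall;
hallucination inserts, per diagnosis, a knowledge-base finding judged
inconsistent with that disease and with the note; irrelevance inserts
an off-topic non-clinical line. The channels are constructed to be
separable so that error classification can attribute each exclusively
— the property the error-recovery tests assert. With all rates zero
the mock is an oracle, which yields the central closed-loop guarantee:
every synthetic case is solved exactly by every variant.

## The synthetic corpus

Per case the generator samples a specialty (weights default to the
annotated corpus's specialty proportions), a differential of
`2 + Poisson(2.6)` diseases from that specialty (mean 4.6, truncated at
the specialty's disease count), and `3 + Poisson(0.1)` findings per
disease (mean 3.1). The note is the shuffled union of the sampled
finding sentences behind a demographic opener; the per-disease sampled
findings are the ground-truth explanations. The minimum of 3 findings
per diagnosis is deliberate: at the default β=3 it makes every
ground-truth diagnosis verifiable from the note alone, preserving the
closed-loop guarantee; the realized explanation-per-diagnosis spread is
correspondingly narrower than a real corpus's.

What the generator does *not* emulate: narrative prose (notes are
finding-sentence concatenations averaging ≈ 95 words rather than free
narrative), negated or distractor findings, diagnosis priority order,
synonym variation between note and annotation, and multi-specialty
presentations. Passing closed-loop tests therefore demonstrates the
correctness of the control loop, the filtering logic, and the metrics —
not clinical performance on real notes, which depends on the backing
model.

## Problem sizes and numerical choices

The acceptance suite runs 200-case batches for the closed-loop and
noise-ordering checks, 500-case batches for error-channel recovery, a
570-case corpus for the statistics and the 10/560 split, and n=500 with
4000 resamples for the bootstrap-vs-analytic check; these sizes keep
every Monte-Carlo comparison inside three standard errors while the
whole suite stays fast. Degenerate inputs are contracts, not crashes:
empty backend responses raise a typed malformed-output error (retried
once), zero metric denominators raise an undefined-metric error, an
empty knowledge base and out-of-range noise rates raise configuration
errors, and unknown diseases in backward recall return empty lists.

## Known limitations

* The lexical judge conflates findings that share ≥ half their content
  tokens; real paraphrase judging needs the pluggable chat-model judge.
* The examination stage cannot distinguish "recall omitted a true
  finding" from "the claim is false" when a claim is absent from both
  note and recall; it discards in that case.
* Whether a real examination module may drop a diagnosis outright
  before the β test is unresolved; filtering here happens solely
  through β.
* Explanations discarded in one iteration may reappear in the next
  (the forward module regenerates freely); only acceptance is sticky.
* The loop can only verify diagnoses the forward module proposes; under
  the simulated clinician the proposal step never misses a disease, so
  diagnostic-accuracy differences between variants are compressed
  relative to what noisy real-model proposals would show, and the
  loop's measurable benefit concentrates in explanation quality.
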