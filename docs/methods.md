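# Methods

## Task model

The task is a five-card lottery with equiprobable red/black draws. An
informative stimulus deterministically signals the outcome (≥ 3 black of 5
⇒ win of 20 cents); a non-informative stimulus is perceptually identical
but its colours are independent of the (fair) outcome. Beliefs are tracked
as `(cards_drawn, n_black)` pairs; the informative win probability is the
binomial tail over the remaining cards, and the non-informative win
probability is 0.5 at every state. For the fair default the tail is
evaluated in exact rational arithmetic (`fractions.Fraction`), so the
closed form and the brute-force enumeration over sequence completions can
be compared for exact equality rather than within a float tolerance.

Per card draw the model reports the reward prediction error
`RPE = win_amount · ΔPr(win)` in cents, the information content
`I = H(prior) − H(posterior)` in bits (binary entropy, base-2 logs), the
expected information `E[I]` (equiprobable successor average of `I`), and
the information prediction error `IPE = I − E[I]`.

**Sign convention.** Information content is defined here as the *reduction*
of belief entropy, so positive information means becoming more certain of
the outcome (win or loss alike), and `E[I]` uses the same orientation. One
common alternative writes the difference in the opposite order
(posterior minus prior entropy); only the orientation relative to
"more/less certain than expected" matters for any sign-binned analysis, and
all labels in this package use the reduction convention consistently.

Sign labels (pos/neg/zero) use a zero tolerance of 1e−9: every zero in the
fair five-card task is analytically exact, so the tolerance only guards
float noise. Task geometry (`cards_total`, `majority`, `win_amount`, card
bias) is parameterised with defaults (5, 3, 20 ¢, 0.5); only the fair case
is exercised by the acceptance suite.

Key analytic properties, all verified by tests against the exhaustive
enumeration: the belief sequence is a martingale (mean successor win
probability equals the state's own, hence mean RPE = 0 per state); mean
IPE per state is 0 by construction of `E[I]`; information telescopes to
exactly 1 bit per informative sequence and RPEs sum to ±10 cents; and the
sample covariance of RPE and IPE over the uniform enumeration is zero,
because swapping colours flips RPE while preserving IPE.

## Behavioural simulator

Sessions are 7 blocks × 16 trials. Choices come from a logistic agent,
`Pr(informative) = σ(choice_noise · (info_value − cost))` with
`info_value` in cents and `choice_noise` in inverse cents. Defaults
(`info_value` 0.5 ¢, `choice_noise` 1.5 ¢⁻¹, participant-level
`info_value` SD 0.75 ¢) give a cohort-mean Pr(informative) near 0.36–0.39
over the default cost levels with wide inter-individual spread, matching
the qualitative behavioural picture of strong preference at zero cost that
declines with price. The cost levels {0, 1, 2} ¢ are a package choice (the
task only fixes that cost is variable); they are uniformly interleaved and
configurable.

Catch trials occur at rate 0.10; compliance is Bernoulli per participant
(default 0.98); each failure deducts $1 and more than two failures flags
the session as excluded from analysis. **Catch trials emit no labelled card
events**: the white X hides one card's colour, so the belief trajectory of
the remaining cards leaves the 21-state graph; rather than invent an
off-graph belief model for ~10% of trials, the simulator keeps catch trials
only for the attention/economy bookkeeping and for their outcome-screen
event. Informative-choice outcomes equal the drawn majority colour;
non-informative outcomes are an independent fair draw; the information
cost is deducted on informative-choice wins only, so payoffs are never
negative. The $15 payment cap affects only the reported winnings metadata.

## Synthetic EEG

Each card and outcome-screen event adds three parametric components:

| component | template | window used for measurement | electrodes |
|---|---|---|---|
| FRN | Gaussian, peak 275 ms, SD 40 ms | 200–350 ms | Fpz, AFz, Fz, FCz, Cz |
| N1 | Gaussian, peak 175 ms, SD 15 ms | 150–200 ms | Fz, F3, F4, Cz, C3, C4 |
| LPP | smoothed boxcar 400–700 ms (edge SD 30 ms) | 400–700 ms | Cz, CPz, CP1, CP2, Pz |

Templates are normalised so their mean over the measurement window is 1:
a modulation coefficient of c µV therefore produces exactly a c µV
window-mean difference in the noiseless forward model, which makes
parameter-recovery targets unambiguous. Amplitude per event is
`base + sign modulations + participant intercept (SD 1 µV) + trial jitter
(SD 1 µV)`. Default sign modulations (FRN: −1.4 µV for negative RPE,
−2.1 µV for negative IPE; N1: −1.3/−1.1 µV; outcome screens: −0.8 µV for
losses) approximate the 1–2 µV condition differences typical of published
feedback-ERP work; they are generator settings, not fitted or target
values. Topographies are fixed gain tables (1.0 over each component's
electrode set, 0.25 elsewhere, 0 at the mastoids) — there is no
volume-conduction or head model, no ocular physiology, and no
channel-covariance structure beyond the shared mastoid reference, which is
the main fidelity gap relative to real EEG: passing recovery tests show the
measurement chain is correct and calibrated, not that it would be robust to
real artifact topographies. Noise is per-channel pink (1/f-amplitude
spectral shaping, scale 8 µV) plus white (SD 8 µV). Event spacing is kept
at ≥ 1 s, the epoch half-width.

## ERP pipeline

Preprocessing: per-channel closed-form linear detrend; 4th-order
Butterworth high-pass at 0.1 Hz, low-pass at 70 Hz and band-stop at
45–55 Hz, each applied forward–backward (zero phase) as second-order
sections with generous reflect padding (the 0.1 Hz edge has a transient of
several seconds, confined to the recording edges outside any analysis
window); then re-referencing to the mastoid average. The exact filter
family and order are package choices — tests assert attenuation contracts
(≥ 20 dB at 50 Hz, pass-band preservation), not coefficients. Eyeblink ICA
and channel interpolation are out of scope; the amplitude screen alone
handles the synthetic artifacts.

Epochs run −1000…+1000 ms around each event with a −100…0 ms baseline;
windows are closed on the left and open on the right, and the t = 0 sample
belongs to the post-stimulus side. The artifact screen flags epochs with
any |sample| > 200 µV on any non-mastoid channel. Component amplitudes are
window means measured on per-condition averages (identical to averaging
single-epoch window means under equal weights). Binning schemes cover RPE
sign, IPE sign (with and without the zero bin), information sign,
pseudo-labels for non-informative stimuli (the same card sequences
relabelled as if informative), and outcome screens (pooled and split by
preceding stimulus kind); zero-labelled epochs are excluded except in the
explicit zero-inclusive scheme. A participant enters an analysis only when
every bin of that analysis keeps ≥ 20 artifact-free epochs, which makes the
analysis N vary with individual choice behaviour, as it does in real
cohorts.

## Statistics

The repeated-measures ANOVA (one or two within-subject factors) uses the
textbook subject × factor sums-of-squares decomposition with
per-effect error terms. The Greenhouse–Geisser epsilon is the sample
estimator `tr(V)² / (df · tr(V·V))`, `V = C′SC`, with `C` an orthonormal
contrast basis for the effect (Kronecker products of Helmert-style
contrasts and level means for two-way designs) and `S` the covariance of
the condition columns; epsilon is clipped to `[1/df, 1]`. The correction
multiplies both degrees of freedom by epsilon and is applied when
epsilon < 1 (an always/never override exists); corrected p-values are
therefore never smaller than uncorrected ones, and a two-level factor has
epsilon ≡ 1 with F equal to the squared paired t statistic. Effect size is
partial η² = SS_effect / (SS_effect + SS_error). Post-hoc paired t-tests
use Bonferroni correction `p = min(1, m·p_raw)`; degenerate zero-variance
inputs return t = 0, p = 1 on the null and a signed infinite t with an
underflow-safe tiny p off it. All tests are two-sided. The implementation
is cross-checked in the test suite against an explicit loop-based
sums-of-squares oracle and against pingouin.

The behavioural analysis runs the rm-ANOVA of preference over cost levels,
a t-test of zero-cost preference against 0.5, a t-test of preference at
positive costs against 0, and a t-test of per-participant OLS cost slopes
against 0.

## Monte-Carlo studies and problem sizes

The end-to-end recovery study simulates 100 cohorts of 20 participants
(full 7 × 16 sessions) and checks that the IPE-sign FRN difference covers
the injected −2 µV in its across-participant 95% CI and is detected at
α = 0.05 in ≥ 80% of cohorts; the type-I-error study runs 500 null
replicates (8 participants × 32 trials, information-preferring agents so
both sign bins stay above the inclusion threshold) and checks the
rejection rate stays at 0.05 within Monte-Carlo error. These studies run
at a reduced sampling rate (200 Hz) and on the FRN electrode subset plus
mastoids — choices that keep a desk-scale simulation practical while
leaving the event structure, filters, windows, inclusion rules and
statistics identical to the full-scale configuration. Estimates of the
condition difference inherit sampling variability from each participant's
realised trial composition (the RPE-sign mix within each IPE bin);
this is genuine design variance, captured by the across-participant CI,
not estimator bias.

## Known limitations

* No volume conduction, ocular artifacts, ICA or channel interpolation;
  the artifact model is transient amplitude excursions only.
* The choice agent is a one-parameter logistic in cost; it fits no real
  data and models no reaction times.
* Catch trials carry no labelled card events (see above), a simplification
  relative to observers who might partially update beliefs around the
  hidden card.
* Fixture EEG is stored as epochs for all but one continuous recording, to
  keep fixture directories small.
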