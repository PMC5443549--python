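# Methods

This note documents the models, estimators and numerical choices behind
`cyclenet`, and the reasoning for the design decisions that were genuinely
open.

## The system being modelled

*Leptothorax* colonies inside a small nest (63×42 mm internal area, ~77
workers) interact through frequent brief pairwise contacts. Colony activity
is strongly structured in time at two scales: short-term activity cycles
(STACs) — quasi-periodic colony-wide bursts with a dominant period λ around
960 s — and a diurnal cycle (lights 07:00–19:00; days are more active, with
faster and stronger short-term cycles than nights). The package asks how
this temporal structure shapes the spread of information carried by
contacts.

## Contact inference geometry

Each ant is approximated by a trapezoid anchored at its tracked thorax
position, long axis along the body orientation, with an interaction point on
the front edge. Defaults (length 3.2 mm, front width 1.0 mm, back width
1.6 mm, interaction point 1.6 mm ahead) are a typical *Leptothorax* worker
body scale; they are configurable, and because every downstream analysis is
threshold-relative, the absolute geometry scale only shifts absolute contact
counts. A contact opens at the first frame where (i) at least one
interaction point is inside the partner's trapezoid and (ii) the circular
orientation difference is ≥ θ; it closes at the first frame where both
interaction points are outside. Design choices:

- **Onset-only angular gate.** The termination rule is stated purely in
  terms of interaction points, so a contact that opens head-on persists if
  the pair later rotates. Whether the gate should be re-evaluated
  continuously is genuinely ambiguous; onset-only is implemented and the
  alternative would only shorten events.
- **Inclusive boundaries.** A point exactly on a trapezoid edge counts as
  inside (deterministic tie-break).
- **Missing detections** close any open contact at the last seen frame;
  re-detection opens a distinct event.

## Activity series and wavelet periodogram

Movement activity is the per-frame mean of instantaneous speeds (frame
displacement × frame rate) of all ants detected in consecutive frames;
contact rate counts each contact twice, at its start and its stop. Both are
binned at 60 s by default before spectral analysis.

The periodogram is a global (time-averaged) continuous-wavelet spectrum:

- Mother wavelet: complex Morlet with nondimensional centre frequency
  ω₀ = 6 (PyWavelets `cmor2.0-0.9549`), the standard choice for
  quasi-periodic ecological series; the Fourier period at scale s is
  1.033 s.
- Scale grid: 64 log-spaced periods spanning the requested band, default
  4–120 min. The band must lie within [2·bin, duration/2] and the series
  must cover at least 4× the longest period.
- Cone of influence: bins within √2 × (Fourier-period-equivalent scale) of
  either edge are excluded from the time average at that scale.
- Normalisation: `power_raw` is the time-averaged squared transform
  magnitude of the mean-subtracted series (it scales with amplitude²);
  `power` is `power_raw` renormalised to sum to 1 over the analysed band.
  Under this convention white noise has a flat expected spectrum, so the
  dominant period λ (argmax; ties break to the shortest period) is read
  against a level background, and `power` is interpretable as the fraction
  of in-band variance per period.
- Missing bins are linearly interpolated up to 5 consecutive bins; longer
  gaps fall back to the series mean with a logged warning.

γ = 1/λ converts the dominant period to a cycle rate in s⁻¹, directly
comparable with the loss rate μ.

## The UIU transmission model

Two states, uninformed (U) and informed (I). During the overlap of a
contact between a U and an I ant, transmission U→I is a Poisson process with
rate β (s⁻¹), capped at one success per contact; informed ants revert I→U
with rate μ (s⁻¹) at any time. β and μ are in per-second units so μ can be
compared with γ dimensionally.

The simulator is event-driven and exact (no time discretisation): contact
onsets are consumed in time order; candidate transmission times (exponential
draws checked against the remaining overlap) and loss times live in a
priority queue. Numerical/semantic choices:

- **Attempt restarts.** If the U–I configuration of an ongoing contact
  changes (a participant flips state through a loss or another contact),
  pending attempts on that contact are invalidated and a fresh exponential
  attempt is drawn if a U–I configuration holds again. The once-per-contact
  cap applies per (contact, direction): a direction that has already
  transmitted in a contact cannot transmit again in that contact.
- **Tie-breaking.** Simultaneous events resolve losses before
  transmissions, then by ant identity, so replays are deterministic.
- **Window edges.** Contacts already in progress at t₀ participate with
  their remaining overlap only; a run ends at extinction or the window end
  (censored).
- **RNG discipline.** Ensembles split a master seed with
  `numpy.random.SeedSequence.spawn`, so run k is reproducible in isolation;
  each run draws its own uniform seed ant.

`beta = inf` gives deterministic transmission at overlap start, in which
case the final informed set equals the time-respecting forward-reachable
set — verified against an independent brute-force reachability oracle.

## Time-explicit steady state and the four metrics

On a non-stationary network the SIS quasi-stationary level is itself
time-dependent. The steady state at focal start time t₀ is defined by a
reference ensemble launched at t₀ − τ; its mean informed count **across
extant runs** traces the steady-state level over [t₀, t₀ + window]. τ is
chosen as the smallest candidate (defaults 2λ, 4λ, 8λ, 16λ) for which
references launched at t₀ − τ and t₀ − 2τ produce extant-mean curves within
5% of each other (the reference has forgotten its launch time); if none
converges the largest candidate is used with a logged warning. τ is
determined once per (network, β, μ) at a representative start time and
reused across t₀ — it reflects the relaxation time of the dynamics, not the
particular start time.

- **P_breakout** — fraction of focal runs with at least one transmission
  beyond the seeding. Reference-free by definition.
- **P_sustain** — fraction of focal runs whose informed count reaches the
  reference mean (hitting time); T̄ is the mean hitting time.
- **P_informed** — grand mean informed count over [hit, hit + persistence
  window] (default 1 h), among runs extant throughout that window, divided
  by colony size.
- **P_lost** — among runs extant at T̄, the fraction that later decline to
  zero before the window end; censored runs never count as lost.

**Degenerate start times.** If every reference run dies before t₀ the
steady state does not exist there. Per-t₀ results carry a `degenerate` flag
with NaN for the reference-relative metrics. At the recording level,
P_breakout averages over *all* start times, and a degenerate t₀ contributes
P_sustain = 0: the reference ensemble's total extinction is direct evidence
that information cannot become self-sustaining at that time. Dropping such
t₀s instead would average each network over only its favourable start times
— on strongly periodic networks at μ ≳ 0.01 this selection inflates the
observed−expected comparison enough to flip its sign. The conditional
quantities P_informed and P_lost remain averaged only where defined. (The
rejected alternative of treating a dead reference as a zero steady-state
level would make every run hit trivially, P_sustain = 1, which is worse.)

Defaults: 100 focal and 100 reference runs per t₀, start times every 3600 s
with margins, observation window min(24 h, time remaining), evaluation grid
60 s.

## Aperiodic null model

For each edge (unique interacting pair), all of that edge's contacts are
displaced by one uniform shift in [−λ/2, +λ/2]; start times wrap circularly
around the recording. Independent per-edge shifts of up to half a cycle
destroy the colony-wide phase alignment (dominant-period power drops by
well over half) while per-edge contact counts and every contact's duration
are conserved exactly, and — because shifts are minutes, not hours — the
diurnal profile is essentially untouched. Boundary handling was genuinely
open (wrap, truncate or reflect); wrap is used because it is the only rule
that conserves counts and durations exactly. A wrapped contact keeps its
full duration, so its end may overhang the nominal recording end by less
than one contact duration.

Sweeps evaluate the four metrics over a {β, μ} grid on the observed network
and on n null replicates (default 20); expected = mean over replicates,
difference = observed − expected, and per-cell empirical significance is a
two-sided rank test of the observed value within the null distribution.
The loss rate of maximal inhibition μ* is the most negative difference
along μ at fixed β (ties to the smallest μ); for P_lost, where impeded flow
*raises* the metric, the curve is negated before the argmin so that μ*
marks the maximal inhibition for all four metrics consistently.

## Synthetic colony generator

The generator emulates the statistical structure of the reference
recordings, not individual behaviour:

- **Activity profile**: level(t) = diurnal(t) × (1 + a(t)·w(phase)), with a
  sinusoid (default) or a relaxation waveform (exponential build-up, sharp
  discharge) for the short-term cycle; a step diurnal baseline at the
  lights-on/off boundaries (day 1.3×, night 0.7× by default); and night
  factors that slow the cycle (×1.4 period) and damp its amplitude (×0.6),
  matching the observation that night cycles are slower and weaker. The
  temperature ramp accompanying the light switch is not modelled.
- **Contact sequences**: inhomogeneous Poisson onsets with intensity =
  mean rate × profile (profile normalised to unit mean, so the configured
  rate is the realised average; 0.3 onsets/s by default, the order of an
  instrumented colony's head-on contact stream), uniform random pairs
  (optionally weighted per pair), and log-normal durations (median 5 s,
  σ_ln = 0.8). Durations are unreported for the reference system; no
  invariant depends on this choice.
- **Trajectories**: correlated random walks (per-frame Gaussian heading
  noise, default 25°/frame at 2 Hz) with step length scaled by the activity
  profile, reflecting walls, orientation = heading. The frame rate default
  (2 Hz) is a declared choice; individual movement statistics (speed
  distribution, turning kernel) are not fitted to data, because none are
  published for this system.

What passing tests on generated data do *not* show: real colonies have
spatial structure (brood pile, queen court, entrance traffic),
heterogeneous per-pair contact propensities, and quasi-periodic (not
phase-coherent) cycles; the generator's uniform mixing and coherent
oscillator are idealisations. Conclusions established here are about the
effect of temporal patterning per se, under controlled conditions.

## Problem sizes used in the validation suite

The qualitative headline checks run on scaled-down colonies chosen to keep
the full suite fast while preserving the relevant time-scale ordering
(contact interval ≪ 1/μ, λ ≪ window): 40-ant, 24-h strongly periodic
networks (full-depth 960-s cycles) with two null replicates, ensembles of
40 runs at ~10 start times for the periodic-vs-aperiodic comparison at
β = 1, μ ∈ {2·10⁻⁴ … 10⁻²}, with a 6-minute prevalence persistence window
(a short window avoids survivorship selection: a window of many information
lifetimes would reduce P_informed to a survivor-only comparison at high
μ); a 30-ant, 30-h diurnal-only colony for the
day/night contrast (β = 1, μ = 0.006); and 500-run ensembles per cell for
the monotonicity checks. μ = 0.02 is excluded from the comparison grid
because 1/μ = 50 s leaves the reference ensemble extinct before t₀ at
essentially every start time (the steady state is undefined there by
construction).

## Known limitations

- There is no canonical wavelet family, scale grid or detrending
  convention for these series; the Morlet/64-scale/mean-subtraction choices
  here are declared defaults, and λ is only resolved to the scale-grid step
  (~5.5%).
- The τ-determination rule (5% self-consistency between τ and 2τ) is a
  declared algorithm; the only hard requirement is that τ suffice for the
  reference ensemble to converge to the steady state.
- The empirical significance uses a small null ensemble (default 20) and a
  rank test; it resolves p no finer than 1/(n+1).
- `P_informed` requires runs extant through the whole persistence window;
  on short observation windows this censors late hitters.
- Trajectory-based contact detection is O(n² · frames) and intended for
  colony-scale (tens of ants), not thousands.
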