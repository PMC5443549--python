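# cyclenet

Collective activity cycles and information transmission on time-ordered ant
contact networks.

Colonies of *Leptothorax* ants synchronise their activity into short-term
activity cycles (STACs): quasi-periodic, colony-wide bursts of movement and
physical contact recurring every ~16–20 minutes, superimposed on a diurnal
rhythm (faster, stronger cycles by day than by night). Because physical
contacts are the substrate over which ants exchange information — chemical
cues, recruitment signals, passive encounters — the temporal patterning of
the contact network shapes how far and how reliably information spreads.
`cyclenet` provides the full analysis chain for asking that question
quantitatively, for researchers in collective behaviour, social-insect
biology and temporal-network epidemiology.

## What it computes

**Contact inference.** Each ant is a trapezoid anchored at its tracked
position with an *interaction point* at the front; a contact opens when one
ant's interaction point enters the other's trapezoid and the circular
orientation difference exceeds a threshold θ ∈ {0°, 60°, 120°}, and closes
when both points are outside (`cyclenet.contacts`).

**Activity spectra.** Colony-level movement activity (mean instantaneous
speed) and contact rate (contact starts + stops per bin) are binned at one
minute and decomposed with a Morlet (ω₀ = 6) continuous wavelet transform.
The time-averaged spectrum over a log grid of periods gives the dominant
cycle period λ, the cycle rate γ = 1/λ, and the cycle amplitude (power at
λ) (`cyclenet.spectral`).

**UIU transmission model.** An SIS-type two-state process relabelled for
information: during contact between an uninformed (U) and an informed (I)
ant, transmission U→I occurs as a Poisson process with rate β per second of
U–I overlap, at most once per contact; informed ants revert I→U at rate μ at
any time. Simulations are event-driven on the raw time-ordered contact
sequence, so spread follows time-respecting paths only (`cyclenet.uiu`).

**Time-explicit steady state and metrics.** On a non-stationary network the
steady state is defined by a *reference* ensemble launched τ before each
focal start time t₀; a focal run "sustains" when its informed count reaches
the reference's extant mean. Four metrics — P_breakout, P_sustain,
P_informed, P_lost — are sampled at regularly spaced t₀ across the recording
(`cyclenet.metrics`).

**Aperiodic null model.** Each edge's contact timeline is shifted by an
independent uniform offset within ±λ/2 (circular). This destroys the
colony-wide oscillation while conserving every contact count and duration
and the diurnal profile; transmission differences observed − expected over a
{β, μ} grid quantify the effect of periodicity, including the loss rate μ*
of maximal inhibition to compare with γ (`cyclenet.nullmodel`).

**Synthetic colonies.** A generator emulating 3-day recordings of ~77
workers in a 63×42 mm nest — inhomogeneous-Poisson contact sequences and
correlated-random-walk trajectories driven by a controllable activity
profile (cycle period/amplitude, day/night levels, lights 07:00–19:00) —
provides ground-truthed inputs (`cyclenet.synth`).

## Worked example

```python
from cyclenet import (make_fixture, contact_rate, wavelet_periodogram,
                      cycle_rate, time_shift_null)

network, truth = make_fixture("periodic_strong", rng=7)   # 40 ants, 24 h
pg = wavelet_periodogram(contact_rate(network, bin_s=60.0))
print(pg.lambda_s, cycle_rate(pg.lambda_s))
# 976.8251638950202 0.001023724651003637
```

The embedded 960-s cycle is recovered to within one scale-grid step
(976.8 s on the 64-point log grid), i.e. γ ≈ 0.0010 cycles per second.
Running `python examples/05_null_comparison.py` then prints, for β = 1:

```
mu = 0.005 (mu > gamma):
  p_breakout  observed=0.693 expected=0.750 diff=-0.057
  p_sustain   observed=0.543 expected=0.679 diff=-0.136
  p_informed  observed=0.562 expected=0.677 diff=-0.115
  p_lost      observed=0.047 expected=0.000 diff=+0.047
```

When information is short-lived relative to the cycle (μ > γ), the periodic
network transmits *worse* than its aperiodic null — quiescent troughs act as
barriers: fewer runs break out of the seed, fewer sustain, prevalence is
lower and total loss more likely. With μ < γ the differences shrink towards
zero (informed ants outlive the troughs). The `examples/` scripts walk
through each capability; a thin CLI (`cyclenet synth|contacts|spectral|
simulate|metrics|compare|pipeline|fixture`) wraps the same functions for
shell use.

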