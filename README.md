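# teamneuro

Symbolic team neurodynamics from multichannel EEG: band-power
symbolization, sliding-window entropy, and neurodynamic information (NI).

## What problem this solves

Teams under stress — an operating-room crew working through a difficult
intubation, a simulation team handling a seizing mannequin — show
*neurodynamic organization*: prolonged stretches during which the joint
EEG-power state of the members dwells in a small part of its possible
state space. `teamneuro` detects and quantifies these periods from
per-second EEG band power, for researchers studying team cognition with
hyperscanning EEG who need a second-by-second, information-theoretic
measure of when a team (or a member) is organized, and against what null.

## The measure

For each team member, sensor and 1-Hz frequency bin (1–40 Hz), per-second
power is discretized by whole-recording tertiles into levels
{−1 low, 1 average, 3 high}. The ordered member levels at each second form
a team *neurodynamic symbol*; for a triad the symbol state space has
3³ = 27 states (the symbol for "member 1 low, member 2 high, member 3
average" = (−1, 3, 1) encodes to index 7). Over the per-second symbol
stream of each (sensor, bin), a 60-s causal sliding window yields the
plug-in Shannon entropy H, inverted as *neurodynamic information*

&nbsp;&nbsp;&nbsp;&nbsp;NI(t) = log₂ S − H(t)  [bits],  S = 3ⁿ (team) or 3 (member),

so organized (predictable) stretches carry high NI. Observed NI is judged
against the interquartile envelope of member-wise shuffled streams, which
sits at the entropy estimator's bias floor. Downstream analyses: member
decomposition, lead/lag cross-correlation between member NI traces,
frequency-band and anterior/posterior region contrasts (rank-sum,
Kruskal–Wallis), ±60-s event bracketing, and raw-level composition.
Details and design rationale: [docs/methods.md](docs/methods.md).

## Worked example

A triad, three frontal sensors, alpha-range bins, 800 s, with a
team-wide organization epoch of *low* power at 400–520 s (organization is
about persistence, not power direction — persistent low power is just as
organized as persistent high power):

```python
import numpy as np
from teamneuro import (
    SynthConfig, GroundTruthEpoch, generate_power_tensor,
    discretize_tensor, team_nds_from_levels, sliding_ni, average_ni,
    shuffle_baseline, iqr_profile, member_ni, cross_correlate,
)

cfg = SynthConfig(
    sensors=("F3", "Fz", "F4"), bins=(9, 10, 11), duration_s=800, seed=42,
    epochs=(GroundTruthEpoch(member="team", interval=(400, 520), forced_level=-1),),
)
tensor, truth = generate_power_tensor(cfg)
streams = discretize_tensor(tensor)            # 27 individual level streams
team = team_nds_from_levels(streams)           # 9 team symbol streams

print(f"{len(streams)} individual and {len(team)} team streams, "
      f"state space {team[0].n_states} symbols, Hmax {sliding_ni(team[0]).hmax:.3f} bits")

ni = average_ni([sliding_ni(nds) for nds in team])
q25, q75 = iqr_profile(ni)
peak = int(np.nanargmax(ni.values))
print(f"team NI: peak {np.nanmax(ni.values):.2f} bits at t={peak} s; "
      f"IQR ({q25:.2f}, {q75:.2f})")

levels = np.stack([np.stack([s.levels for s in streams if s.member == m])
                   for m in tensor.members])
env = shuffle_baseline(levels, n_shuffles=100, seed=42)
above = np.nanmean(ni.values[459:520] > env.q75)
print(f"shuffle baseline IQR ({env.q25:.2f}, {env.q75:.2f}); "
      f"{100*above:.0f}% of epoch seconds exceed q75")

m1 = member_ni([s for s in streams if s.member == "M1"])
m2 = member_ni([s for s in streams if s.member == "M2"])
res = cross_correlate(m1, m2, max_lag_s=60)
print(f"member NI cross-correlation: r={res.r:.2f} at lag {res.lag_s:+d} s")
```

Output:

```
27 individual and 9 team streams, state space 27 symbols, Hmax 4.755 bits
team NI: peak 2.59 bits at t=519 s; IQR (0.39, 0.45)
shuffle baseline IQR (0.33, 0.37); 100% of epoch seconds exceed q75
member NI cross-correlation: r=1.00 at lag -1 s
```

Reading it: outside the epoch, team NI hovers in its IQR just above the
shuffled-data IQR (0.33–0.37 bits) — that gap is the estimator's bias
floor, not organization. During the injected epoch the trace climbs to
2.59 bits, peaking at t = 519 s (the 60-s window trails the epoch), and
every epoch second clears the randomized q75. Because the epoch is
team-wide, the two members' NI traces move together: cross-correlation
r = 1.00 at a lag of −1 s, i.e. essentially synchronous coordination.

## Command line

```sh
teamneuro simulate --seed 7 --duration 800 --out power.csv
teamneuro ni power.csv --out team_ni.csv
teamneuro run --config run.yaml --seed 7 --out results/
```

`run` executes the whole chain (power → symbols → NI → baseline → band
aggregation) from a YAML config and writes tidy CSV artifacts plus a
manifest with the seed and config hash; identical config and seed give
byte-identical outputs. Exit codes: 0 success, 2 validation error,
1 runtime error.

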