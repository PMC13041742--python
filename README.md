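# gatingspring

Single-molecule force-spectroscopy analysis and gating-spring modelling for
tethered mechanosensitive channels, built around the NompC channel of
*Drosophila*: its ankyrin-repeat domains (ARDs) form the compliant "gating
spring" that transmits mechanical stimuli to the channel gate.

The package is aimed at optical-tweezers practitioners and modellers who
want to (i) analyse differential pulling experiments, where a protein is
swapped into a pre-measured DNA tether by toehold-mediated strand
displacement so its absolute force–extension curve can be obtained by
subtraction, (ii) analyse constant-force gating flicker, and (iii) explore
a quantitative Boltzmann model of channel opening driven by ARD tension.
A ground-truth synthetic data generator makes every stage testable without
laboratory data.

## The model

**Tether mechanics.** DNA handles and unfolded polypeptide are inextensible
worm-like chains (WLC) with the interpolation force law

F(x) = (k_B T / P) [ 1/(4 (1 − x/L)²) + x/L − 1/4 ],

with contour length L (0.338 nm/bp for DNA, 0.365 nm/residue for
polypeptide) and persistence length P (40 nm and 0.6 nm respectively), and
the matching entropic energy E(x) = (k_B T/P)(L/4)(3r² − 2r³)/(1 − r),
r = x/L, which is the exact integral of F. The structured protein portion
is an elastic rod, x_s = x₀ + F/k, the nanodisc a rigid ~5 nm offset, and
a bead-to-bead tether is a series composition sharing one tension:
X = x_d + x₀ + F/k + x_u. Compliances add in series; parallel bundles of
n identical chains share the force as F/n each.

**Differential pipeline.** Raw trajectories are boxcar-filtered (50–200 ms),
discretized into uniform force bins, and the DNA-only binned extension,
the disordered-tail WLC extension and the nanodisc offset are subtracted
from the protein–DNA extension. The structured-protein extension is fit
with F = k (x − x₀) to give the gating-spring force constant. Rips are
detected as abrupt extension jumps, branches are fit globally with the WLC
model, and branch contour-length gains map to unfolded residue counts
(gain / 0.365 nm) and ankyrin-repeat counts (residues / 33).

**Gating.** At quasi-static loading the open probability is Boltzmann,

P_open(x) = 1 / (1 + exp(ΔE(x)/k_B T)),

where ΔE is the open/closed energy difference of the stretched complex,
E = F²/2k + E_u + V, with a gating swing of 4.6 nm added to the open-state
intrinsic length and a gate energy V = 8 k_B T. The four ARDs act as a
coupled spring network linked at the N-terminal contact site: with 29
repeats split 9/20, the effective stiffness with N subunits pulled is
k_T(N) = 29N/(9 + 5N) · k_a.

## Worked example

```python
import numpy as np
import gatingspring as gs
from gatingspring.simulate import construct_truth, simulate_pull, simulate_dna_only
from gatingspring.pipeline import differential_stiffness
from gatingspring.io import RunConfig

root = np.random.SeedSequence(1)
truth = construct_truth("wt")            # rod k = 0.7 pN/nm behind DNA handles
streams = root.spawn(6)
dna = [simulate_dna_only(truth, rng=np.random.default_rng(s))[0] for s in streams[:3]]
pulls = [simulate_pull(truth, rng=np.random.default_rng(s))[0] for s in streams[3:]]
result = differential_stiffness(dna, pulls, RunConfig())
print(result["stiffness"].summary())
```

prints

```
Linear gating-spring stiffness fit
----------------------------------
force range        : 1.00 - 7.00 pN
bins / molecules   : 31 / 3
stiffness k        : 0.6961 +/- 0.0074 pN/nm
intrinsic length x0: 19.98 +/- 0.082 nm
converged          : True
```

i.e. the pipeline recovers the generating force constant (0.7 pN/nm) and
intrinsic length (20 nm) of the folded complex from noisy paired pulls.
The gating model side:

```python
print(gs.midpoint_force(gs.GatingConfig()))
# {'x_star_nm': 34.48, 'F_closed_pN': 8.57, 'F_open_pN': 5.71, 'F_avg_pN': 7.14}
print(gs.gating_energy(6.9, 4.7).summary())
# work : 32.43 pN nm = 7.91 kBT = 4.67 kcal/mol
```

The midpoint is the extension at which open and closed states are equally
probable; the average tension there (~7.1 pN) is the model's gating force,
and 6.9 pN × 4.7 nm is the measured gating work in thermal and molar units.

A command-line surface wraps the same pipeline:

```bash
gatingspring fixtures --seed 7 --out data/
gatingspring analyze-fec data/wt_*.tsv --dna data/dna.tsv --out report.json
gatingspring model-curves --out curves.tsv
```

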