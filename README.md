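# protoncage

Analysis pipeline for thermally activated proton displacement between a
carboxyl group and a water molecule, the elementary exchange step at the
active site of proton pumps such as bacteriorhodopsin (the D85/D212
carboxyl pair with the central water molecule and one excess proton).

Because ab initio molecular dynamics of this model system is far beyond
desk scale, the package ships a **stochastic surrogate generator** with
analytic ground truth, and the analysis tools that consume either the
surrogate's trajectories or real Cartesian (extended-XYZ) trajectories:

* **Surrogate dynamics** — overdamped Langevin sampling of the two
  effective reaction coordinates: the carboxyl-oxygen-to-water-oxygen
  distance `x = Ro_c_o_w` and the proton asymmetry
  `q = Ro_c_h − Ro_w_h` (negative: proton on the carboxyl oxygen;
  positive: on the water oxygen), on an analytic surface
  `F(x, q) = ½k_x(x−x0)² + B(x)·((q/q0)²−1)² + s(x−x_c)·q` (in k_BT)
  whose projected forward transfer barrier is calibrated to 3 k_BT and
  whose kinetics give a ~1 ps mean proton residence time at 300 K.
* **Reaction coordinates** — nearest-oxygen proton ownership, asymmetry
  series, and three-centred (bifurcated) hydrogen-bond detection from
  Cartesian frames.
* **Free energies** — Boltzmann inversion `F = −k_BT ln P` of 2D (x, q)
  histograms and of the q-projection, with block-averaged errors and
  forward/reverse barrier extraction.
* **Kinetics** — hysteresis two-state discretization of q, dwell
  extraction with censoring, and residence-time statistics.
* **NMR exchange** — two-site Bloch–McConnell forward models:
  population-weighted shifts, exchange lineshapes and coalescence, and
  z-exchange (EXSY) diagonal/cross-peak intensities with rate inversion.
* **Structure checks** — PDB parsing and unique-atom distance queries
  (e.g. carboxyl-oxygen-to-water distances in an active site).

## Worked example

```python
import numpy as np
from protoncage import *
from protoncage.coords import CoordinateSeries
from protoncage.fes import barrier_heights, project_to_asymmetry
from protoncage.kinetics import discretize, extract_dwells, residence_stats

rc = simulate_rc_langevin(SurrogatePES(), LangevinSettings(seed=1),
                          SimulationProtocol()).production_frames()
series = CoordinateSeries.from_rc(rc)
profile = project_to_asymmetry(series, np.arange(-1.0, 1.0001, 0.05))
est = barrier_heights(profile)
stats = residence_stats(extract_dwells(discretize(series)))
```

prints (via the obvious format statements):

```
analyzed time   : 80.0 ps (320001 frames)
forward barrier : 2.79 +/- 0.22 kBT (water -> carboxyl)
reverse barrier : 2.79 +/- 0.37 kBT
well positions  : q = -0.47 / +0.48 A
mean residence  : 0.87 +/- 0.08 ps (84 dwells)
```

The default protocol is a 40 ps production run (first 5 ps discarded as
equilibration) plus nine 5 ps replicas started from production snapshots:
80 ps of analyzed dynamics.  Boltzmann inversion of the asymmetry
histogram recovers the calibrated 3 k_BT forward barrier within its
sampling error, the two wells sit near q = ±0.5 Å (proton bonded to one
oxygen or the other), and the jump statistics give the ~1 ps residence
time the surface was calibrated for.

The same pipeline is available from the shell:

```sh
protoncage simulate --seed 1 --out run.xyz --rc-out series.tsv
protoncage coords   --traj run.xyz --out series_extracted.tsv
protoncage fes      --series series.tsv --out-profile profile.tsv
protoncage dwell    --series series.tsv
protoncage nmr      --shift-a 13.2 --shift-b 12.2 --k-ex 1000
protoncage pdbdist  --pdb data/1c3w.pdb --sel "ASP 85 OD2" "HOH 402 O"
```

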