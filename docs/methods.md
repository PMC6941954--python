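# Methods

## The model system and its surrogate

The object of study is the elementary proton-exchange step between a
deprotonated carboxyl group and a neighbouring water molecule: a 10-atom
model system of two carboxyl groups, one water and one excess proton
(net charge +1 e), with the proton shuttling along the hydrogen bond
between the water oxygen Ow and the nearest carboxyl oxygen.  Two
effective reaction coordinates describe the transfer:

* `x = Ro_c_o_w` — distance between the active carboxyl oxygen and Ow (Å);
* `q = Ro_c_h − Ro_w_h` — proton asymmetry (Å): negative when the proton
  is bonded to the carboxyl oxygen, positive when bonded to the water.

First-principles dynamics of this system is not reproducible at desk
scale, so the package replaces the electronic-structure engine with a
**surrogate free-energy surface** with analytic ground truth,

    F(x, q) = ½ k_x (x − x0)²  +  B(x) f(q/q0)  +  g(x) q        [k_BT]

with `f(u) = (u² − 1)²` a unit-barrier quartic double well,
`B(x) = max(B0 + c (x − x0), B_floor)` a barrier that grows with the
donor–acceptor distance, and `g(x) = s (x − x_c)` a linear tilt.  This is
the simplest form with the two qualitative regimes of the real system:
at short `x` (≈2.4–2.6 Å) the barrier is low and intermediate proton
positions are common; at large `x` the tilt (s < 0) lowers the water-side
well and the proton localizes on the water.  The section along q is a
genuine double well wherever `|g(x)| q0 / B(x) < 8/(3√3)`.

### Parameters (defaults, units)

| parameter | default | unit | meaning / rationale |
|---|---|---|---|
| `x0` | 2.5 | Å | reference O–O distance (typical strong H-bond) |
| `k_x` | 40 | k_BT/Å² | O–O stiffness → σ_x ≈ 0.16 Å, spanning 2.4–2.6 Å |
| `barrier0` | 3.7120 | k_BT | **calibrated**: projected forward barrier = 3 k_BT |
| `barrier_slope` | 8 | k_BT/Å | barrier–distance coupling (low barrier at short x) |
| `barrier_floor` | 0.2 | k_BT | keeps the q-section confining at rare x < 2.07 Å |
| `q0` | 0.5 | Å | well positions q = ±0.5 Å (O–H 1.0 Å vs O···H 1.5 Å at x = 2.5) |
| `tilt` | −2.0 | k_BT/Å² | water-side localization at large x |
| `x_c` | 2.45 | Å | tilt crossover |
| `gamma_q` | 461 | k_BT·fs/Å² | **calibrated**: mean residence ≈ 1 ps at 300 K |
| `gamma_x` | 2000 | k_BT·fs/Å² | slower O–O breathing (relaxation γ_x/k_x = 50 fs) |
| `dt` | 0.25 | fs | see *Numerical choices* |

Both calibrated constants are frozen in code and re-derivable with
`scripts/calibrate_surrogate.py`: `B0` by root-finding on the analytic
q-projection, `gamma_q` by rescaling a measured mean residence time
(residence ∝ friction in the overdamped regime).

### Dynamics and protocol

Sampling uses overdamped (position) Langevin dynamics,
`dz = −γ_z⁻¹ ∂F/∂z dt + √(2 τ dt/γ_z) ξ` with `τ = T/T_ref`, integrated
with Euler–Maruyama.  The default protocol mirrors a thermostatted
40 ps production run at 300 K whose first 5 ps are flagged as
equilibration, followed by nine 5 ps replicas started from evenly spaced
production snapshots with sub-seeds spawned from the master seed; all
post-equilibration frames are pooled **uniformly** (the weighting of
production vs replica segments is not otherwise constrained — this choice
is recorded in each trajectory's provenance).  Total analyzed time:
(40 − 5) + 9 × 5 = 80 ps.

### Cartesian embedding

For testing the extraction code, reaction-coordinate trajectories are
embedded as 10-atom Cartesian frames: O1a at the origin, Ow at (x, 0, 0),
H2 colinear at ((x+q)/2, 0, 0) — so extraction recovers (x, q) exactly —
and the remaining seven atoms at fixed chemically sensible template
positions (C–O 1.25 Å, O–C–O 125°, O–H 1.0 Å, the second carboxyl one
hydrogen-bond length beyond the water).  Template atoms receive Gaussian
jitter in y and z with σ = √(k_BT/k) for a transverse restraint of
stiffness k (default 50 meV/Å² → σ = 0.719 Å at 300 K).  The template was
chosen so that no hydrogen can approach two non-donor oxygens at once:
the embedded system cannot form three-centred hydrogen bonds, matching
the behaviour of the underlying model system.

## Analyses

**Free energies.**  `F = −k_BT ln P + C` from histograms (default bins
Δq = 0.05 Å, Δx = 0.02 Å; no bin sizes are prescribed by the source
data, so these are package defaults).  Unsampled bins are masked, never
interpolated.  Errors come from 8 contiguous blocks, aligned at the
best-sampled bin so the per-block normalisation cancels.  Barriers:
extrema are located on a 3-bin moving-average-smoothed profile (noise
spikes would otherwise masquerade as extrema) but reported at the raw
profile values; a profile without an interior maximum returns an explicit
single-well result instead of raising.  Analytic reference projections
integrate x over x0 ± 0.7 Å, which covers all thermally relevant O–O
distances including rare excursions below the nominal grid domain.

**Kinetics.**  q is discretized with a symmetric core threshold
(default q_core = 0.4 Å, a package choice; a sensitivity sweep helper is
provided): |q| ≤ q_core is ambiguous and inherits the previous committed
state (hysteresis), which makes dwell counts invariant to barrier-top
noise.  First and last dwells are censored and excluded from means.
Residence times are reported per state and pooled; the headline number
used in recovery checks is the pooled mean.

**Two-site exchange (NMR).**  Standard Bloch–McConnell forms, evaluated
in closed form for the 2×2 problem: the absorption lineshape is
`Re[1ᵀ(iωI − A)⁻¹ p]` with `A = diag(i2πν_j − R2_j) − K`; EXSY peak
intensities are `exp(−(K + R1)τ_m)·diag(p)` via eigenprojectors (stable
for arbitrarily fast exchange).  Conventions: `coalescence_rate` returns
the per-direction jump rate of the symmetric problem, k_c = πΔν/√2; EXSY
uses the total rate k_ex = k_AB + k_BA, with detailed balance
p_A k_AB = p_B k_BA enforced at construction (interconversion:
k_AB = p_B·k_ex, k_BA = p_A·k_ex; for equal populations k_jump = k_ex/2).
Rate inversion from a cross/diagonal ratio is a monotone 1-D root find
against the forward model and returns a saturation flag when the ratio
exceeds its theoretical maximum p_B/p_A.  The default water shift for
exchange-with-water models is 4.8 ppm (a documented constant, not a fit).
Spectra are absorption-mode only; no apodization or pulse-sequence
physics is modelled, and no site-specific rates for real protein residues
are asserted — the module is a forward model.

**Bifurcated (three-centred) hydrogen bonds.**  A hydrogen's donor is its
nearest oxygen (covalent when < 1.2 Å); it is flagged bifurcated in a
frame when at least two *other* oxygens lie in the acceptor window
1.2–2.4 Å (optional donor–H···acceptor angle test, off by default).
Excluding the donor is essential: a shared proton midway between two
oxygens is a strong two-centre bond, not a three-centre one.  The exact
geometric criteria are a documented package choice.

## Numerical choices

* **dt = 0.25 fs** (Euler–Maruyama): at dt = 1 fs the product of step
  mobility and well curvature reaches a·F″ ≈ 0.23 and the EM
  stationary-density bias measurably depresses the recovered projected
  barrier (≈ −0.15 k_BT); at 0.25 fs the bias is below the 80 ps sampling
  noise.  Cost is negligible.
* **Barrier floor** B_floor = 0.2 k_BT: without it B(x) turns negative at
  x < 2.07 Å and the surface is unbounded below in q (the integrator
  diverges).  The floored region carries ≈0.3% of the Boltzmann weight.
* Exact ties in nearest-oxygen assignment break to the lowest atom index
  and are flagged.
* A diverging Langevin step aborts with a diagnostic naming dt and the
  friction constants.
* Degenerate inputs return explicit results, not exceptions, where the
  result is meaningful (single-well profiles, EXSY saturation); they
  raise with precise messages where it is not (all-ambiguous state
  series, empty trajectories, unresolvable atom selections).

## What the surrogate does and does not show

The generator emulates the *statistics* the analyses consume: Boltzmann
sampling of a calibrated (x, q) landscape, two-state exponential-dwell
exchange kinetics, transverse thermal jitter of the cage atoms, and the
embedding geometry of the proton between two oxygens.  It contains no
electronic structure, no proton-transfer quantum effects, no explicit
solvent, no periodicity, and—by default—no Grotthuss identity exchange
(only H2 transfers; relabelling on transfer would be an extension).
Passing recovery tests therefore demonstrates that the *analysis
pipeline* is unbiased and correctly calibrated at realistic sampling
volumes (80–200 ps, ~50–100 exchange events), not that the surrogate
reproduces any particular molecular system.  Recovery precision at these
volumes is inherently limited: the 80 ps barrier estimate carries a
~0.2 k_BT standard deviation, and a 100 ps dwell series estimates a 1 ps
residence time with ~10% standard error.

## Known limitations

* The 2D stationarity check compares block-averaged bin free energies;
  with only 8 blocks the per-bin error estimates are themselves noisy, so
  the test asserts distributional agreement (95% of well-sampled bins
  within 3 SE) rather than a hard per-bin bound.
* The crystal-structure distance checks require a user-supplied PDB file
  (structures are not redistributed with the package).
* `Ro_c_o_w` re-selects the nearest carboxyl oxygen frame by frame by
  default; a fixed-oxygen mode is available when a stable pairing is
  known.
* Dwell durations are measured on the sampling grid (run length × dt),
  adding an O(dt) discretization bias — negligible at the default
  resolutions (dt ≤ τ/250).
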