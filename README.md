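# hoptrack

Single-molecule analysis of membrane-binding kinetics and **hopping** —
the transient dissociation and rapid rebinding of peripheral membrane
proteins observed in TIRF microscopy.  Proteins such as the phosphatase
PTEN shuttle between cytosol and plasma membrane; in single-molecule
movies each membrane visit appears as a fluorescent spot that emerges,
diffuses, and vanishes.  Occasionally a molecule re-appears a short
distance away one or two frames later, having "hopped" along the membrane
instead of mixing back into the cytosol.  Distinguishing genuine rebinding
from the constant rain of freshly recruited molecules — under
photobleaching and within a finite cell outline — is the statistical
problem this package solves.

It is aimed at single-particle-tracking practitioners who have either raw
image stacks or pre-tracked trajectory tables and want the full chain:
spot detection, trajectory linking, dissociation and diffusion kinetics,
and the corrected rebinding probability, plus a stochastic simulator to
validate every step against known ground truth.

## The estimator

For the *j*-th vanished trajectory, the density of spot emergences at
distance *r* and delay *t* splits into hopping and recruitment,
*f_j(r,t) = g_j(r,t) + h_j(r,t)*.  Recruitment from the cytosol is
spatially homogeneous with whole-cell emergence-rate density
*ρ(T) = ρ₀ e^(−k₀T)* (decaying by photobleaching), reduced near the cell
boundary: a circle of radius *r* centred *z* from the boundary keeps only
the fraction *1 − arccos(z/r)/π* of its circumference inside the cell.
The rebinding probability over a window (*r* ∈ [r₋, R₀], *t* < t_max) is
then

    P = (1/N₀) Σ_j [counts_j − ρ(T_j) · (in-cell annulus area) · t_max] − P_lateral

where the last term subtracts, for the consecutive-frame window only, the
tail of the fitted lateral-diffusion displacement mixture

    p(r) = Σᵢ aᵢ · r/(2(DᵢΔt+ε²)) · exp(−r²/(4(DᵢΔt+ε²))),

since a bound molecule stepping farther than the 0.45 µm link radius in
one frame mimics a hop.  Membrane residence is summarized by the survival
curve *S(t) = Σᵢ Aᵢ e^(−kᵢt)* whose components define kinetic states
occupied with frequency *(Aᵢ/kᵢ)/Σ(Aⱼ/kⱼ)*.  With bleaching and boundary
effects switched off the estimator reduces to the classic in-vitro
(supported-bilayer) rebinding statistic with constant density
*N₀/(S₀T₀)*.

## Worked example

Simulate the reference condition (10×10 µm membrane, 33 ms frames, 100 s;
association 1 molecule/µm²/s, D = 0.01 µm²/s, k_off = 1/s, rebinding
probability 0.03 with 66 ms returns, photobleaching 0.03/s) and run the
full analysis:

```python
from hoptrack import (SimConfig, simulate, survival_curve, fit_exp_mixture,
                      displacement_distribution, fit_diffusion_mixture,
                      fit_emergence_rate, rebinding_scalar)

cfg = SimConfig()
truth, tracks = simulate(cfg, seed=0)
print(f"trajectories observed: N0 = {tracks.N0}")

fit = fit_exp_mixture(survival_curve(tracks), n=1)
print(f"dissociation rate: {fit.rates[0]:.3f} /s")

dfit = fit_diffusion_mixture(displacement_distribution(tracks), n=1, dt=cfg.dt)
print(f"membrane diffusion: {dfit.diffusion_coeffs[0]:.4f} um^2/s")

rate = fit_emergence_rate(tracks)
print(f"emergence decay: rho0 = {rate.rho0:.3f} /um^2/s, k0 = {rate.k0:.4f} /s")

p = rebinding_scalar(tracks, rate, dfit,
                     t_min=cfg.t_return, t_max=cfg.t_return + cfg.dt,
                     r_min_late=0.0)
print(f"rebinding probability: {p:.4f}")
```

prints

```
trajectories observed: N0 = 3172
dissociation rate: 1.010 /s
membrane diffusion: 0.0100 um^2/s
emergence decay: rho0 = 1.041 /um^2/s, k0 = 0.0315 /s
rebinding probability: 0.0233
```

The fitted dissociation rate is the total spot-loss rate (k_off plus
bleaching), diffusion and the emergence decay recover their configured
values, and the corrected rebinding probability for this single trial is
within one trial standard deviation (~0.009 at this molecule count) of
the configured 0.03; averaging the 12-trial protocol tightens it to
~0.030 ± 0.003.  Negative per-window values are possible and meaningful:
they indicate locally suppressed association.

The same workflow is available from the shell:

```sh
hoptrack simulate --seed 0 --out run/
hoptrack kinetics --tracks run/tracks.csv --components 3
hoptrack rebinding --tracks run/tracks.csv --r-min 0.45 --r-max 2.0 --t-max 0.133
hoptrack pipeline --seed 0 --out run/      # end-to-end with report.json
```

For image-stack input, `hoptrack detect --movie movie.tif --out spots.csv`
performs correlation-map binarization plus sub-pixel 2D-Gaussian
localization, `hoptrack link` applies nearest-neighbour linking with the
0.45 µm split threshold, and `hoptrack chains` reconstructs successions
of hops and fits the hopping-lifetime exponential.

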