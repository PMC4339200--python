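# memscaffold

Membrane-mediated interaction between rigid, strongly anisotropic, curved
protein scaffolds — the mechanism by which BAR-domain dimers, dynamin and
reticulon oligomers and similar membrane-sculpting proteins feel each other
through the lipid bilayer they deform.

A scaffold is modeled as an infinitely rigid patch of an ellipsoid or
hyperboloid (principal curvature radii `rho_a`, `rho_b`, elliptical
footprint `r_a x r_b`) bound to a fluid membrane that pays the Helfrich
bending energy

    F_m = ∫ (κ/2) J² dA,          J = 2H (total curvature),

with κ = 20 k_BT by default and an optional lateral tension γ.  Along each
scaffold rim the membrane normal must match the scaffold normal (normal
continuity).  The package finds the membrane shape of minimal energy on a
triangulated patch for any pair configuration (distance `d`, in-plane
orientation `φ`, tilt `θ`), and assembles from it

* the **elastic interaction** `F_el(d) = F_min(d) − F_min(d_ref)`, with
  `F_m` minimized over the mutual orientation at every distance,
* the **free energy** `F(d) = −kT log ∬ exp(−F_m/kT) dθ dφ` of the
  orientational ensemble, and
* the **orientational-entropy repulsion** `F_ent(d) = F(d) − F_el(d)`.

The numerical core is a cotangent-Laplacian discretization of the Helfrich
energy with an exact analytic gradient, preconditioned staged L-BFGS
minimization seeded by a linearized biharmonic solve, and an adaptive
Boltzmann integration over the orientation angles.  An independent
finite-difference Monge-gauge solver cross-checks the shallow regime.
`docs/methods.md` documents the model, the discretization choices and
their limitations.

## Worked example

Elastic interaction of two shallow circular scaffolds (radius `a`,
`a/rho_a = 0.2`) whose second principal curvature is reversed
(`c_b = −c_a`, a saddle), at the energy-optimal mutual orientation:

```python
from memscaffold.geometry import ScaffoldShape, ModelParameters
from memscaffold.energies import elastic_interaction, fit_power_law

shape = ScaffoldShape.shallow_circular(cb_over_ca=-1.0)
params = ModelParameters(L=150.0, max_iter=3500)
curve = elastic_interaction(shape, [5.0, 5.9, 6.9, 8.1, 9.5], params,
                            d_ref=20.0)
print(curve.to_frame())
print(fit_power_law(curve))
```

prints (energies in k_BT, distances in units of the scaffold radius)

```
     d      F_el  phi_star  theta_star  fronting_azimuth
0  5.0 -0.839970     90.00   -0.269025             90.00
1  5.9 -0.639905     90.00    0.053750             90.00
2  6.9 -0.488919     78.75    0.037100             78.75
3  8.1 -0.339585     78.75    0.120805             78.75
4  9.5 -0.251404     78.75    0.086590             78.75
(-1.9027270625282535, 0.06580687549185626)
```

The saddles attract (`F_el < 0`), front each other with their
lowest-contact-angle faces (`fronting_azimuth ≈ 90°`, the short-axis
faces), barely tilt, and the attraction decays as `1/d^1.9` — the
far-field power law expected for anisotropically curved inclusions.  The
same pipeline with `cb_over_ca=1.0` (spherical caps) gives a pure
repulsion falling off as `1/d^4`, and with `cb_over_ca=0.75` a shallow
energy well at `d* ≈ 2.35 a`.

## Command line

```bash
memscaffold minimize --config cfg.yaml --d 5 --out shape.ply
memscaffold sweep --config cfg.yaml --out curve.csv
memscaffold free-energy --config cfg.yaml --out free.csv
memscaffold fit-powerlaw --curve curve.csv --dmin 5 --dmax 15
memscaffold reproduce fig3 --profile coarse --outdir results/
```

Configurations are YAML with an explicit unit tag; two presets are built
in: `shallow_circular` (`a/rho_a = 0.2`) and `endophilin_nbar`
(`r_a = 6.5 nm`, `r_b = 1.5 nm`, `rho_a = 8.5 nm`).

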