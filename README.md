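# rodshape

Tools for analysing and simulating **surface-to-volume scaling and
aspect-ratio homeostasis in rod-shaped bacteria**.

Rod-shaped cells such as *E. coli* adjust both length and width with growth
conditions, yet their surface area and volume stay locked on a single power
law, S = γV^(2/3), with a prefactor γ ≈ 2π across nutrient conditions,
antibiotic challenge, and gene deletions.  For a spherocylinder the prefactor
depends only on the aspect ratio η = L/w,

    γ(η) = ηπ (ηπ/4 − π/12)^(−2/3),

so a constant γ *is* a constant aspect ratio (γ = 6.24 ↔ η ≈ 4.1).  The
package implements that geometry, the statistics for fitting it to shape
data, and a mechanistic single-cell model that explains it: cell length
grows exponentially (dL/dt = kL) while a division protein (FtsZ) is produced
in proportion to length (dP/dt = k_P·L) and triggers division when the
ring-bound amount reaches a threshold proportional to the circumference,
P₀ = ρπw.  Each cycle therefore adds a fixed length ΔL = ρπw·k/k_P (the
*adder*), the newborn aspect ratio is ρπk/k_P — independent of size and
medium — and a width-control equation

    dw/dt = w (k − βw/4) · (1 − w/3L) / (1 − w/L)

pins the width at w = 4k/β.  Growth-rate shifts move k/β (width) but not
k/k_P (aspect ratio), which is the homeostasis mechanism; perturbing k_P
(FtsZ knockdown, filamentation) or β (MreB depletion) moves cells along
constant-η curves in the S–V plane.

**Audience:** quantitative microbiologists and biophysicists who want to fit
S–V scaling to shape tables, test adder/threshold division models, or
simulate shape dynamics under nutrient shifts and perturbations.

## Worked example

```python
>>> from rodshape import geometry as geom
>>> geom.eta_from_gamma_rod(6.24)      # aspect ratio behind the fitted prefactor
4.075356966643908
>>> geom.gamma_from_eta_spheroid(1.38) # coccoid (prolate spheroid) prefactor
4.920755179583948
```

`python examples/nutrient_shift.py` runs a 200-lineage downshift
(k: 0.75 → 0.25 h⁻¹) and prints:

```
pre-shift newborn aspect ratio : 2.854
peak transient after downshift : 3.443  (+20.6%)
late-time value                : 2.843  (0.40% from baseline)
width: 0.795 -> 0.521 um (new fixed point 4k/beta = 0.520)
```

The newborn aspect ratio overshoots while the width relaxes to the new
4k/β, then returns to its pre-shift value — aspect-ratio homeostasis.  The
other scripts in `examples/` cover the geometry maps, power-law fitting on
synthetic tables, the single-cell adder, and the FtsZ-knockdown /
filamentation perturbations, each printing the numbers it computes and what
they mean.

A thin CLI wraps the same functions:

```sh
rodshape geometry --gamma 6.24            # -> eta = 4.075
rodshape synth --kind population --seed 1 --out pop.csv
rodshape fit pop.csv --out fits.csv
rodshape shift --config shift.yaml --out-dir run/
```

## Layout

- `rodshape.geometry` — spherocylinder / prolate-spheroid closed forms, γ↔η maps
- `rodshape.scaling` — S = γV^β fits, growth law, aspect-ratio and lineage statistics
- `rodshape.divider` — single-cell model (elongation, protein threshold, width ODE)
- `rodshape.population` — ensemble protocols: steady state, shifts, perturbations
- `rodshape.synth` — synthetic shape tables and lineages
- `rodshape.cli`, `rodshape.config` — command line and YAML configuration

See `docs/methods.md` for the model assumptions, parameter defaults, and
numerical choices.
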