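# gelrelease

Forward and inverse modelling of growth-factor retention in heparin-based
hydrogels under a daily media-exchange release assay.

## The problem

Heparin-functionalised hydrogels sequester heparin-binding growth factors such
as EGF (~6.2 kDa) and release them only slowly, which is the property that
makes them useful as sustained-delivery culture scaffolds. The standard bench
characterisation premixes the growth factor into the gel (here 50 ng mL⁻¹ in
1.5 mL of gel in a 12-well plate), overlays 1.5 mL of protein-free media,
exchanges the full supernatant every 24 h for 72 h, and quantifies the
collected EGF by ELISA. `gelrelease` reproduces this assay in silico and
answers the inverse question: *what fraction of the growth factor must be
heparin-bound to explain the measured retention?*

## The model

Free EGF diffuses in water with the Polson diffusivity

&nbsp;&nbsp;&nbsp;&nbsp;D_EW = 9.40×10⁻¹⁵ · T / (μ · M^⅓)   [m² s⁻¹, T in K, μ in Pa s, M in g mol⁻¹]

Binding to immobile heparin sites is a fast local equilibrium with bound
fraction f_b, so transport of the total concentration in the gel uses the
retarded diffusivity

&nbsp;&nbsp;&nbsp;&nbsp;D_EH = (1 − f_b) · D_EW + f_b · D_H,&nbsp;&nbsp; D_H = 0 (crosslinked matrix),

equivalent to D_EW / (1 + K) with K = f_b/(1 − f_b). The well is a 1-D
two-layer axial domain (gel slab below, supernatant above, both sealed at the
outer faces) solved by an implicit finite-volume scheme on the free aqueous
concentration, which is continuous across the gel–media interface; the gel's
porosity ε (0.69) enters as accessible-water fraction, giving the gel a
partition capacity ε(1 + K) relative to the media. At each exchange the media
mass is logged as that interval's release and reset to zero. Inversely, f_b
is identified by least squares on the per-interval ELISA masses, and a
bisection finds the minimum f_b consistent with a retention target.

## Worked example

```python
import gelrelease as gr

setup = gr.reference_configuration()          # packaged 12-well assay
curve = gr.run_release_experiment(
    setup.params, setup.geometry, setup.protocol, setup.solver)
print(round(gr.retention_at(curve, 72 * 3600), 2))       # 98.11
print(round(curve.cumulative_released_percent[-1], 2))    # 1.89
print([round(m, 3) for m in curve.interval_released_ng])  # [0.489, 0.47, 0.457]

f_star = gr.min_binding_for_retention(
    96.73, setup.params, setup.geometry, setup.protocol, setup.solver)
print(round(100 * f_star, 2))                             # 99.11
```

At the reference binding fraction f_b = 0.995, 1.89% of the 75 ng load leaves
the gel over three days (≈0.49, 0.47, 0.46 ng in the three collected
supernatants) and 98.11% is retained — strong sequestration with under-5%
cumulative release. The last number is the smallest binding fraction
(99.11%) whose simulated 72 h retention reaches the ELISA-measured 96.73%.

The same pipeline is scriptable from a shell:

```bash
gelrelease simulate --out out/            # curve CSV + summary JSON (+ --plot)
gelrelease fit --observed elisa.csv --out out/
gelrelease recover --true-fb 0.995 --cv 0.05 --n-seeds 20 --out out/
gelrelease reproduce --out out/           # full reference report
```

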