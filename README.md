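# rootstress

Semi-empirical modelling of soybean (*Glycine max*) primary-root elongation
under combined **mechanical** and **hydric** soil stress, for soil
physicists and crop modellers who need a structure-aware root-growth
reduction function.

Roots growing through soil face two coupled physical constraints: the
mechanical impedance of the matrix, measured as penetration resistance
(Qp, MPa), and the water status of the pore space, expressed here as the
degree of water saturation (S, %) — volumetric water content over total
porosity. Both act differently in an intact, no-tillage soil structure
("Field", with continuous biopores) than in sieved, re-packed columns at
set bulk densities ("Packed"). `rootstress` implements the full analysis
chain for quantifying that difference on a very clayey Oxisol:

1. **Soil physical state** — total porosity (saturation-mass or
   particle-density route), volumetric water content θv = w·BD, air-filled
   porosity, saturation degree S = 100·θv/TP, degree of compactness
   DC = 100·BD/BD_Proctor, and elongation rates from primary-root lengths.
2. **Busscher penetration-resistance model** — the power law
   **Qp = a·BD^b·w^c**, fitted per structure by Levenberg–Marquardt
   (damped Gauss–Newton) from a log-linear least-squares start.
3. **3D Gaussian elongation surface** — relative root elongation
   **Re(Qp, S) = a·exp(−½[((S−x₀)/b)² + ((Qp−y₀)/c)²])**, fitted per
   structure by seeded multi-start nonlinear least squares, with
   stress-reduction contrasts and Field/Packed surface comparison grids.
4. **Evaluation** — RMSE, coefficient of residual mass (CRM), Pearson r and
   the Willmott index of agreement d on a stratified 70/30
   fit/validation split.
5. **Synthetic experiments** — a seeded generator emulating the 200-column
   design (110 Field + 90 Packed over five matric potentials, two
   seedlings per column, 87 h growth) with known ground truth, enabling
   closure and parameter-recovery studies in place of the undeposited
   field data.

## Worked example

```python
from rootstress import FIELD_SURFACE, PACKED_SURFACE, relative_elongation, stress_reduction

for s in (60, 90):
    f = relative_elongation(FIELD_SURFACE, 0.3, s)
    p = relative_elongation(PACKED_SURFACE, 0.3, s)
    print(f"S = {s}%: Field {f:.2f}   Packed {p:.2f}")
print(f"Field Qp 1 -> 3.5 MPa at S 60%: {stress_reduction(FIELD_SURFACE, 's', 60, 1.0, 3.5):.0f}% drop")
print(f"Packed Qp 1 -> 3.5 MPa at S 60%: {stress_reduction(PACKED_SURFACE, 's', 60, 1.0, 3.5):.0f}% drop")
```

prints

```
S = 60%: Field 0.74   Packed 0.97
S = 90%: Field 0.43   Packed 0.35
Field Qp 1 -> 3.5 MPa at S 60%: 52% drop
Packed Qp 1 -> 3.5 MPa at S 60%: 74% drop
```

At low resistance and moderate saturation the packed columns elongate
faster (0.97 vs 0.74 of the reference rate), but as either stress rises
the intact structure wins: near saturation its relative elongation is 0.43
against 0.35, and a resistance increase from 1 to 3.5 MPa costs 52% of
elongation in intact soil versus 74% in packed soil — the pore network of
the undisturbed structure buffers both stresses.

The `examples/` directory holds one short narrative script per capability
(physical state, resistance model, elongation surface, synthetic
recovery); each prints its results with a line on what they mean. A thin
CLI mirrors the pipeline stages:

```bash
rootstress simulate --seed 3 --out samples.csv
rootstress fit-busscher --input samples.csv --structure Field --out busscher.json
rootstress run-all --simulate --seed 3 --outdir out/
```

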