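"""Derive soil physical state for a few soil columns.

Builds three sample records spanning loose-wet to compact-dry conditions
and prints the derived porosity, volumetric water content, degree of water
saturation S (the hydric-stress variable) and degree of compactness DC
(bulk density as a percent of the Proctor maximum, 1.53 Mg m^-3 here).
"""

from rootstress import SampleRecord, derive_state

records = [
    SampleRecord("loose-wet", "Packed", bulk_density=1.02, gravimetric_wc=0.44, matric_potential=-10),
    SampleRecord("mid", "Field", bulk_density=1.10, gravimetric_wc=0.35, matric_potential=-100),
    SampleRecord("compact-dry", "Packed", bulk_density=1.26, gravimetric_wc=0.25, matric_potential=-5000),
]

print(f"{'sample':>12} {'TP':>6} {'theta_v':>8} {'air':>6} {'S %':>6} {'DC %':>6}")
for rec in records:
    st = derive_state(rec)
    print(
        f"{st.sample_id:>12} {st.total_porosity:6.3f} {st.theta_v:8.3f} "
        f"{st.air_porosity:6.3f} {st.saturation_pct:6.1f} {st.compactness_pct:6.1f}"
    )
print()
print("S is volumetric water content over total porosity; DC > 80% signals")
print("strong compaction relative to the Proctor maximum bulk density.")
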