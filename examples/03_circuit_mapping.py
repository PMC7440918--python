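"""Analyze a synthetic optogenetic circuit-mapping session.

Simulates a 32x32 photostimulation scan (16 um pitch, 3 trials per spot)
with three light-sensitive presynaptic cells, two of them connected to the
recorded postsynaptic cell.  Computes each source's optical footprint (the
spots firing it in at least 2/3 of trials), the postsynaptic input map
(spots evoking an IPSC in at least 2/3 of trials), and their areas; also
prints the chloride reversal potential implied by the recording solutions,
which makes the IPSCs inward at a -70 mV holding potential.
"""

import vtasst as v

aps, ipsc, truth = v.synth_photostim_session(
    n_sources=3, connection_prob=0.7, seed=4
)
footprints = [v.compute_footprint(g) for g in aps]
input_map = v.compute_input_map(ipsc)

for i, (fp, con) in enumerate(zip(footprints, truth["connected"])):
    tag = "connected" if con else "not connected"
    print(f"source {i}: footprint {fp.n_pixels:3d} px = {fp.area_um2:6.0f} um^2  ({tag})")
print(f"input map: {input_map.n_pixels} px = {input_map.area_um2:.0f} um^2, "
      f"{v.count_clusters(input_map)} discrete cluster(s), "
      f"max IPSC {input_map.max_amplitude_pa:.0f} pA")
summary = v.convergence_summary(footprints, [input_map])
print(f"median footprint {summary['footprint_median_um2']:.0f} um^2 vs "
      f"input field {summary['input_median_um2']:.0f} um^2 "
      f"(ratio {summary['median_ratio']:.1f}: >1 suggests convergent inputs)")

internal = v.solution_chloride([("KCl", 140), ("NaCl", 4), ("CaCl2", 0.5)])
external = v.solution_chloride(
    [("NaCl", 126), ("KCl", 1.6), ("MgCl2", 1.2), ("CaCl2", 2.5)]
)
e_cl = v.nernst_potential(-1, internal, external, temperature_c=24.0)
print(f"chloride: {internal:.0f} mM internal / {external:.0f} mM external "
      f"-> E_Cl = {e_cl:+.1f} mV (IPSCs inward at -70 mV)")
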