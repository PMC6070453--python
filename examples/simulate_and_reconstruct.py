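"""Simulate a SPECT acquisition and reconstruct it with OSEM.

Acquires multi-window projections of the comparison phantom (attenuation,
depth-dependent collimator blur, kernel scatter, Poisson noise), applies
triple-energy-window scatter correction and reconstructs with OSEM, then
compares the in-compartment means against the filled concentrations.
"""

from qspect.intercomparison import (
    make_comparison_phantom,
    reconstruct_protocol,
    site_protocols,
)
from qspect.simulator import acquire

bundle = make_comparison_phantom("H1", spacing=4.8, n_xy=64, n_z=64)
protocol = site_protocols(n_projections=60)["H1"]

print(f"protocol {protocol.name}: {protocol.acquisition.n_projections} "
      f"projections, windows "
      f"{[w.name for w in protocol.acquisition.windows]}, OSEM "
      f"{protocol.recon.iterations}i/{protocol.recon.subsets}s, "
      f"scatter={protocol.recon.scatter_correction}")

projections = acquire(bundle.activity, bundle.density, protocol.acquisition,
                      seed=42)
total = projections.counts["pk208"].sum()
print(f"photopeak counts acquired: {total:.3e}")

recon = reconstruct_protocol(projections, bundle.density, protocol)
inner = bundle.masks["inner"].values.astype(bool)
outer = bundle.masks["outer"].values.astype(bool)
# reconstructed values are cps/voxel; sensitivity 10 cps/MBq converts back
voxel_ml = bundle.activity.voxel_volume_ml
conc_inner = recon.values[inner].mean() / 10.0 / voxel_ml
conc_outer = recon.values[outer].mean() / 10.0 / voxel_ml
print(f"reconstructed concentration, inner: {conc_inner:.2f} MBq/ml "
      f"(filled 2.00)")
print(f"reconstructed concentration, outer: {conc_outer:.3f} MBq/ml "
      f"(filled {2.0 / 15.0:.3f})")
print("-> the inner deficit and outer excess are the partial-volume "
      "spill-out/spill-in this exercise quantifies")
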