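"""End-to-end aquatic eddy covariance processing on a synthetic deployment.

Generates a 3-hour, 8 Hz velocity + O2 record with a known benthic flux of
-5 mmol m-2 h-1 and an O2 build-up worth +0.75 mmol m-2 h-1 of storage,
then runs the full processing chain (quality filter, block averaging,
despiking, double rotation, Reynolds detrending, time-shift correction,
covariance flux) and prints the hourly flux table and diagnostics.
"""

import numpy as np

import streammetab as smb

spec = smb.TurbulenceSpec(true_flux=-5.0, storage_slope=5.0, seed=42)
series, truth = smb.gen_turbulence(spec)
meta = smb.DeploymentMeta(height=0.15, depth=0.40, site="demo", season="summer")

hourly, diag = smb.process_deployment(series, meta)

print("hourly flux table (mmol m-2 h-1):")
cols = ["f_ec_mmol_m2_h", "f_storage_mmol_m2_h", "f_benthic_mmol_m2_h",
        "u_star_m_s", "lag_s"]
print(hourly[cols].round(3).to_string())

print(f"\nimposed turbulent flux : {truth['true_flux_mmol_m2_h']:.2f}")
print(f"recovered EC flux      : {hourly['f_ec_mmol_m2_h'].mean():.2f}"
      "  (mean of hourly covariances)")
print(f"storage term           : {hourly['f_storage_mmol_m2_h'].mean():.2f}"
      "  (O2 accumulating below the sensor)")
print(f"benthic flux           : {hourly['f_benthic_mmol_m2_h'].mean():.2f}"
      "  (EC + storage = true sediment-water exchange)")

print(f"\nfriction velocity u*   : {hourly['u_star_m_s'].mean()*100:.2f} cm/s")
print(f"roughness length z0    : {diag['z0_m']*1000:.2f} mm")
print(f"drag coefficient       : {diag['drag_coefficient']:.4f}")
print(f"90% footprint length   : {diag['footprint_length_m']:.0f} m"
      f" x {diag['footprint_width_m']:.1f} m wide"
      "  (upstream bed area sensed by the instrument)")
print(f"spikes replaced        : {sum(diag['spike_counts'].values())} samples")
print(f"sensor tilt corrected  : yaw {diag['yaw_deg']:.1f} deg,"
      f" pitch {diag['pitch_deg']:.1f} deg")
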