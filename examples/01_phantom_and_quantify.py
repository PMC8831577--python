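"""Generate a synthetic cardiac CT phantom and quantify its epicardial fat.

Builds one noise-free phantom, runs fat-window thresholding inside the
true pericardial-sac mask (after 3 mm median filtering), and compares the
recovered EAT volume with the phantom's analytic truth.
"""

import deepfat as df

phantom = df.generate_phantom(df.PhantomSpec(noise_sd=0.0), seed=1)
result = df.quantify_eat(phantom.ct, phantom.sac)

print(f"analytic EAT volume : {phantom.truth_eat_cm3:.3f} cm^3")
print(f"recovered EAT volume: {result.total_volume_cm3:.3f} cm^3")
print(f"mean fat attenuation: {result.mean_hu:.1f} HU")

# At zero noise the compartment HU values guarantee voxel-exact recovery,
# so the two volumes agree exactly; the mean HU sits near the -100 HU
# fat-tissue mean, well inside the [-190, -30] HU fat window.
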