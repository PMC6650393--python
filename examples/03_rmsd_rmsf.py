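"""Per-lobe RMSD time series and per-residue RMSF on a synthetic ensemble.

The trajectory drifts from a closed toward an open conformation, so the
RMSD from the initial frame grows along the series, and the RMSF profile
concentrates at the termini of the helices the opening path reorients.
"""

import numpy as np

from hvmap import (
    SyntheticLobeSpec,
    SyntheticTrajectorySpec,
    generate_trajectory,
    rmsd_series,
    rmsf_profile,
    synthetic_lobe_def,
)

lobe = synthetic_lobe_def(SyntheticLobeSpec(0.0, 0.0))
selection = [seg for hand in (lobe.hand1, lobe.hand2) for seg in hand.segments()]

ens, _ = generate_trajectory(
    SyntheticTrajectorySpec(30, [(40.0, -15.0), (60.0, 10.0)],
                            angular_noise_sd=0.5, seed=5))

rmsd = rmsd_series(ens, ens.models[0], selection)
print("RMSD from the initial frame (Å):")
print("  first 5:", np.round(rmsd.values[:5], 3))
print("  last 5: ", np.round(rmsd.values[-5:], 3))

rmsf = rmsf_profile(ens, selection)
top = np.argsort(rmsf.values)[-5:][::-1]
print("\nmost mobile residues (RMSF, Å):")
for t in top:
    print(f"  residue {rmsf.residues[t]:>3}: {rmsf.values[t]:.3f}")
print("\nRMSD rises with the opening path; the most mobile residues sit at "
      "the ends of the reorienting helices.")
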