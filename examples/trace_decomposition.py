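"""Decompose one particle's polarization trace into dipole states.

Three frozen dyes share one diffraction-limited spot; their distinct
polarization ratios let the trace be segmented into discrete states, one per
fluorophore, which are then localized individually.
"""

import numpy as np

import spcryolm as sp

rng = np.random.default_rng(3)
gt = sp.GroundTruthParticle(0, "ii", 19.0, (25.0, 0.0, 0.0), (10.0, 50.0, 85.0))
schedule = sp.simulate_blinking(gt, 520, seed=rng)
events = sp.emit_events(gt, schedule, 10.0, seed=rng)

trace = sp.PolarizationTrace.from_events(events)
dec = sp.decompose_trace(trace)
print(f"on-events in trace   : {len(trace)}")
print(f"states found         : {dec.n_states} (true dipoles: 3)")
print(f"state mean p         : {np.round(dec.state_means, 3)}")
print(f"true cos^2(azimuth)  : {np.round(np.cos(np.deg2rad(gt.dipole_azimuths))**2, 3)}")
print(f"trace SNR            : {dec.snr:.1f} (retained if > 3.5)")

particle = sp.localize_particle(trace, dec)
print(f"fluorophore precision: {np.round(particle.precisions, 2)} nm")
print("-> the sorted state means recover the dipoles' Malus-law ratios and each")
print("   state localizes one blade tip with nanometer precision.")
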