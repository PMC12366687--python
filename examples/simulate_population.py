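"""Generate a synthetic trimer population and its localization event stream.

Draws particles from the three conformational classes (9/19/34 nm sides, mixed
21/51/28 %), simulates blinking and polarization-split photon counts, and
prints the population composition and event statistics.  The printed precision
is the per-fluorophore localization precision the event noise implies.
"""

import numpy as np

import spcryolm as sp

ds = sp.simulate_dataset(200, seed=7)
parts = sp.localize_known_fluorophores(ds.events)

print(f"particles simulated : {len(ds.truth)}")
for lab in ("i", "ii", "iii"):
    n = (ds.truth.class_label == lab).sum()
    print(f"  class {lab:<3} : {n:3d}  ({n / len(ds.truth):.0%})")
print(f"localization events : {len(ds.events)}")
print(f"photons per event   : {np.mean(ds.events.counts_ch1 + ds.events.counts_ch2):.1f}")
print(f"median precision    : {np.median([p.mean_precision for p in parts]):.2f} nm")
print("-> class fractions near 21/51/28 % and ~1.4 nm precision reproduce the")
print("   regime the downstream analysis assumes.")
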