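"""Extract the dominant activity-cycle period from a contact sequence.

Generates a strongly periodic colony, bins the contact rate at one minute,
and computes the Morlet wavelet periodogram.  The dominant period lambda and
cycle rate gamma = 1/lambda are the quantities every downstream comparison
(null-model shift window, mu-vs-gamma diagnostics) is anchored to.
"""

import numpy as np

from cyclenet import contact_rate, cycle_rate, make_fixture, wavelet_periodogram

network, truth = make_fixture("periodic_strong", rng=7)
series = contact_rate(network, bin_s=60.0)
pg = wavelet_periodogram(series, period_range_s=(240.0, 7200.0))

print(f"generator period: {truth['stac_period_s']:.0f} s")
print(f"recovered lambda: {pg.lambda_s:.0f} s "
      f"(power fraction {pg.lambda_power:.3f})")
print(f"cycle rate gamma: {cycle_rate(pg.lambda_s):.5f} /s")
print(f"peak-to-median power ratio: "
      f"{pg.lambda_power / np.median(pg.power):.1f}x")
# lambda lands within one scale-grid step of the embedded 960-s cycle, and
# the peak stands far above the median power - an unambiguous rhythm.
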