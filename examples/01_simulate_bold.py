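"""Simulate noiseless BOLD for one attention-left trial.

The ground-truth network couples VC and SPL within each hemisphere;
during the four 10-s attention blocks the aL input drives the right SPL
and strengthens the right VC<->SPL coupling.  The printed numbers are
percent-signal-change peaks per region: the right hemisphere responds,
the left stays silent (no interhemispheric connections, no left drive).
"""

import numpy as np

from rtdcm import HemodynamicParams, simulate_timeseries
from rtdcm.synth import ground_truth_params, make_design

design = make_design("neurofeedback", n_trials=1)
params = ground_truth_params()
series = simulate_timeseries(params, HemodynamicParams(), design)

window = series.values[:90]  # the 90-scan regulation window
print(f"simulated {series.n_scans} scans at TR = {series.TR} s")
for r, label in enumerate(series.region_labels):
    print(f"  {label}: peak {window[:, r].max():+.3f}% "
          f"(sd {window[:, r].std():.3f}%)")
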