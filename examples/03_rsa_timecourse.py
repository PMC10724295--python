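"""Time-resolved RSA for one subject: neural RDMs vs model RDMs.

At each time point (-100..600 ms, 10 ms grid) a 9x9 neural dissimilarity
matrix over the inconsistent characters is correlated (partial Spearman)
with the binary consistency predictors and the log-frequency model.
Consistency effects are injected in the oddball condition only, the
frequency code in both conditions — and that is what the time courses show.
"""

import numpy as np

import oddrsa as od
from oddrsa.preprocess import preprocess_recording
from oddrsa.rsa import default_controls, rsa_timecourse

table = od.make_default_character_table(seed=1)
session = od.generate_session(table, n_trials_oddball=240, n_trials_equal=240,
                              seed=1)
rec = od.simulate_subject(session, table, noise_sd=8.0, seed=2)
ep = preprocess_recording(rec)
models = od.model_rdms(table)

for cond in ("oddball", "equal_probability"):
    stack = od.neural_rdm_timecourse(ep, cond, table)
    t = stack.times_ms
    print(f"\n{cond}: partial Spearman rho, mean in window vs baseline")
    for name in ("orthographic", "phonological", "semantic", "frequency"):
        ctrl = [models[c] for c in default_controls(name)]
        tc = rsa_timecourse(stack, models[name], ctrl, model_name=name)
        lo, hi = (150, 220) if name == "frequency" else (200, 450)
        win = (t >= lo) & (t <= hi)
        base = t < 0
        print(f"  {name:13s} in-window {np.nanmean(tc.partial_rho[win]):+.3f}   "
              f"baseline {np.nanmean(tc.partial_rho[base]):+.3f}")
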