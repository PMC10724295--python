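"""Score the colour-change detection task on a synthetic response log.

A press within 700 ms of the colour change is a hit; any other press is a
false alarm (denominator: non-target trials).
"""

import oddrsa as od
from oddrsa.behavior import score_responses, simulate_response_log

table = od.make_default_character_table(seed=1)
for seq in od.generate_session(table, seed=1):
    log = simulate_response_log(seq, seed=2)
    s = score_responses(log)
    print(f"{seq.block:22s} hit rate {s['hit_rate']:.2%} "
          f"({s['n_targets']} targets) | FA rate {s['false_alarm_rate']:.2%} | "
          f"mean latency {s['mean_latency_ms']:.0f} ms")
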