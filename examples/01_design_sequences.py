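"""Generate a full session design and check every constraint.

A session is one equal-probability block (every character p = 0.25 per
category) followed by three oddball blocks (consistent standards p = 0.75,
one inconsistent category as deviants p = 0.25, never twice in a row).
"""

import oddrsa as od

table = od.make_default_character_table(seed=1)
print(table.frame[["character_id", "category", "radical_set", "frequency"]]
      .to_string(index=False))

session = od.generate_session(table, seed=1)
for seq in session:
    roles = seq.roles
    n_targets = sum(t.is_target for t in seq.trials)
    violations = od.validate_sequence(seq)
    print(f"{seq.block:22s} {len(seq):3d} trials | "
          f"standards {roles.count('standard'):3d} | "
          f"deviants {roles.count('deviant'):3d} | "
          f"targets {n_targets:2d} | violations: {violations}")

# every block satisfies the design: exact role counts, no adjacent deviants,
# and each colour-change target directly follows a non-target (standard) trial
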