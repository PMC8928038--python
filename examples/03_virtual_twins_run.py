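"""One full virtual-twins run on synthetic data with a planted subgroup.

Recovers the planted two-condition rule: a 20% split trains the Step-1
forest, Z = f(1,X) - f(0,X) is computed on the other 80%, and a shallow
regression tree on Z (race excluded) exposes the subgroup; the corrected
proportion tests then validate it on the full table and show the
Simpson-style reversal.
"""

from vtwins import generate_episodes, render_tree, run_virtual_twins, validate_subgroups
from vtwins.synth import recovery_config

cfg = recovery_config(n_episodes=50_000, seed=353809936)
table = generate_episodes(cfg)
print(f"planted rule: service_setting = residential AND homeless = No "
      f"(true inside-Z = +0.06, outside ~ -0.059)\n")

res = run_virtual_twins(table, seed=631865393)
print(render_tree(res.tree, "text"))
print(f"selected most-vulnerable subgroup: {res.selected.describe()}")
print(f"  leaf mean Z = {res.selected.mean_z:+.4f}, "
      f"coverage {100 * res.selected.coverage:.0f}%\n")

rep = validate_subgroups(res.rules, table, alpha=0.05, selected=res.selected)
frame = rep.to_frame()
print(frame[["rule", "p1", "p2", "p_display", "threshold",
             "significant"]].to_string(index=False))
print(f"\nreversal flag: {rep.reversal} -- marginally African American "
      "episodes wait LESS, inside the identified subgroup they wait MORE.")
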