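"""Phase diagram of pathway fate over the control-parameter plane.

Sweeps the forward/backward ratios r1 = k1/k_m1 and r2 = k2/k_m2 on a log
grid at an intermediate backward-rate ratio (rb = 1) and prints an ASCII
rendering: R = repaired (P > 50%), G = trapped intermediate dominates,
B = unrepaired substrate dominates.  Repair needs the second step to beat
its own back-reaction; when it does not, a fast first step makes things
worse by feeding the trap.
"""

from kinetrap import compute_phase_diagram, default_grid

spec = default_grid(rb=1.0, n_points=13)
diagram = compute_phase_diagram(spec)

print("rows: r1 from 1e-2 (top) to 1e2; columns: r2 from 1e-2 to 1e2\n")
for i, r1 in enumerate(spec.r1_values):
    row = "".join(diagram.colors[i, j].value[0] for j in range(len(spec.r2_values)))
    print(f"r1={r1:8.3g}  {row}")

n_red = sum(c.value == "RED" for c in diagram.colors.ravel())
print(f"\n{n_red}/{diagram.colors.size} grid cells are repaired (RED).")
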