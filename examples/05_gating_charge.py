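"""Gating charge of a model transition: a probe charge crossing the membrane.

A +1 e test charge is moved from 10 Å below a 28 Å slab to 10 Å above it.
For each inner-bath voltage in a -50..+50 mV sweep, the charge's interaction
energy with the transmembrane field is computed in both states; the valence
is the (negated) least-squares slope of Delta-G versus V in elementary-charge
units.  A full traversal must give ~1 e — the charge crosses the entire
potential drop.
"""

import memslab as m
from memslab.workflows import WorkflowConfig, gating_charge

state1, state2 = m.build_test_charge_system(z1=-24.0, z2=24.0, q=1.0)
cfg = WorkflowConfig(
    "gating_charge", [state1, state2],
    nodes=65, lengths=(100.0,), eps_protein=2.0,
    membrane=m.MembraneGeometry(z_bottom=-14.0, thickness=28.0),
    V_max_mV=50.0, sweep_points=5,
)
res = gating_charge(cfg)
print(res.sweep.to_string(index=False))
print(f"\nvoltage-sensor valence: {res.valence_e:.3f} e  (full traversal -> ~1)")
print(f"sweep linearity residual: {res.fit_residual_kT:.2e} kT")
print("\nThe small shortfall from exactly 1 e is the fraction of the")
print("potential drop that persists beyond ±24 Å in the electrolyte")
print("(the Debye tails the probe does not traverse).")
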