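"""Temperature-correct a dissociation constant and compute free concentrations.

A laser T-jump perturbs a binding equilibrium by heating the sample a few
degrees in nanoseconds.  To interpret the relaxation that follows, we need
the equilibrium at the *post-jump* temperature: the van 't Hoff relation
moves the calorimetric Kd from the pre-jump 29 degC to 36 degC, and the
mass-action quadratic then gives the free enzyme and ligand concentrations
whose sum sets the relaxation rate of the binding step.
"""

from trelax import BindingParameters, adjust_kd, free_concentrations

params = BindingParameters(kd_ref=4.7, delta_H=-10.0, T_ref=302.15)  # 29 degC
kd_36 = adjust_kd(params, 309.15)                                    # 36 degC
print(f"Kd at 29 degC: {params.kd_ref:.2f} uM")
print(f"Kd at 36 degC: {kd_36:.2f} uM  (binding is exothermic, so heating weakens it)")

for ligand in (25.0, 100.0, 200.0):
    eq = free_concentrations(E_total=100.0, L_total=ligand, Kd=kd_36)
    print(f"  {ligand:5.0f} uM folate: [E]free = {eq.E_free:6.2f}, "
          f"[L]free = {eq.L_free:6.2f}, sum = {eq.sum_free:6.2f} uM")

print("The free-concentration sum is the x-axis of the rate analysis:")
print("k_fast = k_on * ([E]free + [L]free) + k_off")
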