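"""Is the droplet-envelope ("shape") scattering negligible in the window?

Evaluates the polydispersity-smeared intensity of a micron-scale
core/two-shell droplet (oil core, porous hydrogel shell, thin dense coat)
over the instrument window and compares its maximum with a noise floor.
On the synthetic fixtures' intensity scale the envelope is below the 2%
noise level everywhere in-window, which justifies fitting the measured
curve with the internal-structure model alone.  At the droplet
concentration implied by the sample's oil content on the true absolute
scale, however, the envelope is NOT below a realistic noise band near
q_min - the neglect is safe only away from the lowest decade.
"""

from poroshell import UnifiedModel, crossover_prefactor, instrument_grid, \
    shape_term_negligibility, unified_intensity
from poroshell.synthetic import droplet_profile

grid = instrument_grid()
fixture = UnifiedModel.single_level(
    1.0, 150.0, crossover_prefactor(1.0, 150.0, 2.5, grid=grid), 2.5
)
floor = 0.02 * unified_intensity(grid, fixture)[0]
print(f"noise floor (2% of the fixture intensity at q_min): {floor:.3g} cm^-1")

for label, nd in [("fixture scale", 5e-20), ("sample oil content", 2.6e-14)]:
    report = shape_term_negligibility(droplet_profile(number_density=nd),
                                      grid, floor)
    print(f"{label:22s} nd={nd:.1e} A^-3: max {report.max_intensity:.3g} cm^-1 "
          f"at q={report.q_at_max:.4f} -> {report.verdict}")
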