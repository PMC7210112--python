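"""Desk-scale conductance optimization against a self-generated template.

A feature template (spike shape, rate, timing statistics at 10 pA) is
extracted from a reference model, then an elitist genetic algorithm
searches the somatic conductance-density space to match it.  The best
summed feature distance is printed per generation (non-increasing by the
elitism contract).  Fitting only the first 500 ms leaves the slow
adaptation dials underdetermined — the biological point: short protocols
cannot distinguish the subtypes.
"""

from grcsim import GrCModel
from grcsim.population import OptimizationConfig, make_template, optimize_conductances

base = GrCModel.from_config().with_gmax({("Kv1.1", "soma"): 1.2})
truth = {("Cav2.2", "soma"): 0.02, ("KCa1.1", "soma"): 0.6}
template = make_template(base.with_gmax(truth), currents=(10.0,))

cfg = OptimizationConfig(
    population_size=16,
    n_generations=5,
    template=template,
    template_currents=(10.0,),
    genes=(
        ("Nav1.6", "soma"),
        ("Kv3.4", "soma"),
        ("Kv2", "soma"),
        ("Cav2.2", "soma"),
        ("KCa1.1", "soma"),
    ),
    seed=3,
)
pop = optimize_conductances(cfg, base_model=base)

print("best summed feature distance per generation:",
      [round(h, 3) for h in pop.history])
print("best individual (mS/cm^2):")
for (chan, comp), val in pop.best().items():
    print(f"  {chan}@{comp}: {val:.4f}")
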