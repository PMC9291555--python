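"""Fit the fitness surface and extract selection gradients.

Simulates a population, fits the penalized-spline Poisson surface
(trait + environment smooths, trait x environment interaction tensors,
spatial smooth, year covariable), then reports standardized gradients
with parametric-bootstrap standard errors, next to the generator's
ground truth.
"""

import pandas as pd

import ecograd as eg

params = eg.default_params(n_plants=1200, seed=11)
pop = eg.generate_population(params)
truth = eg.true_gradients(params, pop)

spec = eg.SmoothSpec(k_main=5, k_interaction=4, k_spatial=6)
surface = eg.fit_surface(spec, pop)
print(f"deviance explained: {100 * eg.deviance_explained(surface):.1f}% "
      f"(effective df {surface.edf:.1f})")

boot, grads = eg.parametric_bootstrap(surface, pop, n_boot=100, seed=2)
print("\nlinear gradients beta (estimate +/- SE vs truth):")
print(pd.DataFrame({"estimate": grads.beta.round(3),
                    "se": grads.se["beta"].round(3),
                    "p": grads.p["beta"].round(3),
                    "truth": truth.beta.round(3)}))
print("\necological gradients (trait x environment), estimates:")
print(grads.eco.round(3))
print("\nA gradient within ~2 SE of its true value is recovered; the")
print("p-values come from the sign distribution of bootstrap replicates.")
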