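"""Interpolate the response at a drug concentration never seen in training.

Simulates a dose-response screen (Hill-shaped latent shifts over seven
log-spaced concentrations), withholds the second-highest dose, and asks
the dose-conditioned model for the response there. The printed curve is
the predicted mean expression of the strongest true DEGs per dose; the
held-out dose's prediction should fall smoothly between its neighbours.
"""

import perturbcf as pcf

result = pcf.dose_benchmark(seed=1)
print(f"held-out dose: {result['held_dose']:.3g}")
print(f"R^2 on top-50 DEGs at the held-out dose: {result['r2_model']:.3f}")
print(f"control-centroid baseline R^2:           {result['r2_baseline']:.3f}")
for pert, curve in result["curves"].items():
    print(f"\npredicted dose-response of {pert} (mean of top true DEGs):")
    for dose in sorted(curve):
        marker = "  <- held out" if dose == result["held_dose"] else ""
        print(f"  dose {dose:8.3g}: {curve[dose]:.3f}{marker}")
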