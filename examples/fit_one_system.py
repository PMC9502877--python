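"""Fit (k12, B12) for a single system and check parameter recovery.

Generates one noiseless synthetic system at a known ground truth, refits
it from the default initial guess and prints the recovered parameters.
"""

from tracerdiff import ModelParams, fit_params
from tracerdiff.synthetic import GeneratorConfig, _system_stream, gen_system

truth = ModelParams(k12=0.05, b12=1.5)
config = GeneratorConfig(seed=42, points_per_system=(20, 20), noise_cv=0.0)
system, _ = gen_system(config, _system_stream(config, 0), true_params=truth)

fit = fit_params(system)

print(f"true    k12 = {truth.k12:+.6f}   B12 = {truth.b12:.6f}")
print(f"fitted  k12 = {fit.params.k12:+.6f}   B12 = {fit.params.b12:.6f}")
print(f"AARD = {fit.metrics.aard:.2e} %  over {fit.metrics.ndp} points "
      f"({fit.n_evaluations} objective evaluations)")
print()
print("Noiseless data regenerate the exact truth: AARD collapses to ~0 and")
print("both parameters match to far better than experimental resolution.")
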