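"""Fit a whole synthetic database and print the pooled deviation report.

Generates a database with the default four-subset solvent mix and 3%
multiplicative measurement noise, fits every system, and pools the
deviations per subset and globally (sums run over points, not systems).
"""

from tracerdiff import evaluate_database, fit_params
from tracerdiff.synthetic import GeneratorConfig, gen_database

config = GeneratorConfig(seed=1, n_systems=20, points_per_system=(5, 100),
                         noise_cv=0.03)
database = gen_database(config)
systems = [ms for ms, _ in database]
fits = [fit_params(ms) for ms in systems]
report = evaluate_database(systems, fits)

print(report.per_subset.to_string(index=False))
print()
print(f"GLOBAL: AARD = {report.global_metrics.aard:.2f}%  "
      f"ARD = {report.global_metrics.ard:+.2f}%  "
      f"(ndp = {report.ndp}, systems = {report.n_systems}, "
      f"excluded = {report.n_excluded})")
print()
print("With 3% relative noise the pooled AARD settles near the noise floor")
print("E|N(0, 0.03)| = 2.39%, and the signed ARD stays near zero (no bias).")
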