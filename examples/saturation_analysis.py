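"""Build a cross-cell-type master list and extrapolate catalogue saturation.

Generates 50 per-cell-type enhancer catalogues whose discovery follows a
planted Weibull law, merges them into a master list of disjoint
elements (max 5,000 bp), samples the discovery curve over random cell
subsets and fits A(1 - exp(-(x/b)^c)) to estimate the asymptotic
catalogue size.
"""

import numpy as np

from ernatlas import simulate
from ernatlas.catalog import build_master_list, cell_specificity, fit_weibull, saturation_curve

cfg = simulate.SimConfig(seed=7, weibull_A=500.0)
catalogs, truth = simulate.generate_catalog_series(cfg)

ml = build_master_list(catalogs)
spec = cell_specificity(ml)
print(f"master list: {ml.element_count()} elements, "
      f"{ml.coverage_bp() / 1e3:.0f} kb covered")
print(f"mean cell specificity: {spec['n_cell_types'].mean():.1f} of "
      f"{cfg.n_cell_types} cell types")

curve = saturation_curve(catalogs, n_samples=2000, rng=np.random.default_rng(8))
fit = fit_weibull(curve["x"], curve["mean_count"])
print(f"\nWeibull fit: A = {fit.A:.0f} +/- {fit.A_sd:.0f}, "
      f"b = {fit.b:.1f}, c = {fit.c:.2f}, r2 = {fit.r2:.4f}")
print(f"planted asymptote: {truth.weibull_params[0]:.0f}")
print(f"discovered so far: {ml.element_count()} "
      f"({100 * ml.element_count() / fit.A:.0f}% of the predicted total)")

# A is the predicted number of distinct elements if ever more cell
# types were profiled; the discovered fraction says how saturated the
# current catalogue already is.
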