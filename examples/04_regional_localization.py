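"""Localize where planted tissue shifts happen, region by region.

Fits the age direction on a phantom cohort, synthesizes the image a 10-year
increment implies, converts it to a fractional density change map, and
apportions the change over a synthetic atlas.
"""

from tbm3d import PhantomSpec, RunConfig
from tbm3d.localize import change_map, region_fractions
from tbm3d.pipeline import CohortAnalysis
from tbm3d.prep import residualize
from tbm3d.stats import correlated_direction, fit_t_scale

spec = PhantomSpec(
    n_subjects=16, grid_shape=(24, 24, 24), effect_amplitude=1.0,
    noise_amplitude=0.4, seed=23,
)
cfg = RunConfig(phantom=spec, perms=200, seed=2, n_regions=6)
analysis = CohortAnalysis(cfg)

v = residualize(analysis.covariates["age"].to_numpy(float), None)
direction = correlated_direction(analysis.pca, v)
direction.slope_t_per_unit = fit_t_scale(direction.scores, v)

cm = change_map(direction, 10.0, analysis.reference, covariate="age")
table = region_fractions(cm, analysis.atlas, analysis.reference)
print("share of tissue displacement per region for a 10-year age increase:")
for _, row in table.iterrows():
    print(f"  {row['name']}: {row['fraction_pct']:5.1f}%  ({row['n_voxels']} voxels)")
print(f"  total: {table['fraction_pct'].sum():.1f}%")
print()
print("Shares apportion the mass-weighted absolute density change over the")
print("atlas; the planted ring effect concentrates them in shell regions.")
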