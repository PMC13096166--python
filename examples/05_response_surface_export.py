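"""Export a posterior response surface for one precursor combination.

After a campaign, the fitted surrogate predicts activity recovery over a
zinc-concentration x ligand-concentration grid at a fixed salt-ligand
pair, the map a chemist consults before committing reagents.
"""
import numpy as np

from phbo import ObservationSet, fit_mle, make_enzyme_landscape, rsm_grid
from phbo.batching import space_filling_points

landscape = make_enzyme_landscape(seed=7)
space = landscape.space
rng = np.random.default_rng(0)

obs = ObservationSet()
for p in space_filling_points(space, 64, rng.spawn(1)[0]):
    obs.add(p, landscape.evaluate(p, rng=rng).noisy_value)
surrogate = fit_mle(obs, space, rng=rng.spawn(1)[0])

best = max(obs.records, key=lambda r: r.y)
pair = {k: best.point.z[k] for k in ("zinc_salt", "ligand")}
grid = rsm_grid(
    surrogate,
    space,
    fixed_categoricals=pair,
    fixed_continuous={"reaction_time": best.point.x["reaction_time"]},
    grid_axes=("zinc_conc", "ligand_conc"),
    resolution=48,
)
czn, clig = grid.argmax()
print(f"pair {pair['zinc_salt']} + {pair['ligand']}, "
      f"time fixed at {best.point.x['reaction_time']:.0f} min")
print(f"predicted AR peak {100 * grid.mean.max():.1f}% at "
      f"log10 c_zn = {czn:+.2f}, log10 c_lig = {clig:+.2f}")
print(f"posterior sd at the peak cell: {100 * grid.sd.ravel()[np.argmax(grid.mean)]:.1f}%")
df = grid.to_dataframe()
print(f"long-format export: {len(df)} rows with columns {list(df.columns)}")
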