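"""Suggest a parallel batch of experiments with the nearby-liar strategy.

Each suggestion maximizes the expected UCB under probabilistic
reparameterization of the categorical variables; before the next
suggestion, the point is temporarily imputed with the mean objective of
its nearest evaluated neighbors, so the batch spreads instead of
clustering on one optimum.
"""
import numpy as np

from phbo import (
    AcquisitionConfig,
    BatchConfig,
    ObservationSet,
    make_enzyme_landscape,
    suggest_batch,
)
from phbo.batching import space_filling_points

landscape = make_enzyme_landscape(seed=7)
space = landscape.space
rng = np.random.default_rng(0)

# prior screen: 16 space-filling reactions
obs = ObservationSet()
for p in space_filling_points(space, 16, rng.spawn(1)[0]):
    obs.add(p, landscape.evaluate(p, rng=rng).noisy_value)

diag = {}
batch = suggest_batch(
    obs,
    space,
    acq_config=AcquisitionConfig(ucb_beta=9.0, n_restarts=4, maxiter=40),
    batch_config=BatchConfig(q=8, n_nl=3),
    rng=rng.spawn(1)[0],
    diagnostics=diag,
)

print("suggested conditions (one row per parallel reaction):")
for p, liar in zip(batch, diag["liar_values"]):
    print(
        f"  {p.z['zinc_salt']:>7s} + {p.z['ligand']:<6s} "
        f"log10 c_zn={p.x['zinc_conc']:+.2f} log10 c_lig={p.x['ligand_conc']:+.2f} "
        f"t={p.x['reaction_time']:5.0f} min   (liar value used: {liar:.3f})"
    )
print(f"working-set sizes during construction: {diag['working_sizes']}")
# Sizes grow by one per suggestion (the liar records); the caller's
# dataset itself is never modified and contains no liar rows afterwards.
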