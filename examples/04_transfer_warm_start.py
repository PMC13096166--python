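"""Transfer a finished campaign to a new target (e.g. a different enzyme).

The source observations enter the target campaign as warm-up data with
inflated observation noise, and the source GP's fitted prior mean and
hyperparameters seed the target fit.  The first suggested batch is then
already model-informed rather than space-filling.
"""
import numpy as np

from phbo import (
    AcquisitionConfig,
    ObservationSet,
    SurrogateConfig,
    fit_mle,
    make_task_pair,
    prior_from_source,
    run_campaign,
    warm_start_dataset,
)
from phbo.batching import space_filling_points

source, target = make_task_pair(seed=0)
space = source.space
rng = np.random.default_rng(0)

src_obs = ObservationSet()
for p in space_filling_points(space, 48, rng.spawn(1)[0]):
    src_obs.add(p, source.evaluate(p, rng=rng).noisy_value)
src_fit = fit_mle(src_obs, space, SurrogateConfig(n_restarts=4), rng.spawn(1)[0])

acfg = AcquisitionConfig(ucb_beta=9.0, n_restarts=4, maxiter=40)
warm_tr, _ = run_campaign(
    "phbo", target.make_objective(), space, 1, seed=42,
    surrogate_config=SurrogateConfig(n_restarts=4), acq_config=acfg,
    warm_start=warm_start_dataset(src_obs, space),
    prior_init=prior_from_source(src_fit),
)
cold_tr, _ = run_campaign(
    "phbo", target.make_objective(), space, 0, seed=42,
    surrogate_config=SurrogateConfig(n_restarts=4), acq_config=acfg,
)

warm_first = 100 * np.mean(warm_tr.rounds[1].values)
cold_first = 100 * np.mean(cold_tr.rounds[0].values)
print(f"first-batch mean activity recovery, warm-started: {warm_first:.1f}%")
print(f"first-batch mean activity recovery, cold-started: {cold_first:.1f}%")
# Warm-started first batches typically land several-fold higher because the
# transferred data already identifies the productive precursor block.
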