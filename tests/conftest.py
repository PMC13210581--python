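import numpy as np
import pytest

from ensdm import fitcore, occprep, synthgen, varscreen
from ensdm.grid_io import GridSpec, PredictorStack, RasterLayer


@pytest.fixture
def tiny_spec():
    return GridSpec(n_rows=10, n_cols=12, lon_min=100.0, lat_max=30.0, cell_size=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_layer(spec, rng, name="x", n_masked=0):
    values = rng.standard_normal(spec.shape)
    mask = np.zeros(spec.shape, dtype=bool)
    if n_masked:
        idx = rng.choice(spec.n_rows * spec.n_cols, size=n_masked, replace=False)
        mask.flat[idx] = True
        values = values.copy()
    return RasterLayer(spec, values, mask, name)


@pytest.fixture
def small_spec():
    return synthgen.default_spec(60, 60)


@pytest.fixture(scope="session")
def small_pipeline():
    """One cheap end-to-end run shared by cross-module tests (seed 7)."""
    from ensdm import ensemble_eval

    seed = 7
    spec = synthgen.default_spec(60, 60)
    stack = synthgen.default_stack(seed, spec)
    truth = synthgen.true_suitability(synthgen.default_true_model(), stack)
    occ = synthgen.sample_occurrences(truth, 100, seed=seed)
    cleaned, _ = occprep.clean_records(occ, occprep.CleaningRules(domain=(100, 115, 20, 35)))
    final = occprep.validate_on_stack(occprep.thin_records(cleaned, spec), stack)
    sample = varscreen.build_screening_sample(stack, final, 500, seed=seed)
    report = varscreen.screen(sample)
    pa_sets = fitcore.draw_pseudo_absences(
        stack, final, n_per_set=400, n_sets=2, buffer_km=5, seed=seed)
    datasets = {s.set_id: fitcore.assemble_dataset(stack, final, s, report["retained"])
                for s in pa_sets}
    splits = {k: fitcore.make_splits(d.y, 0.75, 3, seed, k) for k, d in datasets.items()}
    learners = fitcore.make_learners(["glm_quad", "ridge_quad", "sre"])
    replicates = fitcore.fit_replicates(learners, list(datasets.values()), splits, seed)
    evals = ensemble_eval.evaluate_replicates(replicates, datasets)
    model = ensemble_eval.build_ensemble(replicates, gate=0.5)
    ens_eval = ensemble_eval.ensemble_apparent_eval(model, datasets)
    smap = ensemble_eval.ensemble_predict(model, stack)
    return dict(seed=seed, spec=spec, stack=stack, truth=truth, occ=final,
                screen=report, datasets=datasets, replicates=replicates,
                evals=evals, model=model, ens_eval=ens_eval, smap=smap)
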