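import pytest

import nirscart.cohort as cohort_mod
import nirscart.outliers as outliers_mod
import nirscart.preprocess as preprocess_mod
from nirscart import CohortConfig, PipelineConfig, TrainConfig


@pytest.fixture(scope="session")
def default_cohort():
    """The default ten-pony study cohort (seed 42)."""
    return cohort_mod.generate_cohort(CohortConfig())


@pytest.fixture(scope="session")
def front_half(default_cohort):
    """Preprocessed matrices, PCA, MVEE and outlier report of the default cohort."""
    ds = default_cohort
    wavelengths, x_vitro = preprocess_mod.preprocess_matrix(ds.in_vitro, ds.grids)
    _, x_vivo = preprocess_mod.preprocess_matrix(ds.in_vivo, ds.grids)
    pca = outliers_mod.fit_pca(x_vitro)
    scores_vitro = outliers_mod.project(pca, x_vitro)
    scores_vivo = outliers_mod.project(pca, x_vivo)
    ellipsoid = outliers_mod.fit_mvee(scores_vitro)
    report = outliers_mod.radius_sweep(
        ellipsoid, scores_vivo, [75, 90, 100, 105, 125, 150], 105
    )
    return dict(
        cohort=ds,
        wavelengths=wavelengths,
        x_vitro=x_vitro,
        x_vivo=x_vivo,
        pca=pca,
        scores_vitro=scores_vitro,
        scores_vivo=scores_vivo,
        ellipsoid=ellipsoid,
        report=report,
    )


@pytest.fixture(scope="session")
def tiny_config():
    """A five-pony, one-line cohort with a two-epoch schedule: fast enough
    for end-to-end plumbing tests while exercising every stage."""
    return PipelineConfig(
        cohort=CohortConfig(
            n_experimental=3,
            n_control=2,
            site_lines=("distal",),
            legs=("L",),
            in_vivo_repeats=5,
            seed=7,
        ),
        train=TrainConfig(max_epochs=2, early_stop_patience=5, lr_patience=3,
                          batch_size=16),
        sweep_radii=(75.0, 100.0, 105.0, 150.0),
        seed=7,
    )
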