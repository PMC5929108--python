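"""Shared fixtures: region sets, templates, and the expensive session-scoped
artifacts (3-node recovery benchmark, full synthetic group pipeline)."""

import numpy as np
import pytest

from netdcm.connectivity import EffectiveConnectivity
from netdcm.forward import FrequencyGrid, estimate_csd
from netdcm.inversion import ParameterSpace, default_priors, invert_spectral_dcm
from netdcm.regions import RegionSet, load_region_fixture
from netdcm.synthetic import make_template_A, simulate_bold


@pytest.fixture(scope="session")
def regions15():
    return load_region_fixture()


@pytest.fixture(scope="session")
def template15(regions15):
    return make_template_A(regions15)


@pytest.fixture(scope="session")
def rs3():
    return RegionSet(("a", "b", "c"), ("X", "X", "X"))


@pytest.fixture(scope="session")
def truth3(rs3):
    A = np.array(
        [
            [-0.5, 0.3, 0.0],
            [-0.2, -0.5, 0.15],
            [0.05, -0.3, -0.5],
        ]
    )
    return EffectiveConnectivity(A, rs3)


def invert_benchmark(truth, T, seed=7, order=8, n_bins=64):
    """Simulate -> estimate CSD -> invert, returning (posterior, space, csd, priors)."""
    ts = simulate_bold(truth, T=T, dt=2.0, seed=seed)
    grid = FrequencyGrid.default(T=170, dt=2.0, n_bins=n_bins)
    csd = estimate_csd(ts, grid, order=order)
    space = ParameterSpace(truth.regions)
    priors = default_priors(truth.regions, space=space)
    post = invert_spectral_dcm(csd, priors)
    return post, space, csd, priors


@pytest.fixture(scope="session")
def recovery3(truth3):
    """The fixed-seed 3-node benchmark with long data."""
    post, space, csd, priors = invert_benchmark(truth3, T=2048, seed=7)
    return {"truth": truth3, "post": post, "space": space, "csd": csd, "priors": priors}


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """Full synthetic group analysis: N = 20 subjects from the default template."""
    from netdcm.pipeline import PipelineConfig, run_pipeline

    out = tmp_path_factory.mktemp("pipeline") / "run"
    cfg = PipelineConfig.from_dict({"cohort": {"n_subjects": 20, "seed": 2027}})
    manifest = run_pipeline(cfg, out)
    import json

    with open(out / "report.json") as fh:
        report = json.load(fh)
    return {"config": cfg, "out": out, "manifest": manifest, "report": report}
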