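import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from aavtropism.simulate import ImageSimConfig


@pytest.fixture(scope="session")
def small_image_config():
    """A fast, low-density image: 40 well-separated nuclei in 256 px."""
    return ImageSimConfig(width_px=256, height_px=256, n_nuclei=40,
                          transduction_fraction=0.5,
                          hotspot_sigma_um=math.inf, seed=11)


@pytest.fixture(scope="session")
def small_image(small_image_config):
    from aavtropism.simulate import simulate_image

    return simulate_image(small_image_config)


@pytest.fixture(scope="session")
def small_pipeline(small_image_config):
    """Simulated image + control carried through segmentation/measurement."""
    from aavtropism.nuclei import measure_nuclei, segment_nuclei
    from aavtropism.simulate import simulate_control_image, simulate_image

    img, truth = simulate_image(small_image_config)
    ctrl, ctruth = simulate_control_image(small_image_config)
    table = measure_nuclei(img, segment_nuclei(img))
    ctrl_table = measure_nuclei(ctrl, segment_nuclei(ctrl))
    return {"image": img, "truth": truth, "table": table,
            "control": ctrl, "control_truth": ctruth, "control_table": ctrl_table}


def make_nucleus_table(mean_gfp, mean_a=None, mean_b=None, image_id="img"):
    """Hand-build a minimal NucleusTable from per-nucleus channel means."""
    n = len(mean_gfp)
    return pd.DataFrame({
        "nucleus_id": np.arange(1, n + 1),
        "row": np.linspace(5, 50, n),
        "col": np.linspace(5, 50, n),
        "area_px": np.full(n, 25),
        "mean_dapi": np.full(n, 100.0),
        "mean_633": np.asarray(mean_a if mean_a is not None else np.zeros(n), dtype=float),
        "mean_488": np.asarray(mean_gfp, dtype=float),
        "mean_546": np.asarray(mean_b if mean_b is not None else np.zeros(n), dtype=float),
        "image_id": image_id,
        "roi_id": "whole_slice",
    })
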