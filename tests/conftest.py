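import numpy as np
import pytest

from tdikin.assays import gal_design, generate_curves, tcache_reference_rates
from tdikin.fitting import fit_curves_from_progress
from tdikin.mechanisms import build_scheme


@pytest.fixture(scope="session")
def tcache_rates():
    return tcache_reference_rates()


@pytest.fixture(scope="session")
def stage1_truth(tcache_rates):
    return {k: tcache_rates[k] for k in ("k1", "k2", "k3", "k4")}


def _coarsen(design, dt):
    from dataclasses import replace

    return replace(design, sample_dt_s=dt)


@pytest.fixture(scope="session")
def product_series_curves(tcache_rates):
    """Noiseless sequential-addition curves, coarsely sampled for speed."""
    design = _coarsen(gal_design("product_series"), 10.0)
    mech = build_scheme("slyke_cullen_product")
    curves = generate_curves(design, mech, tcache_rates)
    return design, curves


@pytest.fixture(scope="session")
def product_series_fit_curves(product_series_curves):
    design, curves = product_series_curves
    return fit_curves_from_progress(curves, design)


@pytest.fixture(scope="session")
def gal_series_curves(tcache_rates):
    design = _coarsen(gal_design("gal_fit_series"), 10.0)
    mech = build_scheme("slyke_cullen_product_inhibitor")
    curves = generate_curves(design, mech, tcache_rates)
    return design, curves


@pytest.fixture(scope="session")
def gal_series_fit_curves(gal_series_curves):
    design, curves = gal_series_curves
    return fit_curves_from_progress(curves, design)
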