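"""Shared fixtures: small phantoms and calibrated phasor pipelines.

Everything is generated programmatically at test time; session scope keeps
the heavier rendered phantoms to one build each.
"""

import numpy as np
import pytest

import adipoflim as af

REF_LIFETIME = 5.4  # ns, known lifetime of the synthetic calibration standard


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def make_uniform_stack(tau, spec=None, **overrides):
    """Noiseless uniform monoexponential stack plus its matching reference."""
    params = dict(image_size=16, irf_fwhm=0.2, seed=1)
    params.update(overrides)
    spec = af.TissuePhantomSpec(lipid_lifetime=tau, **params)
    labels = np.full((spec.image_size, spec.image_size), 2, dtype=np.uint8)
    stack, _, _ = af.render_decay_stack(labels, spec, noise=False)
    ref = af.generate_reference_measurement(REF_LIFETIME, spec, noise=False)
    return stack, ref, spec


def calibrated_field(stack, ref, bin_factor=5, min_photons=10):
    cal = af.ReferenceCalibration.from_stack(ref, REF_LIFETIME)
    return af.calibrate(
        af.phasor_transform(stack, bin_factor=bin_factor, min_photons=min_photons),
        cal,
    )


@pytest.fixture(scope="session")
def bat_phantom():
    """Noisy BAT phantom with full analysis products."""
    return _analyzed_phantom("BAT", seed=5)


@pytest.fixture(scope="session")
def scwat_phantom():
    return _analyzed_phantom("scWAT", seed=5)


def _analyzed_phantom(tissue, seed):
    spec = af.tissue_spec(tissue, seed=seed)
    labels = af.generate_phantom_geometry(spec)
    stack, fad_img, truth = af.render_decay_stack(labels, spec, noise=True)
    ref = af.generate_reference_measurement(REF_LIFETIME, spec, noise=False)
    field = calibrated_field(stack, ref)
    llif_map = af.llif(field, spec.tau_short, spec.tau_long)
    nadh = af.normalize_by_power_squared(af.integrate_decay(stack), 1.0)
    fad = af.normalize_by_power_squared(fad_img, 1.0)
    return dict(
        spec=spec, labels=labels, stack=stack, truth=truth, field=field,
        llif_map=llif_map, nadh=nadh, fad=fad,
    )
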