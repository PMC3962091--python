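import pytest

from memflux import builtin_catalog, load_membrane, reference_highflux_deff


@pytest.fixture(scope="session")
def catalog():
    return builtin_catalog()


@pytest.fixture(scope="session")
def highflux():
    return load_membrane("highflux_fiber")


@pytest.fixture(scope="session")
def nanofab():
    return load_membrane("nanofab_1um")


@pytest.fixture(scope="session")
def highflux_deff():
    """Measured high-flux effective diffusivities, cm^2/s (bundled inputs)."""
    return reference_highflux_deff()


@pytest.fixture(scope="session")
def nanofab_deff_published():
    """Published nanofabricated-membrane effective diffusivities, cm^2/s."""
    return {"Endothelin": 13.87e-7, "Cystatin C": 5.73e-7,
            "Interleukin-6": 3.45e-7}
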