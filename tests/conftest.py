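"""Shared fixtures: published rate constants and standard assay layouts."""

import pytest

from preqfit import AssayConditions, BindingParameters

# Published (k_on [M^-1 s^-1], k_off [s^-1], K_i [nM]) for the plasma
# kallikrein bicyclic peptide inhibitor panel.
TABLE2 = {
    "1b": (3.86e5, 7.0e-4, 1.8),
    "2b": (5.7e6, 5.82e-4, 0.10),
    "2c": (2.40e6, 8.2e-4, 0.34),
    "2d": (1.37e6, 2.99e-4, 0.22),
    "4b": (1.06e7, 1.49e-3, 0.14),
    "5a": (2.28e6, 7.88e-4, 0.36),
    "5b": (2.62e6, 1.38e-3, 0.53),
    "5c": (3.5e6, 1.92e-4, 0.061),
    "5d": (8.0e5, 4.39e-4, 0.55),
}

# [EI]_t for peptide 2d at E_0 = I_0 = 2 nM, t = 900 s, frozen from direct
# Radau integration of the binding ODE at rtol 1e-12 (independent oracle).
EI_2D_2NM_900S = 1.2917469197822854e-09


@pytest.fixture
def peptide_2d() -> BindingParameters:
    k_on, k_off, _ = TABLE2["2d"]
    return BindingParameters(k_on=k_on, k_off=k_off)


@pytest.fixture
def peptide_5c() -> BindingParameters:
    k_on, k_off, _ = TABLE2["5c"]
    return BindingParameters(k_on=k_on, k_off=k_off)


@pytest.fixture
def standard_conditions() -> AssayConditions:
    """1 nM enzyme with the default pre-equilibrium incubation schedule."""
    return AssayConditions(E_0=1e-9, timepoints=(300.0, 900.0, 2700.0, 7200.0))
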