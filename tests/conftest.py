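import numpy as np
import pytest

import halokin as hk


@pytest.fixture(scope="session")
def scheme_3cl() -> hk.KineticScheme:
    """Sequential scheme at the published resorcinol-chlorination constants."""
    return hk.reference.reference_scheme("3", "Cl")


@pytest.fixture(scope="session")
def scheme_16cl() -> hk.KineticScheme:
    """Branched scheme at the published 3-aminophenol-chlorination constants."""
    return hk.reference.reference_scheme("16", "Cl")


@pytest.fixture(scope="session")
def small_scheme() -> hk.KineticScheme:
    """Non-stiff scheme for comparison against a fixed-step integrator."""
    return hk.scheme_from_macroscopic(
        "sequential",
        {
            "1": hk.MacroscopicParameters(2.0, 10.0),
            "2": hk.MacroscopicParameters(0.5, 5.0),
        },
        ka_fixed=1.0,
    )


def rk4_integrate(scheme: hk.KineticScheme, y0, t_end: float, dt: float) -> np.ndarray:
    """Independent fixed-step 4th-order Runge–Kutta oracle.

    Deliberately re-derives mass-action rates from the reaction list
    rather than calling the package's vectorized right-hand side.
    """
    names = list(scheme.species_names)

    def rhs(y):
        dy = np.zeros_like(y)
        for rxn in scheme.reactions:
            rate = scheme.rate_constants[rxn.rate_label]
            for r in rxn.reactants:
                rate *= y[names.index(r)]
            for r in rxn.reactants:
                dy[names.index(r)] -= rate
            for p in rxn.products:
                dy[names.index(p)] += rate
        return dy

    y = np.asarray(y0, dtype=float).copy()
    n = int(round(t_end / dt))
    for _ in range(n):
        k1 = rhs(y)
        k2 = rhs(y + 0.5 * dt * k1)
        k3 = rhs(y + 0.5 * dt * k2)
        k4 = rhs(y + dt * k3)
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return y
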