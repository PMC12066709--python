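import numpy as np
import pytest

import sanddbl


@pytest.fixture(scope="session")
def simple_calibration():
    """Stern-Volmer curve with known parameters for forward/inverse tests."""
    return sanddbl.CalibrationCurve("simple", R0=2.0, K_sv=0.02)


@pytest.fixture(scope="session")
def default_ensemble():
    """Reduced single-grain ensemble spanning the studied (U, C0) ranges.

    Pore-water velocities 0-500 µm s^-1 and O2 1-100 µmol L^-1, solved once
    per session at the default grid and shared by the transport property
    tests and the acceptance checks.
    """
    cfg = sanddbl.GrainModelConfig()
    df = sanddbl.run_ensemble(
        cfg, np.array([0.0, 50.0, 150.0, 300.0, 500.0]),
        np.array([1.0, 10.0, 50.0, 100.0]),
    )
    assert df.converged.all()
    return df


@pytest.fixture(scope="session")
def scaling_ensemble():
    """Advective-regime ensemble for Sand_DBL power-law fitting.

    Velocities 50-500 µm s^-1 with a finer O2 grid: the Sherwood correlation
    behind the DBL thickness is an advective mass-transfer law, so the
    stagnant runs are excluded from scaling-law calibration.
    """
    cfg = sanddbl.GrainModelConfig()
    df = sanddbl.run_ensemble(
        cfg, np.array([50.0, 150.0, 300.0, 500.0]),
        np.array([5.0, 10.0, 20.0, 40.0, 70.0, 100.0]),
    )
    assert df.converged.all()
    return df


@pytest.fixture(scope="session")
def anoxic_solution():
    """One converged strongly-anoxic run (low O2, slow flow) plus its summary."""
    cfg = sanddbl.GrainModelConfig(inflow_velocity_um_s=10.0, inflow_o2_umol_L=2.0)
    sol = sanddbl.solve_solutes(cfg)
    return cfg, sol, sanddbl.summarize(cfg, sol)
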