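import numpy as np
import pytest

from silkdyn.fitting import Observation
from silkdyn.models import MODELS, integrate
from silkdyn.protocols import InfusionProtocol
from silkdyn.synthetic import ARCHETYPES, DEFAULT_TIMES, SyntheticDesign


@pytest.fixture(scope="session")
def protocol():
    return InfusionProtocol()


@pytest.fixture(scope="session")
def obs_times():
    return DEFAULT_TIMES.copy()


def make_observation(rates_or_curve, protocol, times, fluid="plasma",
                     shift=0.0, n_leu=1, i0=None, noise_sd=0.0, rng=None,
                     protein_id="P1", peptide="ELVDK", fraction="F1",
                     charge=2, zero_at_t0=True):
    """Observation whose adjusted RIA equals a model curve (+shift +noise)."""
    protocol = protocol or InfusionProtocol()
    times = np.asarray(times, float)
    if isinstance(rates_or_curve, np.ndarray):
        r = rates_or_curve
    else:
        traj = integrate("single", list(rates_or_curve), protocol, times,
                         method="expm")
        r = traj.r_plasma
    if zero_at_t0:
        r = np.where(times == 0.0, 0.0, r)
    target = r + shift
    if noise_sd:
        target = target + (rng or np.random.default_rng(0)).normal(
            0.0, noise_sd, len(times))
    if i0 is None:
        i0 = np.full(len(times), 1e5)
    rho = np.clip(np.asarray(target) * n_leu, 0.0, 0.9)
    i6 = rho * np.asarray(i0, float) / (1.0 - rho)
    return Observation(protein_id=protein_id, peptide_seq=peptide,
                       fraction=fraction, charge=charge, fluid=fluid,
                       n_leu=n_leu, times=times, i0=np.asarray(i0, float),
                       i6=i6)


@pytest.fixture
def clean_single_obs(protocol, obs_times):
    return make_observation((0.01, 0.15), protocol, obs_times, shift=0.002)


@pytest.fixture(scope="session")
def simplified_spec():
    return MODELS["three_bc_simplified"]


@pytest.fixture(scope="session")
def faster_csf_rates(simplified_spec):
    return np.array([ARCHETYPES["faster_csf"][k]
                     for k in simplified_spec.rate_names])


@pytest.fixture(scope="session")
def quiet_design():
    """Low-contamination design for tests that isolate one mechanism."""
    return SyntheticDesign(outlier_rate=0.0, missing_rate=0.0)
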