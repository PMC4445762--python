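import pytest

from gliomapi import Kinetics, SolverSettings, front_profile, simulate


@pytest.fixture(scope="session")
def kin_mid():
    """A mid-range virtual patient: v = 2*sqrt(15*8) ~ 21.9 mm/yr."""
    return Kinetics(D=15.0, rho=8.0, K=1e5)


@pytest.fixture(scope="session")
def kin_fast():
    """Fast-growing patient used for wave-speed checks: v = 40 mm/yr."""
    return Kinetics(D=25.0, rho=16.0, K=1e5)


@pytest.fixture(scope="session")
def settings_mid(kin_mid):
    return SolverSettings.auto(kin_mid, r_max=60.0)


@pytest.fixture(scope="session")
def developed_lesion(kin_mid, settings_mid):
    """A 15 mm T1Gd lesion with the traveling-wave profile."""
    return front_profile(kin_mid, settings_mid, 15.0, 0.8)


def synthesize_noiseless(kin, detect=15.0, scans=(0, 60, 120, 180), settle=120.0):
    """Noise-free serial two-modality radii from a simulated patient."""
    from gliomapi import RadiusObservation, extract_radius

    v_day = kin.velocity / 365.25
    r_max = detect + v_day * (settle + scans[-1]) + 14 * kin.gradient_length + 10
    st = SolverSettings.auto(kin, r_max=r_max)
    f0 = front_profile(kin, st, detect, 0.8)
    snaps = simulate(kin, f0, settle + scans[-1], st,
                     snapshot_times=[settle + s for s in scans])
    obs = []
    for s, f in zip(scans, snaps):
        obs.append(RadiusObservation(s, "T1Gd", extract_radius(f, 0.80)))
        obs.append(RadiusObservation(s, "T2", extract_radius(f, 0.16)))
    return obs
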