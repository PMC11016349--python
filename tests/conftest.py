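import pytest

from sgrt_dynqa import SimulationConfig, build_motion_plan, simulate_session


@pytest.fixture(scope="session")
def default_plan():
    return build_motion_plan()


@pytest.fixture(scope="session")
def zero_noise_session(default_plan):
    """Full default session: no sensor noise, no latency, with MV images."""
    cfg = SimulationConfig(seed=11, surf_noise_mm=0.0, surf_noise_deg=0.0,
                           surf_latency_s=0.0)
    traj, surf, images, truth = simulate_session(default_plan, cfg)
    return {"plan": default_plan, "config": cfg, "traj": traj, "surf": surf,
            "images": images, "truth": truth}


@pytest.fixture(scope="session")
def noisy_session(default_plan):
    """Default noise (0.05 mm / 0.05 deg), 0.20 s surface latency, no images."""
    cfg = SimulationConfig(seed=12, surf_latency_s=0.20, render_images=False)
    traj, surf, images, truth = simulate_session(default_plan, cfg)
    return {"plan": default_plan, "config": cfg, "traj": traj, "surf": surf,
            "images": images, "truth": truth}
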