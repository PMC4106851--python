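import numpy as np
import pytest

from vtemaze import (ControllerParams, HebbianController, Maze, MazeConfig,
                     RobotPose)


@pytest.fixture(scope="session")
def cfg() -> MazeConfig:
    """Default full-size maze."""
    return MazeConfig()


@pytest.fixture(scope="session")
def maze(cfg) -> Maze:
    return Maze(cfg)


@pytest.fixture(scope="session")
def small_cfg() -> MazeConfig:
    """Scaled-down maze with a short step budget, for protocol-heavy tests."""
    return MazeConfig(central_arm_length=60.0, central_arm_width=30.0,
                      cross_arm_length=60.0, cross_arm_width=30.0,
                      timeout_steps=600)


def make_controller(eta=0.2, zeta=0.02, delta=10, topology="full", **kw):
    params = ControllerParams.uniform(eta=eta, zeta=zeta, delta=delta,
                                      v_forward=kw.pop("v_forward", 2.0), **kw)
    return HebbianController(params, topology=topology)


@pytest.fixture()
def controller() -> HebbianController:
    return make_controller()


def random_valid_poses(cfg: MazeConfig, n: int, seed: int, body_r: float = 0.0):
    """Rejection-sample n poses whose body disc fits in the free space."""
    rng = np.random.default_rng(seed)
    poses = []
    while len(poses) < n:
        x = rng.uniform(-cfg.x_extent, cfg.x_extent)
        y = rng.uniform(cfg.y_bottom, cfg.y_top)
        h = rng.uniform(-np.pi, np.pi)
        if cfg.contains_disc(x, y, body_r):
            poses.append(RobotPose(x, y, h))
    return poses
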