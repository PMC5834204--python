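"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from skittles.config import TaskConfig


@pytest.fixture(scope="session")
def default_config() -> TaskConfig:
    """A generic task: central post, target up and to the right."""
    return TaskConfig(target_center=(25.0, 80.0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# brute-force scoring oracle, written from scratch against the closed form
# x(t) = exp(-t/tau) * (x0 cos(w t) + (vx0 + x0/tau)/w * sin(w t)) per axis


def oracle_launch(angle_deg: float, vel_deg_s: float, config: TaskConfig):
    th = math.radians(angle_deg)
    thd = math.radians(vel_deg_s)
    L = config.lever_length
    px, py = config.lever_pivot
    x0 = px + L * math.cos(th)
    y0 = py + L * math.sin(th)
    vx0 = -L * thd * math.sin(th)
    vy0 = L * thd * math.cos(th)
    return x0, y0, vx0, vy0


def oracle_positions(x0, y0, vx0, vy0, t, config: TaskConfig):
    w, tau = config.omega, config.tau
    env = np.exp(-t / tau)
    kx = (vx0 + x0 / tau) / w
    ky = (vy0 + y0 / tau) / w
    x = env * (x0 * np.cos(w * t) + kx * np.sin(w * t))
    y = env * (y0 * np.cos(w * t) + ky * np.sin(w * t))
    return x, y


def oracle_score(angle_deg: float, vel_deg_s: float, config: TaskConfig, dt: float = 1e-5):
    """Dense-sampling minimum-distance oracle at 0.01 ms resolution.

    The flight is truncated at the post-contact time, located by bisection
    on the closed form between the bracketing dense samples; the distance at
    the contact time itself is included.
    """
    x0, y0, vx0, vy0 = oracle_launch(angle_deg, vel_deg_s, config)
    T = 2.0 * math.pi / config.omega
    t = np.arange(0.0, T + dt / 2.0, dt)
    x, y = oracle_positions(x0, y0, vx0, vy0, t, config)
    post_hit = False
    t_end = None
    if config.post_radius > 0:
        pxc, pyc = config.post_center
        r2 = (config.post_radius + config.ball_radius) ** 2
        inside = (x - pxc) ** 2 + (y - pyc) ** 2 < r2
        if inside.any():
            post_hit = True
            i = int(np.argmax(inside))
            if i == 0:
                t_end = 0.0
            else:
                a, b = t[i - 1], t[i]
                for _ in range(60):
                    m = 0.5 * (a + b)
                    xm, ym = oracle_positions(x0, y0, vx0, vy0, np.array([m]), config)
                    if (xm[0] - pxc) ** 2 + (ym[0] - pyc) ** 2 < r2:
                        b = m
                    else:
                        a = m
                t_end = 0.5 * (a + b)
            keep = t <= t_end
            x, y, t = x[keep], y[keep], t[keep]
            if t_end > 0:
                xe, ye = oracle_positions(x0, y0, vx0, vy0, np.array([t_end]), config)
                x = np.append(x, xe)
                y = np.append(y, ye)
    txc, tyc = config.target_center
    d = np.hypot(x - txc, y - tyc)
    if d.size == 0:
        xe, ye = oracle_positions(x0, y0, vx0, vy0, np.array([0.0]), config)
        d = np.hypot(xe - txc, ye - tyc)
    return float(d.min()), post_hit


def ols_slope(y: np.ndarray, x: np.ndarray) -> float:
    """Closed-form ordinary-least-squares slope, used as the estimator oracle."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    return float(np.sum(xc * y) / np.sum(xc * xc))
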