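import numpy as np
import pytest

from fqspec import ForceFieldVariant, GeneratorConfig, generate_snapshots, water_topology


def tip3p_water(origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """One rigid water (O, H, H) in Angstrom, O at *origin*."""
    ang = np.deg2rad(104.52)
    o = np.asarray(origin, dtype=float)
    h1 = o + 0.9572 * np.array([np.cos(ang / 2), np.sin(ang / 2), 0.0])
    h2 = o + 0.9572 * np.array([np.cos(ang / 2), -np.sin(ang / 2), 0.0])
    return np.array([o, h1, h2])


@pytest.fixture
def one_water():
    return tip3p_water()[None, :, :]


@pytest.fixture
def two_waters():
    return np.array([tip3p_water(), tip3p_water((4.0, 0.5, -0.3))])


@pytest.fixture
def small_droplet():
    """A 7 A droplet ensemble shared across solver-level tests."""
    cfg = GeneratorConfig(n_snapshots=3, droplet_radius=7.0, seed=11)
    return cfg, generate_snapshots(cfg)


def random_water_cluster(rng: np.random.Generator, n_mol: int) -> np.ndarray:
    """Well-separated random waters for oracle comparisons."""
    waters = []
    centers: list[np.ndarray] = []
    while len(waters) < n_mol:
        c = rng.uniform(-5.0, 5.0, 3)
        if any(np.linalg.norm(c - p) < 2.8 for p in centers):
            continue
        w = tip3p_water(c)
        rot = np.linalg.qr(rng.standard_normal((3, 3)))[0]
        waters.append(c + (w - c) @ rot.T)
        centers.append(c)
    return np.array(waters)


def topology_for(coords, variant: ForceFieldVariant):
    return water_topology(coords, "toy", variant)
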