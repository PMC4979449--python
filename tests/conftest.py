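import itertools

import numpy as np
import pytest

import conemosaic as cm


def render_blob(
    shape: tuple[int, int],
    center: tuple[float, float],
    sigma: float,
    amplitude: float = 100.0,
    background: float = 0.0,
) -> np.ndarray:
    """Analytic isotropic Gaussian blob; (x, y) center, pixel-center coords."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    x0, y0 = center
    return background + amplitude * np.exp(
        -((yy - y0) ** 2 + (xx - x0) ** 2) / (2.0 * sigma * sigma)
    )


def blob_mosaic(shape, centers_sigmas, amplitude=100.0, background=0.0,
                pixel_scale_um=0.85) -> cm.MosaicImage:
    img = np.full(shape, float(background))
    for (x0, y0), s in centers_sigmas:
        img += render_blob(shape, (x0, y0), s, amplitude)
    return cm.MosaicImage(pixels=img, pixel_scale_um=pixel_scale_um)


# --- independent statistics oracle -----------------------------------------


def permutation_p(
    a: np.ndarray,
    b: np.ndarray,
    statistic: str = "welch",
    n_draws: int | None = 4000,
    rng: np.random.Generator | None = None,
) -> float:
    """Two-sided permutation p-value for the difference of two groups.

    Exchanges group labels and compares |t| of each relabeling against the
    observed |t|.  ``n_draws=None`` enumerates all label assignments
    (feasible only for tiny samples); otherwise draws random relabelings.
    Independent of the package's own test code by construction.
    """

    def t_stat(x, y):
        if statistic == "welch":
            return (x.mean() - y.mean()) / np.sqrt(
                x.var(ddof=1) / len(x) + y.var(ddof=1) / len(y)
            )
        sp2 = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / (
            len(x) + len(y) - 2
        )
        return (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / len(x) + 1 / len(y)))

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pool = np.concatenate([a, b])
    na = len(a)
    t_obs = abs(t_stat(a, b))
    if n_draws is None:
        hits = total = 0
        for comb in itertools.combinations(range(len(pool)), na):
            mask = np.zeros(len(pool), bool)
            mask[list(comb)] = True
            if abs(t_stat(pool[mask], pool[~mask])) >= t_obs - 1e-12:
                hits += 1
            total += 1
        return hits / total
    rng = rng or np.random.default_rng(0)
    hits = 0
    for _ in range(n_draws):
        perm = rng.permutation(len(pool))
        if abs(t_stat(pool[perm[:na]], pool[perm[na:]])) >= t_obs - 1e-12:
            hits += 1
    return hits / n_draws


# --- shared synthetic fixtures (session-scoped: rendering is the slow part)


@pytest.fixture(scope="session")
def rp_mosaic():
    params = cm.rp_profile(seed=42)
    mosaic, truth = cm.generate_mosaic(params)
    return params, mosaic, truth


@pytest.fixture(scope="session")
def rp_measurements(rp_mosaic):
    _, mosaic, truth = rp_mosaic
    cones = cm.detect(mosaic)
    return cm.measure_all(mosaic, cones)


@pytest.fixture(scope="session")
def control_mosaic():
    params = cm.control_profile(seed=7)
    mosaic, truth = cm.generate_mosaic(params)
    return params, mosaic, truth
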