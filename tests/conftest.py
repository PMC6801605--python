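import numpy as np
import pytest

import mabpen as mp


@pytest.fixture(scope="session")
def circular_edge_only():
    """Noiseless circular tumor, edge source only (analytic oracle is exact)."""
    params = mp.SyntheticSectionParams(
        image_shape=(420, 420), pixel_size=0.65, tumor_radius=120.0,
        boundary_roughness=0.0, vessel_amplitude=0.0, n_vessels=0,
        noise_model="none", seed=1)
    section, truth = mp.generate_section(params)
    return params, section, truth


@pytest.fixture(scope="session")
def circular_vessel_only():
    """Noiseless circular tumor, one vessel, vessel source only."""
    params = mp.SyntheticSectionParams(
        image_shape=(420, 420), pixel_size=0.65, tumor_radius=120.0,
        boundary_roughness=0.0, edge_amplitude=0.0, n_vessels=1,
        noise_model="none", seed=2)
    section, truth = mp.generate_section(params)
    return params, section, truth


@pytest.fixture(scope="session")
def default_section():
    """One section at generator defaults (rough boundary, both sources, noise)."""
    params = mp.SyntheticSectionParams(seed=7)
    section, truth = mp.generate_section(params)
    return params, section, truth


@pytest.fixture
def uniform_section():
    """Constant antibody field c = 0.3 inside a clean circular tumor."""
    params = mp.SyntheticSectionParams(
        image_shape=(256, 256), pixel_size=1.3, tumor_radius=120.0,
        boundary_roughness=0.0, edge_amplitude=0.0, vessel_amplitude=0.0,
        n_vessels=2, background=0.3, noise_model="none", seed=3)
    section, truth = mp.generate_section(params)
    return params, section, truth


def truth_geometry(truth):
    """Ground-truth masks/contour, bypassing segmentation: profiling fidelity
    is tested against the generator oracle with exact geometry; segmentation
    accuracy is covered separately by Dice."""
    from mabpen.segmentation import extract_contour
    tumor = mp.Mask(truth.tumor_mask, "tumor")
    vessels = mp.Mask(truth.vessel_mask, "vessel")
    return tumor, extract_contour(truth.tumor_mask), vessels


def brute_force_km(times, events):
    """Independent product-limit estimator over explicit risk sets."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    uniq = np.unique(times[events])
    s = 1.0
    out_t, out_s = [0.0], [1.0]
    for t in uniq:
        at_risk = np.sum(times >= t)  # censored at t still at risk for deaths at t
        deaths = np.sum((times == t) & events)
        s *= 1.0 - deaths / at_risk
        out_t.append(float(t))
        out_s.append(float(s))
    return np.array(out_t), np.array(out_s)


def brute_force_logrank(t_a, e_a, t_b, e_b):
    """Observed-minus-expected log-rank chi-square over explicit risk sets."""
    t_all = np.concatenate([t_a, t_b])
    e_all = np.concatenate([e_a, e_b]).astype(bool)
    grp = np.concatenate([np.zeros(len(t_a)), np.ones(len(t_b))])
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(t_all[e_all]):
        at_risk = t_all >= t
        n = at_risk.sum()
        n_a = (at_risk & (grp == 0)).sum()
        d = (e_all & (t_all == t)).sum()
        d_a = (e_all & (t_all == t) & (grp == 0)).sum()
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return o_minus_e ** 2 / var
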