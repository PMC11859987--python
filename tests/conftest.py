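"""Shared fixtures: seeded RNGs, small soundscapes, and a cached 20-seed
flow-structure sweep used by several tests (it is the expensive part of the
suite, so it runs once per session)."""

import warnings

import numpy as np
import pytest

from soundflow import flow_network as fn
from soundflow import transfer_entropy as te
from soundflow.reporting import _series_by_site
from soundflow.synthetic import SoundscapeSpec, gen_soundscape


@pytest.fixture
def rng():
    return np.random.default_rng(20250101)


@pytest.fixture(scope="session")
def small_soundscape():
    """Three-day duty-cycle soundscape (720 windows/site), default layout."""
    real = gen_soundscape(SoundscapeSpec(seed=7, days=3))
    real.index_matrix.attrs["window_s"] = 360
    return real


@pytest.fixture(scope="session")
def flow_structure_sweep():
    """Per-seed flow summaries on the default soundscape, 20 seeds.

    For each seed: arrow counts of the dawn/day/night networks under a shared
    cross-period 75th-percentile cutoff, group densities of the all-period
    network, and the dawn/night normalized distance indices, all for the H
    index with the Shannon estimator.
    """
    params = te.TEParams()
    rows = []
    for seed in range(20):
        spec = SoundscapeSpec(seed=seed)
        matrix = gen_soundscape(spec).index_matrix
        matrix.attrs["window_s"] = spec.window_s + spec.pause_s
        periods = fn.split_periods(matrix["timestamp"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            te_by_period = {}
            for label in fn.PERIODS:
                series, blocks = _series_by_site(
                    matrix, "H", periods == label
                )
                te_by_period[label] = te.te_matrix(
                    series, params, blocks_by_site=blocks
                )
            # site-diameter normalization for d_n so sparse-period values
            # are comparable (the longest-drawn-arrow reading saturates at 1
            # when a period keeps only one or two arrows)
            nets = fn.period_networks(
                te_by_period, spec.site_map, p=75, d_max_mode="all_pairs"
            )
            series, blocks = _series_by_site(matrix, "H")
            full = te.te_matrix(series, params, blocks_by_site=blocks)
            net_all = fn.build_network(full, spec.site_map, p=75)
        dens = fn.arrow_density(net_all, spec.site_map)
        rows.append(
            {
                "seed": seed,
                "dawn_arrows": nets["dawn"].n_bar,
                "day_arrows": nets["day"].n_bar,
                "night_arrows": nets["night"].n_bar,
                "internal_density": dens["internal"],
                "external_density": dens["external"],
                "dawn_dn": nets["dawn"].d_n,
                "night_dn": nets["night"].d_n,
            }
        )
    return rows
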