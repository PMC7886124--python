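"""Shared fixtures.

The two expensive simulations (the 100-cell tuning-recovery population and
the 5-seed end-to-end clustering benchmark) are session-scoped so the module
tests and the acceptance suite evaluate the same computation once.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from rgctypes import stimuli as st
from rgctypes import synthetic, workflow

E2E_SEEDS = (1, 2, 3, 4, 5)


@pytest.fixture(scope="session")
def archetypes() -> dict[str, synthetic.SyntheticCellSpec]:
    return {a.label: a for a in synthetic.make_archetypes()}


@pytest.fixture(scope="session")
def mixed_population():
    """Small mixed population (all 10 archetypes, default noise), analyzed."""
    config = synthetic.PopulationConfig(cells_per_archetype=3, noise=0.3,
                                        include_bars=False)
    trains, labels = synthetic.generate_population(config, seed=7)
    analyses = workflow.analyze_population(trains)
    return trains, labels, analyses


def _recovery_cellspecs(n_cells: int, rng: np.random.Generator):
    """Cells spanning the 6x4 tuning grid (centers on grid points)."""
    specs = []
    grid = [(p, f) for p in st.GRATING_PERIODS_UM for f in st.GRATING_FREQS_HZ]
    for i in range(n_cells):
        p, f = grid[i % len(grid)]
        pol = ("ON", "OFF", "ON-OFF")[i % 3]
        specs.append(synthetic.SyntheticCellSpec(
            label=f"grid_{i}", polarity=pol, kinetic_tau=0.1,
            tf_center=math.log2(f), tf_sigma=0.8,
            sf_center=math.log2(p), sf_sigma=0.8,
            contrast_c50=0.3, baseline_rate=3.0, max_rate=70.0,
            true_cluster=i))
    return specs


@pytest.fixture(scope="session")
def tuning_recovery():
    """100 noiseless cells on the tuning grid -> injected vs recovered tuning.

    Returns a list of dicts with the injected (period, frequency, polarity)
    and the analyzed profile per cell.
    """
    rng = np.random.default_rng(2024)
    specs = _recovery_cellspecs(100, rng)
    config = synthetic.PopulationConfig(
        cells_per_archetype=1, noise=0.0, include_bars=False,
        include_chirp=False, include_contrast_ramp=False)
    trains, labels = synthetic.generate_population(config, archetypes=specs, seed=2024)
    analyses = workflow.analyze_population(trains)
    out = []
    for spec, a in zip(specs, analyses):
        out.append({
            "sf_um": 2.0 ** spec.sf_center,
            "tf_hz": 2.0 ** spec.tf_center,
            "polarity": spec.polarity,
            "profile": a.profile,
            "map": a.grating_map,
        })
    return out


def archetype_map(spec) -> np.ndarray:
    """Noise-free normalized 6x4 grating map implied by a cell's tuning."""
    sf = np.log2(np.asarray(st.GRATING_PERIODS_UM))
    tf = np.log2(np.asarray(st.GRATING_FREQS_HZ))
    m = (np.exp(-0.5 * ((sf[:, None] - spec.sf_center) / spec.sf_sigma) ** 2)
         * np.exp(-0.5 * ((tf[None, :] - spec.tf_center) / spec.tf_sigma) ** 2))
    return m / m.max()


@pytest.fixture(scope="session")
def separated_maps(archetypes):
    """30 cells per grating-only archetype, map noise sigma = 0.05."""
    rng = np.random.default_rng(99)
    protos = [archetype_map(archetypes[n]) for n in
              ("grating_only_fast_fine", "grating_only_slow_coarse",
               "grating_only_mid_wide")]
    X, truth = [], []
    for label, proto in enumerate(protos):
        for _ in range(30):
            noisy = np.clip(proto + rng.normal(0, 0.05, proto.shape), 0, None)
            X.append(noisy.ravel())
            truth.append(label)
    return np.asarray(X), np.asarray(truth)


@pytest.fixture(scope="session")
def end_to_end():
    """Mixed 8-archetype recovery at default noise across 5 seeds.

    Returns per-seed dicts with the adjusted Rand index between true and
    recovered labels, the chosen k and the step counts.
    """
    arch = [a for a in synthetic.make_archetypes()
            if a.true_cluster in (1, 2, 3, 4, 5, 9, 10, 11)]
    results = []
    for seed in E2E_SEEDS:
        config = synthetic.PopulationConfig(cells_per_archetype=25, noise=0.3,
                                            include_bars=False)
        trains, labels = synthetic.generate_population(config, archetypes=arch,
                                                       seed=seed)
        analyses = workflow.analyze_population(trains)
        result = workflow.cluster_population(analyses, seed=seed)
        truth = [l.true_cluster for l in labels]
        pred = [(-1 if a.cluster is None else a.cluster) for a in result.assignments]
        results.append({
            "seed": seed,
            "ari": adjusted_rand_score(truth, pred),
            "k": None if result.kmeans is None else result.kmeans.k,
            "counts": result.step_counts,
        })
    return results
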