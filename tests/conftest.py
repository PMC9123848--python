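from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/_oracles.py

from rnsfc.config import PipelineConfig
from rnsfc.parcellation import make_parcellation
from rnsfc.pipeline import analyze_cohort, compute_connectivity
from rnsfc.synthetic import CohortDesign, plan_cohort


@pytest.fixture(scope="session")
def parc_small():
    """32 ROIs in 16 modules: the scaled-down cohort parcellation."""
    return make_parcellation(32, 16)


@pytest.fixture(scope="session")
def parc_tiny():
    """8 ROIs in 4 modules (2 per hemisphere)."""
    return make_parcellation(8, 4)


def run_small_cohort(seed, parcellation, design_kwargs=None, **analyze_kwargs):
    """Simulate + analyze one scaled-down cohort, in memory."""
    design = CohortDesign(seed=seed, **(design_kwargs or {}))
    cfg = PipelineConfig(
        n_rois=parcellation.n_rois, n_modules=parcellation.n_modules,
        seed=seed, design=design,
    )
    plan = plan_cohort(design, parcellation)
    conn = compute_connectivity(plan, cfg)
    results = analyze_cohort(
        conn,
        [s.outcome for s in plan.patients],
        [s.subject_id for s in plan.controls],
        parcellation,
        cfg,
        **analyze_kwargs,
    )
    return plan, results


@pytest.fixture(scope="session")
def small_cohort(parc_small):
    """One fully analyzed default-design cohort (22 R / 9 NR / 15 controls)."""
    return run_small_cohort(11, parc_small, n_boot=100)
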