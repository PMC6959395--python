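"""End-to-end convenience layer: simulate -> places -> features -> samples
-> cross-validated classification."""

from __future__ import annotations

import zlib

import numpy as np

from .classify import FAMILIES, cross_validated_report
from .features import MobilityFeatureExtractor
from .samples import build_samples, split_xy, undersample
from .simulate import SimulationConfig, simulate_cohort


def child_seed(seed: int, *keys) -> int:
    """Deterministically fan one top-level seed out to sub-components."""
    tags = [zlib.crc32(repr(k).encode()) for k in keys]
    return int(np.random.SeedSequence([int(seed)] + tags).generate_state(1)[0] % (2**31))


def featurize(locations, **extractor_params):
    """Daily mobility-metric table from a raw location table."""
    return MobilityFeatureExtractor(**extractor_params).fit_transform(locations)


def balanced_samples(daily, symptoms, t_hist: int, t_hor: int, seed: int):
    """Build the (t_hist, t_hor) sample set and balance it 1:1 by random
    under-sampling (balance-before-CV, the pooled-CV reporting mode)."""
    samples = build_samples(daily, symptoms, t_hist, t_hor)
    return undersample(samples, seed=child_seed(seed, "undersample", t_hist, t_hor))


def cohort_cv_reports(
    config: SimulationConfig,
    t_hist: int = 1,
    t_hor: int = 1,
    families=FAMILIES,
    seed: int = 0,
    cv: int = 10,
    daily=None,
    symptoms=None,
):
    """Simulate a cohort (unless ``daily``/``symptoms`` are supplied), build
    balanced samples at (t_hist, t_hor) and return
    ``{family: EvaluationReport}`` from 10-fold out-of-fold predictions."""
    if daily is None or symptoms is None:
        locations, symptoms, _ = simulate_cohort(config)
        daily = featurize(locations)
    samples = balanced_samples(daily, symptoms, t_hist, t_hor, seed)
    X, y = split_xy(samples)
    groups = samples["user_id"].to_numpy()
    return {
        fam: cross_validated_report(
            fam, X, y, cv=cv, seed=child_seed(seed, "cv", fam), groups=groups
        )
        for fam in families
    }
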