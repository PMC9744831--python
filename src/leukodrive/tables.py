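"""Packaged summary statistics of the reference driving cohort.

The package ships the published summary statistics of a cohort of 101
licensed older drivers (mean age 77.9 y) who underwent FLAIR/T1 MRI,
a dynamic-visual-cognition (DVC) test and an instructor-rated on-road
driving-safety-performance (DSP) assessment: per-variable means and
standard deviations, and the 17 x 17 Pearson correlation matrix over

    age, the six location DSP scores (P1..P6), total DSP,
    DVC tracking and sudden-motion scores, brain atrophy, and
    leukoaraiosis volume in five compartments plus the total.

Correlations are printed to two decimals; assembled covariance matrices
therefore carry rounding error, and the full matrix is very slightly
indefinite (total LA correlates 1.00 with periventricular LA).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Number of participants in the reference cohort.
COHORT_N = 101

#: Canonical variable order of the reference correlation matrix.
VARIABLES = [
    "age",
    "dsp_p1", "dsp_p2", "dsp_p3", "dsp_p4", "dsp_p5", "dsp_p6",
    "dsp_total",
    "dvc_tracking", "dvc_sudden",
    "brain_atrophy",
    "la_frontal", "la_temporal", "la_parietal", "la_occipital",
    "la_periventricular", "la_total",
]


def _read(name: str, **kw) -> pd.DataFrame:
    with resources.files("leukodrive.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, **kw)


def cohort_summary() -> pd.DataFrame:
    """Per-variable mean, SD and observed range, indexed by variable name."""
    return _read("cohort_summary.csv", index_col=0)


def cohort_correlations() -> pd.DataFrame:
    """The 17 x 17 reference Pearson correlation matrix (2-dp as published)."""
    r = _read("cohort_correlations.csv", index_col=0)
    assert list(r.index) == VARIABLES
    return r


def cohort_sds() -> pd.Series:
    return cohort_summary()["sd"]


def cohort_means() -> pd.Series:
    return cohort_summary()["mean"]
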