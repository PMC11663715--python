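"""Shared test utilities: tiny table builders and a brute-force cosine oracle."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from conjnet.feature_io import FeatureTable, Sample, Spectrum
from conjnet.spectral_network import CosineParams


def mini_table(features, samples=None, qc=0):
    """Build a FeatureTable from a list of row dicts.

    ``features``: dicts with id, polarity, mz, rt and sample intensities.
    ``samples``: list of Sample objects; derived from the columns if omitted
    (ids starting with "QC" become QC injections).
    """
    df = pd.DataFrame(features)
    if samples is None:
        sample_cols = [c for c in df.columns if c not in ("id", "polarity", "mz", "rt")]
        samples = [
            Sample(id=c, is_qc=c.startswith("QC"), genotype="WT", treatment="mock", weight=5.0)
            if not c.startswith("QC")
            else Sample(id=c, is_qc=True)
            for c in sample_cols
        ]
    return FeatureTable(df, {s.id: s for s in samples})


def random_spectrum(rng, n_peaks=None, feature_id="S", mz_range=(50.0, 500.0)):
    n = int(n_peaks if n_peaks is not None else rng.integers(2, 7))
    peaks = np.column_stack(
        [rng.uniform(*mz_range, n), rng.uniform(1.0, 100.0, n)]
    )
    return Spectrum(
        feature_id=feature_id,
        precursor_mz=float(rng.uniform(100.0, 600.0)),
        peaks=peaks,
    )


def brute_force_cosine(a: Spectrum, b: Spectrum, params: CosineParams) -> float:
    """Exhaustive maximum over all one-to-one candidate-pair matchings."""
    wa = a.intensities ** params.intensity_power
    wa = wa / np.sqrt((wa**2).sum())
    wb = b.intensities ** params.intensity_power
    wb = wb / np.sqrt((wb**2).sum())
    shift = a.precursor_mz - b.precursor_mz
    candidates = []
    for i in range(len(a)):
        for j in range(len(b)):
            d = a.mz[i] - b.mz[j]
            ok = abs(d) <= params.fragment_tolerance
            if params.allow_precursor_shift:
                ok = ok or abs(d - shift) <= params.fragment_tolerance
            if ok:
                candidates.append((i, j, wa[i] * wb[j]))

    best = 0.0
    # enumerate subsets of candidate pairs that form a valid matching
    for size in range(1, min(len(a), len(b), len(candidates)) + 1):
        for combo in itertools.combinations(candidates, size):
            rows = {i for i, _, _ in combo}
            cols = {j for _, j, _ in combo}
            if len(rows) < size or len(cols) < size:
                continue
            best = max(best, sum(w for _, _, w in combo))
    return min(best, 1.0)
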