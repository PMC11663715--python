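"""Differential-accumulation statistics across genotype x treatment groups.

Per-feature one-way ANOVA on (by default) log10-transformed intensities with
a pseudo-count offset, Benjamini-Hochberg adjustment across features, and
log2 fold changes for declared contrasts (e.g. wound/mock) used to size
network nodes.  QC injections are always excluded.

The one-way layout treats each genotype:treatment combination as one group;
a two-way genotype x treatment model with interaction is available through
:func:`anova_two_way` for single features.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .feature_io import FeatureTable, FeatureTableError

__all__ = ["DiffResult", "anova_per_feature", "log2_fold_change", "tukey_posthoc"]


@dataclass
class DiffResult:
    """Per-feature ANOVA outcome plus contrast fold changes."""

    feature_id: str
    group_means: dict[str, float]
    f_stat: float
    pvalue: float
    p_adjusted: float
    log2fc: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return self.p_adjusted < 0.05


def _design_from_metadata(table: FeatureTable) -> dict[str, str]:
    return {s: table.samples[s].group for s in table.biological_sample_ids}


def _group_columns(design: Mapping[str, str]) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    for sample, group in design.items():
        groups.setdefault(group, []).append(sample)
    return groups


def anova_per_feature(
    table: FeatureTable,
    design: Mapping[str, str] | None = None,
    log_transform: bool = True,
    pseudo: float = 1.0,
    contrasts: Sequence[tuple[str, str]] = (),
    adjust: str = "fdr_bh",
) -> list[DiffResult]:
    """One-way ANOVA per feature with multiplicity adjustment.

    ``design`` maps sample id -> group label; by default every non-QC
    sample's genotype:treatment combination.  Intensities are transformed to
    log10(x + pseudo) unless ``log_transform`` is False.  Features whose
    values are identical across all samples carry no information and are
    flagged ``zero_variance`` with p = 1.  ``adjust`` is any statsmodels
    multipletests method (``fdr_bh`` default, ``bonferroni`` available).

    Fold changes for ``contrasts`` (numerator group, denominator group) are
    computed on the raw group means with the same pseudo-count.
    """
    design = dict(design) if design is not None else _design_from_metadata(table)
    qc = set(table.qc_sample_ids)
    if qc & set(design):
        raise FeatureTableError("QC samples cannot appear in the design")
    groups = _group_columns(design)
    if len(groups) < 2:
        raise FeatureTableError("ANOVA needs at least 2 groups")
    for g, cols in groups.items():
        if len(cols) < 2:
            raise FeatureTableError(f"group {g!r} has fewer than 2 replicates")

    raw = {g: table.intensities(cols).to_numpy() for g, cols in groups.items()}
    value = {
        g: np.log10(x + pseudo) if log_transform else x for g, x in raw.items()
    }
    arrays = list(value.values())
    stacked = np.hstack(arrays)
    constant = np.all(stacked == stacked[:, [0]], axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f_stat, pvalue = stats.f_oneway(*arrays, axis=1)
    f_stat = np.asarray(f_stat, dtype=float)
    pvalue = np.asarray(pvalue, dtype=float)
    bad = constant | ~np.isfinite(pvalue)
    f_stat[bad] = 0.0
    pvalue[bad] = 1.0

    p_adj = multipletests(pvalue, method=adjust)[1] if len(pvalue) else np.array([])

    raw_means = {g: np.nanmean(x, axis=1) for g, x in raw.items()}
    results: list[DiffResult] = []
    ids = table.feature_ids
    for k, fid in enumerate(ids):
        log2fc = {}
        for num, den in contrasts:
            log2fc[f"{num}/{den}"] = float(
                np.log2((raw_means[num][k] + pseudo) / (raw_means[den][k] + pseudo))
            )
        results.append(
            DiffResult(
                feature_id=fid,
                group_means={g: float(m[k]) for g, m in raw_means.items()},
                f_stat=float(f_stat[k]),
                pvalue=float(pvalue[k]),
                p_adjusted=float(p_adj[k]),
                log2fc=log2fc,
                flags=["zero_variance"] if bad[k] else [],
            )
        )
    return results


def log2_fold_change(
    table: FeatureTable,
    contrast: tuple[str, str],
    pseudo: float = 1.0,
    design: Mapping[str, str] | None = None,
) -> dict[str, float]:
    """log2((mean numerator + pseudo) / (mean denominator + pseudo)).

    ``contrast`` names two groups of the design.  With ``pseudo = 0`` the
    fold change is antisymmetric under swapping the contrast (means > 0).
    """
    design = dict(design) if design is not None else _design_from_metadata(table)
    groups = _group_columns(design)
    num, den = contrast
    for g in contrast:
        if g not in groups:
            raise FeatureTableError(f"unknown group in contrast: {g!r}")
    m_num = table.intensities(groups[num]).mean(axis=1, skipna=True)
    m_den = table.intensities(groups[den]).mean(axis=1, skipna=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.log2((m_num + pseudo) / (m_den + pseudo))
    return {fid: float(v) for fid, v in fc.items()}


def tukey_posthoc(
    table: FeatureTable,
    feature_id: str,
    design: Mapping[str, str] | None = None,
    log_transform: bool = True,
    pseudo: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons for one feature (optional report)."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    design = dict(design) if design is not None else _design_from_metadata(table)
    row = table.intensities(list(design)).loc[feature_id]
    values = row.to_numpy(dtype=float)
    if log_transform:
        values = np.log10(values + pseudo)
    labels = [design[s] for s in row.index]
    result = pairwise_tukeyhsd(values, labels, alpha=alpha)
    frame = pd.DataFrame(
        result.summary().data[1:], columns=result.summary().data[0]
    )
    return frame
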