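"""Redundancy cleaning: within-mode adduct grouping, cross-mode merging.

One neutral metabolite typically appears as several LC-MS features: the
reference ion ([M+H]+ in positive mode, [M-H]- in negative mode) plus
adducts at characteristic mass offsets sharing the retention time.  This
module groups those features (keeping one representative per metabolite)
and links the positive- and negative-mode records of the same neutral
molecule.

Adduct mass offsets are derived at load time from the element mass table
(never hard-coded as literals), so the rules stay consistent with the rest
of the exact-mass arithmetic.  Grouping is greedy in descending intensity:
the most intense unassigned feature is presumed to be the reference ion and
collects its adducts; a feature joins at most one group, which prevents
chained merges across distinct metabolites.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .chemmass import ELECTRON_MASS, ION_SPECIES, MONOISOTOPIC_MASS, PROTON_MASS, IonSpecies

__all__ = [
    "AdductRule",
    "AdductGroup",
    "default_adduct_rules",
    "group_adducts",
    "audit_groups",
    "merge_modes",
]

#: Reference ion per polarity.
REFERENCE_ION = {1: "[M+H]+", -1: "[M-H]-"}

#: Adducts complementary to the reference ion, per polarity.
_DEFAULT_ADDUCTS = {
    1: ["[M+Na]+", "[M+K]+", "[M+NH4]+"],
    -1: [
        "[M+Na-2H]-",
        "[M+K-2H]-",
        "[M+Cl]-",
        "[M+HCOO]-",
        "[M+NO3]-",
        "[M+CH3COO]-",
        "[M+HCOO+HCOONa]-",
    ],
}


@dataclass(frozen=True)
class AdductRule:
    """m/z offset of an adduct relative to its polarity's reference ion."""

    name: str
    polarity: int
    delta: float  # Da


def _ion_shift(ion: IonSpecies) -> float:
    """Mass shift of the ion relative to the neutral M, electron included."""
    mass = sum(MONOISOTOPIC_MASS[e] * n for e, n in ion.delta.items())
    return mass - ion.charge * ELECTRON_MASS


def default_adduct_rules() -> list[AdductRule]:
    """Adduct rules with deltas derived from the element mass table.

    Positive mode: Na, K, NH4 relative to [M+H]+.  Negative mode: Na, K, Cl,
    formate, nitrate, acetate, and the sodium-formate cluster relative to
    [M-H]-.
    """
    rules: list[AdductRule] = []
    for polarity, names in _DEFAULT_ADDUCTS.items():
        ref_shift = _ion_shift(ION_SPECIES[REFERENCE_ION[polarity]])
        for name in names:
            rules.append(
                AdductRule(
                    name=name,
                    polarity=polarity,
                    delta=_ion_shift(ION_SPECIES[name]) - ref_shift,
                )
            )
    return rules


@dataclass
class AdductGroup:
    """Features attributed to one neutral metabolite in one mode."""

    representative: str
    members: list[tuple[str, str]]  # (feature id, ion label), reference first
    neutral_mass: float
    polarity: int
    rt: float


def _median_intensity(table_df: pd.DataFrame, sample_cols: list[str]) -> pd.Series:
    if not sample_cols:
        return pd.Series(0.0, index=table_df.index)
    return table_df[sample_cols].median(axis=1, skipna=True).fillna(0.0)


def group_adducts(
    table,
    rules: Sequence[AdductRule] | None = None,
    mz_tol: float = 0.006,
    rt_tol: float = 0.2,
):
    """Group adduct features under their reference ion, per polarity.

    For each candidate reference feature (processed in descending median
    intensity), an unassigned feature sitting at reference m/z + rule delta
    within ``mz_tol`` and within ``rt_tol`` minutes is claimed as that
    adduct (nearest Δm/z when several qualify).  The cleaned table keeps one
    representative per group — the presumed reference ion — plus all
    ungrouped features; the feature count never increases and the operation
    is idempotent on its own output.

    Returns ``(cleaned_table, groups)``.
    """
    rules = list(rules) if rules is not None else default_adduct_rules()
    df = table.data
    sample_cols = table.sample_ids
    order = _median_intensity(df, sample_cols).sort_values(ascending=False, kind="stable").index

    mz = df["mz"].to_numpy()
    rt = df["rt"].to_numpy()
    pol = df["polarity"].to_numpy()
    ids = df["id"].to_numpy()
    assigned = np.zeros(len(df), dtype=bool)
    groups: list[AdductGroup] = []

    pos_of = {idx: k for k, idx in enumerate(df.index)}
    for idx in order:
        i = pos_of[idx]
        if assigned[i]:
            continue
        polarity = int(pol[i])
        members: list[tuple[int, str]] = []
        for rule in rules:
            if rule.polarity != polarity:
                continue
            target = mz[i] + rule.delta
            cand = np.flatnonzero(
                (~assigned)
                & (pol == polarity)
                & (np.abs(mz - target) <= mz_tol)
                & (np.abs(rt - rt[i]) <= rt_tol)
            )
            cand = cand[cand != i]
            cand = cand[~np.isin(cand, [m for m, _ in members])]
            if cand.size == 0:
                continue
            j = cand[np.argmin(np.abs(mz[cand] - target))]
            members.append((int(j), rule.name))
        if not members:
            continue
        assigned[i] = True
        for j, _ in members:
            assigned[j] = True
        ref_name = REFERENCE_ION[polarity]
        neutral = mz[i] - polarity * PROTON_MASS
        groups.append(
            AdductGroup(
                representative=str(ids[i]),
                members=[(str(ids[i]), ref_name)] + [(str(ids[j]), nm) for j, nm in members],
                neutral_mass=float(neutral),
                polarity=polarity,
                rt=float(rt[i]),
            )
        )

    drop = {m for g in groups for m, _ in g.members[1:]}
    cleaned = replace(
        table, data=df[~df["id"].isin(drop)].reset_index(drop=True)
    )
    return cleaned, groups


def audit_groups(
    groups: Sequence[AdductGroup],
    table,
    rules: Sequence[AdductRule] | None = None,
    mz_tol: float = 0.006,
) -> pd.DataFrame:
    """Self-consistency audit: reconstruct each member m/z from its group.

    Every member's observed m/z must equal the group neutral mass ionized as
    its adduct label within ``mz_tol``; the returned table reports the
    residuals.
    """
    rules = list(rules) if rules is not None else default_adduct_rules()
    delta_of = {(r.polarity, r.name): r.delta for r in rules}
    for polarity, ref in REFERENCE_ION.items():
        delta_of[(polarity, ref)] = 0.0
    mz_of = dict(zip(table.data["id"], table.data["mz"]))
    rows = []
    for g in groups:
        ref_mz = g.neutral_mass + g.polarity * PROTON_MASS
        for fid, ion in g.members:
            expected = ref_mz + delta_of[(g.polarity, ion)]
            residual = mz_of[fid] - expected
            rows.append(
                {
                    "representative": g.representative,
                    "id": fid,
                    "ion": ion,
                    "expected_mz": expected,
                    "residual": residual,
                    "within_tol": abs(residual) <= mz_tol,
                }
            )
    return pd.DataFrame(rows)


def merge_modes(
    pos_table,
    neg_table,
    pos_groups: Sequence[AdductGroup] = (),
    neg_groups: Sequence[AdductGroup] = (),
    mz_tol: float = 0.006,
    rt_tol: float = 0.2,
) -> pd.DataFrame:
    """Link positive- and negative-mode records of the same neutral molecule.

    Both tables should already be adduct-cleaned.  Each remaining feature's
    neutral mass is inferred from its group (when it represented one) or by
    the reference-ion assumption (m/z -/+ one proton); a positive and a
    negative feature are linked when the neutral masses agree within
    ``mz_tol`` and RT within ``rt_tol``.  Links are one-to-one, assigned
    greedily by smallest neutral-mass difference.

    Neither table is modified; the returned link table carries a
    ``preferred_mode`` flag (the more intense record) for downstream
    statistics to deduplicate on.
    """

    def _neutrals(table, groups, polarity):
        by_rep = {g.representative: g.neutral_mass for g in groups}
        df = table.data[table.data["polarity"] == polarity]
        med = _median_intensity(df, table.sample_ids)
        return pd.DataFrame(
            {
                "id": df["id"].to_numpy(),
                "neutral": [
                    by_rep.get(fid, m - polarity * PROTON_MASS)
                    for fid, m in zip(df["id"], df["mz"])
                ],
                "rt": df["rt"].to_numpy(),
                "intensity": med.to_numpy(),
            }
        )

    pos = _neutrals(pos_table, pos_groups, 1)
    neg = _neutrals(neg_table, neg_groups, -1)
    candidates = []
    for p in pos.itertuples(index=False):
        for n in neg.itertuples(index=False):
            dm = abs(p.neutral - n.neutral)
            if dm <= mz_tol and abs(p.rt - n.rt) <= rt_tol:
                candidates.append((dm, p, n))
    candidates.sort(key=lambda c: (c[0], c[1].id, c[2].id))
    used_pos: set[str] = set()
    used_neg: set[str] = set()
    rows = []
    for dm, p, n in candidates:
        if p.id in used_pos or n.id in used_neg:
            continue
        used_pos.add(p.id)
        used_neg.add(n.id)
        rows.append(
            {
                "pos_id": p.id,
                "neg_id": n.id,
                "neutral_mass": (p.neutral + n.neutral) / 2.0,
                "rt": (p.rt + n.rt) / 2.0,
                "delta_neutral": dm,
                "preferred_mode": 1 if p.intensity >= n.intensity else -1,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["pos_id", "neg_id", "neutral_mass", "rt", "delta_neutral", "preferred_mode"],
    )
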