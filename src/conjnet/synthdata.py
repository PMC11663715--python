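"""Ground-truth simulator for two-polarity LC-MS/MS metabolomics runs.

Every pipeline stage is testable without instrument data: the generator
emits a feature table (both ionization modes), MS2 spectra, sample metadata
and a truth record that stays exactly consistent with the package's own
exact-mass arithmetic before jitter is applied.

What is emulated
----------------
* compound *families* sharing MS2 fragments (the structural basis of
  molecular-network clusters), each tagged with a metabolic category;
* planted hormone-amino-acid conjugates at exact conjugate ion masses, and
  free hormones, so the targeted screen has true positives;
* an adduct series per neutral compound (reference ion always, other
  adducts per emission probability) and cross-mode emission of the same
  neutral molecule;
* group-structured intensities (genotype x treatment means from planted
  log2 effects, multiplicative log-normal noise) plus pooled-QC injections
  resampling a pooled mean at the QC coefficient of variation;
* Gaussian m/z and retention-time jitter, and pure-noise features with
  random spectra.

:func:`truth_score` grades pipeline outputs against the truth: adduct-group
recovery, cross-mode link recovery, network family purity, annotation
category accuracy, and a differential-call confusion matrix.
"""

from __future__ import annotations

import json
from collections.abc import Mapping, Sequence
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dedup
from .annotate import Annotation, MassRtLibraryEntry, SpectralLibraryEntry
from .chemmass import (
    AMINO_ACIDS,
    DEFAULT_HORMONES,
    PROTON_MASS,
    conjugate_formula,
    monoisotopic_mass,
)
from .feature_io import FeatureTable, Sample, Spectrum

__all__ = [
    "FamilySpec",
    "PlantedConjugate",
    "PlantedEffect",
    "GeneratorConfig",
    "FeatureTruth",
    "CompoundTruth",
    "GroundTruth",
    "SyntheticDataset",
    "generate",
    "paper_like_config",
    "truth_libraries",
    "truth_score",
]


@dataclass(frozen=True)
class FamilySpec:
    """A compound family: one metabolic category, shared MS2 fragments."""

    category: str
    n_compounds: int
    n_shared_fragments: int = 6


@dataclass(frozen=True)
class PlantedConjugate:
    """A hormone-amino-acid conjugate planted at its exact ion masses."""

    hormone: str
    amino_acid: str


@dataclass(frozen=True)
class PlantedEffect:
    """A log2 intensity effect for groups matching genotype/treatment.

    ``"*"`` matches any genotype or treatment; effects matching the same
    group add up.
    """

    compound: str
    genotype: str
    treatment: str
    log2fc: float


@dataclass
class GeneratorConfig:
    """All the knobs of one simulated experiment (seed mandatory)."""

    seed: int
    families: list[FamilySpec] = field(default_factory=list)
    conjugates: list[PlantedConjugate] = field(default_factory=list)
    conjugate_category: str = "N-acyl amino acids"
    free_hormones: list[str] = field(default_factory=list)
    hormone_category: str = "oxylipins"
    genotypes: list[str] = field(default_factory=lambda: ["WT"])
    treatments: list[str] = field(default_factory=lambda: ["mock", "wound"])
    n_replicates: int = 3
    effects: list[PlantedEffect] = field(default_factory=list)
    adduct_probability: float = 0.3
    cross_mode_probability: float = 0.5
    intensity_cv: float = 0.2
    mz_jitter_sd: float = 0.001
    rt_jitter_sd: float = 0.03
    fragment_mz_jitter_sd: float = 0.003
    n_qc: int = 3
    qc_cv: float = 0.10
    n_noise_features: int = 20
    n_specific_fragments: int = 5
    n_noise_peaks: int = 3
    mass_range: tuple[float, float] = (150.0, 800.0)
    rt_range: tuple[float, float] = (1.0, 14.0)
    base_intensity: float = 1e5
    tissue_weight: float = 5.0  # mg, uniform across samples

    def __post_init__(self):
        for p in (self.adduct_probability, self.cross_mode_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for cv in (self.intensity_cv, self.qc_cv):
            if cv < 0:
                raise ValueError("coefficients of variation must be >= 0")
        known = {c.label for c in self._compound_plan()}
        for e in self.effects:
            if e.compound not in known:
                raise ValueError(f"effect for unplanted compound {e.compound!r}")

    def _compound_plan(self) -> list["_CompoundPlan"]:
        plan: list[_CompoundPlan] = []
        for fam in self.families:
            for k in range(fam.n_compounds):
                plan.append(
                    _CompoundPlan(
                        label=f"{fam.category}_{k + 1:02d}",
                        family=fam.category,
                        category=fam.category,
                        formula=None,
                    )
                )
        for conj in self.conjugates:
            formula = conjugate_formula(
                DEFAULT_HORMONES[conj.hormone], AMINO_ACIDS[conj.amino_acid]
            )
            plan.append(
                _CompoundPlan(
                    label=f"{conj.hormone}-{conj.amino_acid}",
                    family="conjugates",
                    category=self.conjugate_category,
                    formula=formula,
                    prefer_negative=True,
                )
            )
        for hormone in self.free_hormones:
            plan.append(
                _CompoundPlan(
                    label=hormone,
                    family="free-hormones",
                    category=self.hormone_category,
                    formula=DEFAULT_HORMONES[hormone],
                    prefer_negative=True,
                )
            )
        return plan


@dataclass(frozen=True)
class _CompoundPlan:
    label: str
    family: str
    category: str
    formula: object  # MolecularFormula or None (random mass)
    prefer_negative: bool = False


@dataclass
class FeatureTruth:
    feature_id: str
    compound: str | None
    category: str | None
    family: str | None
    ion: str | None
    polarity: int
    neutral_mass: float | None
    is_noise: bool


@dataclass
class CompoundTruth:
    name: str
    category: str
    family: str
    neutral_mass: float
    rt: float
    modes: list[int]
    effects: dict[str, float]  # group label -> planted log2 effect


@dataclass
class GroundTruth:
    features: dict[str, FeatureTruth]
    compounds: dict[str, CompoundTruth]
    adduct_groups: list[list[str]]  # reference id first; groups with >= 2 members
    cross_mode_pairs: list[tuple[str, str]]  # (positive ref id, negative ref id)

    def to_dict(self) -> dict:
        return {
            "features": {k: asdict(v) for k, v in self.features.items()},
            "compounds": {k: asdict(v) for k, v in self.compounds.items()},
            "adduct_groups": self.adduct_groups,
            "cross_mode_pairs": [list(p) for p in self.cross_mode_pairs],
        }


@dataclass
class SyntheticDataset:
    table: FeatureTable
    spectra: list[Spectrum]
    truth: GroundTruth
    config: GeneratorConfig

    def spectra_by_id(self) -> dict[str, Spectrum]:
        return {s.feature_id: s for s in self.spectra}

    def polarities(self) -> dict[str, int]:
        return dict(zip(self.table.data["id"], self.table.data["polarity"].astype(int)))

    def write(self, outdir) -> None:
        """Emit features_pos/neg.csv, metadata.csv, spectra.mgf, truth.json."""
        from .feature_io import write_feature_table, write_metadata, write_mgf

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        split = self.table.split_polarity()
        for polarity, suffix in ((1, "pos"), (-1, "neg")):
            if polarity in split:
                write_feature_table(split[polarity], outdir / f"features_{suffix}.csv")
        write_metadata(self.table.samples, outdir / "metadata.csv")
        write_mgf(self.spectra, outdir / "spectra.mgf")
        (outdir / "truth.json").write_text(json.dumps(self.truth.to_dict(), indent=1))


def _effect_log2(
    effects: Sequence[PlantedEffect], compound: str, genotype: str, treatment: str
) -> float:
    return sum(
        e.log2fc
        for e in effects
        if e.compound == compound
        and e.genotype in ("*", genotype)
        and e.treatment in ("*", treatment)
    )


def generate(config: GeneratorConfig) -> SyntheticDataset:
    """Simulate one two-polarity untargeted run with known ground truth.

    Deterministic for a fixed seed.  Before jitter, every planted
    relationship (adduct offsets, cross-mode pairing, conjugate masses) is
    exact under the package's element-mass arithmetic.
    """
    rng = np.random.default_rng(config.seed)
    sigma = float(np.sqrt(np.log1p(config.intensity_cv**2)))
    qc_sigma = float(np.sqrt(np.log1p(config.qc_cv**2)))

    samples: dict[str, Sample] = {}
    for g in config.genotypes:
        for t in config.treatments:
            for r in range(1, config.n_replicates + 1):
                sid = f"{g}_{t}_{r}"
                samples[sid] = Sample(
                    id=sid, genotype=g, treatment=t, replicate=r,
                    weight=config.tissue_weight,
                )
    for i in range(1, config.n_qc + 1):
        sid = f"QC_{i}"
        samples[sid] = Sample(id=sid, is_qc=True)
    bio_ids = [s for s in samples if not samples[s].is_qc]
    qc_ids = [s for s in samples if samples[s].is_qc]
    groups = [(g, t) for g in config.genotypes for t in config.treatments]

    # family-level shared fragment patterns
    family_frags: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for plan_fam, n_shared in _families_in_order(config):
        mz = np.sort(rng.uniform(50.0, 400.0, n_shared))
        intensity = rng.uniform(60.0, 100.0, n_shared)
        family_frags[plan_fam] = (mz, intensity)

    adduct_rules = dedup.default_adduct_rules()
    rows: list[dict] = []
    spectra: list[Spectrum] = []
    feat_truth: dict[str, FeatureTruth] = {}
    comp_truth: dict[str, CompoundTruth] = {}
    adduct_groups: list[list[str]] = []
    cross_pairs: list[tuple[str, str]] = []
    counter = 0

    def next_id(prefix: str = "F") -> str:
        nonlocal counter
        counter += 1
        return f"{prefix}{counter:04d}"

    for plan in config._compound_plan():
        if plan.formula is not None:
            neutral = monoisotopic_mass(plan.formula)
        else:
            neutral = float(rng.uniform(*config.mass_range))
        rt = float(rng.uniform(*config.rt_range))
        base = config.base_intensity * float(rng.lognormal(0.0, 0.5))
        shared_mz, shared_int = family_frags[plan.family]
        specific_mz = rng.uniform(50.0, 400.0, config.n_specific_fragments)
        specific_int = rng.uniform(10.0, 40.0, config.n_specific_fragments)
        frag_mz = np.concatenate([shared_mz, specific_mz])
        frag_int = np.concatenate(
            [shared_int * rng.uniform(0.8, 1.2, len(shared_int)), specific_int]
        )

        if plan.prefer_negative:
            modes = [-1] + ([1] if rng.random() < config.cross_mode_probability else [])
        elif rng.random() < config.cross_mode_probability:
            modes = [1, -1]
        else:
            modes = [1] if rng.random() < 0.5 else [-1]

        group_mean = {
            f"{g}:{t}": base * 2.0 ** _effect_log2(config.effects, plan.label, g, t)
            for g, t in groups
        }
        pooled = float(np.mean(list(group_mean.values())))

        comp_truth[plan.label] = CompoundTruth(
            name=plan.label,
            category=plan.category,
            family=plan.family,
            neutral_mass=neutral,
            rt=rt,
            modes=list(modes),
            effects={
                f"{g}:{t}": _effect_log2(config.effects, plan.label, g, t)
                for g, t in groups
                if _effect_log2(config.effects, plan.label, g, t) != 0.0
            },
        )

        ref_ids: dict[int, str] = {}
        for polarity in modes:
            ref_mz = neutral + polarity * PROTON_MASS
            emitted: list[tuple[str, str, float, float]] = [
                (next_id(), dedup.REFERENCE_ION[polarity], ref_mz, 1.0)
            ]
            ref_ids[polarity] = emitted[0][0]
            for rule in adduct_rules:
                if rule.polarity != polarity:
                    continue
                if rng.random() < config.adduct_probability:
                    emitted.append(
                        (next_id(), rule.name, ref_mz + rule.delta,
                         float(rng.uniform(0.1, 0.5)))
                    )
            if len(emitted) > 1:
                adduct_groups.append([fid for fid, *_ in emitted])
            for fid, ion, true_mz, scale in emitted:
                obs_mz = true_mz + float(rng.normal(0.0, config.mz_jitter_sd))
                obs_rt = max(0.0, rt + float(rng.normal(0.0, config.rt_jitter_sd)))
                row = {"id": fid, "polarity": polarity, "mz": obs_mz, "rt": obs_rt}
                for g, t in groups:
                    mean = group_mean[f"{g}:{t}"] * scale
                    for r in range(1, config.n_replicates + 1):
                        row[f"{g}_{t}_{r}"] = mean * float(
                            np.exp(rng.normal(-(sigma**2) / 2.0, sigma))
                        )
                for sid in qc_ids:
                    row[sid] = (pooled * scale) * float(
                        np.exp(rng.normal(-(qc_sigma**2) / 2.0, qc_sigma))
                    )
                rows.append(row)
                feat_truth[fid] = FeatureTruth(
                    feature_id=fid, compound=plan.label, category=plan.category,
                    family=plan.family, ion=ion, polarity=polarity,
                    neutral_mass=neutral, is_noise=False,
                )
                peak_mz = frag_mz + rng.normal(0.0, config.fragment_mz_jitter_sd, len(frag_mz))
                peak_int = frag_int * rng.uniform(0.9, 1.1, len(frag_int))
                if config.n_noise_peaks > 0:
                    peak_mz = np.concatenate(
                        [peak_mz, rng.uniform(50.0, 400.0, config.n_noise_peaks)]
                    )
                    peak_int = np.concatenate(
                        [peak_int, rng.uniform(1.0, 5.0, config.n_noise_peaks)]
                    )
                spectra.append(
                    Spectrum(
                        feature_id=fid, precursor_mz=obs_mz,
                        peaks=np.column_stack([peak_mz, peak_int]), rt=obs_rt,
                    )
                )
        if 1 in ref_ids and -1 in ref_ids:
            cross_pairs.append((ref_ids[1], ref_ids[-1]))

    for _ in range(config.n_noise_features):
        polarity = 1 if rng.random() < 0.5 else -1
        fid = next_id("N")
        obs_mz = float(rng.uniform(*config.mass_range))
        obs_rt = float(rng.uniform(*config.rt_range))
        base = config.base_intensity * float(rng.lognormal(0.0, 1.0))
        row = {"id": fid, "polarity": polarity, "mz": obs_mz, "rt": obs_rt}
        for sid in bio_ids:
            row[sid] = base * float(np.exp(rng.normal(-(sigma**2) / 2.0, sigma)))
        for sid in qc_ids:
            row[sid] = base * float(np.exp(rng.normal(-(qc_sigma**2) / 2.0, qc_sigma)))
        rows.append(row)
        feat_truth[fid] = FeatureTruth(
            feature_id=fid, compound=None, category=None, family=None,
            ion=None, polarity=polarity, neutral_mass=None, is_noise=True,
        )
        n_peaks = int(rng.integers(6, 12))
        peaks = np.column_stack(
            [rng.uniform(50.0, 400.0, n_peaks), rng.uniform(1.0, 100.0, n_peaks)]
        )
        spectra.append(Spectrum(feature_id=fid, precursor_mz=obs_mz, peaks=peaks, rt=obs_rt))

    columns = ["id", "polarity", "mz", "rt"] + bio_ids + qc_ids
    table = FeatureTable(pd.DataFrame(rows, columns=columns), samples)
    truth = GroundTruth(
        features=feat_truth,
        compounds=comp_truth,
        adduct_groups=adduct_groups,
        cross_mode_pairs=cross_pairs,
    )
    return SyntheticDataset(table=table, spectra=spectra, truth=truth, config=config)


def _families_in_order(config: GeneratorConfig) -> list[tuple[str, int]]:
    fams = [(f.category, f.n_shared_fragments) for f in config.families]
    if config.conjugates:
        fams.append(("conjugates", 6))
    if config.free_hormones:
        fams.append(("free-hormones", 6))
    return fams


def paper_like_config(seed: int) -> GeneratorConfig:
    """Default study-like preset: wounded vs mock liverwort genotypes.

    Genotypes WT, gh3a (conjugation-deficient) and coi1 (receptor mutant),
    mock vs wound treatments, 3 replicates.  Nine hormone-amino-acid
    conjugates are planted in negative mode with wound-induced accumulation
    in WT and the receptor mutant but not in the conjugation-deficient
    mutant, while the free hormone is wound-induced everywhere and
    over-accumulates in the conjugation-deficient background.  The contrasts
    are qualitative study structure, never quantitative reproduction.
    """
    conjugate_aas = ["Glu", "Gln", "His", "Asp", "Asn", "Ala", "Val", "Leu", "Ile"]
    effects: list[PlantedEffect] = []
    for aa in conjugate_aas:
        name = f"dn-iso-OPDA-{aa}"
        effects.append(PlantedEffect(name, "WT", "wound", 2.0))
        effects.append(PlantedEffect(name, "coi1", "wound", 1.5))
    effects.append(PlantedEffect("dn-iso-OPDA", "WT", "wound", 2.0))
    effects.append(PlantedEffect("dn-iso-OPDA", "coi1", "wound", 1.0))
    effects.append(PlantedEffect("dn-iso-OPDA", "gh3a", "wound", 3.0))
    families = [
        FamilySpec("oxylipins", 6),
        FamilySpec("terpenoids", 6),
        FamilySpec("phenylpropanoids", 6),
        FamilySpec("flavonoids", 6),
    ]
    for fam in families:
        for k in (1, 2):  # a couple of wound-induced compounds per family
            effects.append(PlantedEffect(f"{fam.category}_{k:02d}", "*", "wound", 1.5))
    return GeneratorConfig(
        seed=seed,
        families=families,
        conjugates=[PlantedConjugate("dn-iso-OPDA", aa) for aa in conjugate_aas],
        free_hormones=["dn-iso-OPDA"],
        genotypes=["WT", "gh3a", "coi1"],
        treatments=["mock", "wound"],
        effects=effects,
    )


def truth_libraries(
    dataset: SyntheticDataset, mass_every: int = 3
) -> tuple[list[MassRtLibraryEntry], list[SpectralLibraryEntry]]:
    """Derive annotation libraries from the ground truth.

    The exact-mass/RT library holds every ``mass_every``-th compound's
    reference ion(s) at their true m/z and retention time (what a standards
    library provides).  The spectral library holds the first reference-ion
    spectrum of each family in each polarity (what public MS2 libraries
    provide for well-known family members).
    """
    truth = dataset.truth
    spectra = dataset.spectra_by_id()
    mass_lib: list[MassRtLibraryEntry] = []
    for k, name in enumerate(sorted(truth.compounds)):
        if k % mass_every:
            continue
        comp = truth.compounds[name]
        for polarity in comp.modes:
            ion = dedup.REFERENCE_ION[polarity]
            mass_lib.append(
                MassRtLibraryEntry(
                    name=name, category=comp.category,
                    mz=comp.neutral_mass + polarity * PROTON_MASS,
                    ion=ion, rt=comp.rt,
                )
            )
    spec_lib: list[SpectralLibraryEntry] = []
    seeded: set[tuple[str, int]] = set()
    for fid in sorted(truth.features):
        ft = truth.features[fid]
        if ft.is_noise or ft.ion not in dedup.REFERENCE_ION.values():
            continue
        key = (ft.family, ft.polarity)
        if key in seeded:
            continue
        seeded.add(key)
        spec_lib.append(
            SpectralLibraryEntry(
                id=fid, name=ft.compound, category=ft.category, spectrum=spectra[fid]
            )
        )
    return mass_lib, spec_lib


# ---------------------------------------------------------------------------
# Scoring pipeline outputs against the truth


def _pairs_within(groups: Sequence[Sequence[str]]) -> set[frozenset]:
    pairs: set[frozenset] = set()
    for g in groups:
        members = list(g)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pairs.add(frozenset((members[i], members[j])))
    return pairs


def _safe_ratio(num: int, den: int) -> float:
    return num / den if den else 1.0


def truth_score(
    truth: GroundTruth,
    adduct_groups: Sequence[dedup.AdductGroup] | None = None,
    links: pd.DataFrame | None = None,
    network=None,
    annotations: Mapping[str, Annotation] | None = None,
    diff=None,
    alpha: float = 0.05,
) -> dict:
    """Per-stage precision/recall of pipeline outputs against the truth.

    Pass whichever outputs exist; only those metrics are reported.
    ``adduct_groups`` from :func:`conjnet.dedup.group_adducts` (both modes
    concatenated), ``links`` from :func:`conjnet.dedup.merge_modes`,
    ``network`` a molecular network, ``annotations`` a feature->annotation
    mapping, ``diff`` a list of differential results (significance at
    BH-adjusted p < ``alpha``).
    """
    report: dict = {}

    if adduct_groups is not None:
        pred = _pairs_within([[fid for fid, _ in g.members] for g in adduct_groups])
        true = _pairs_within(truth.adduct_groups)
        tp = len(pred & true)
        report["adduct_grouping"] = {
            "precision": _safe_ratio(tp, len(pred)),
            "recall": _safe_ratio(tp, len(true)),
            "n_pred_pairs": len(pred),
            "n_true_pairs": len(true),
        }

    if links is not None:
        pred_links = {(p, n) for p, n in zip(links["pos_id"], links["neg_id"])}
        true_links = set(truth.cross_mode_pairs)
        tp = len(pred_links & true_links)
        report["cross_mode"] = {
            "precision": _safe_ratio(tp, len(pred_links)),
            "recall": _safe_ratio(tp, len(true_links)),
            "n_pred_links": len(pred_links),
            "n_true_links": len(true_links),
        }

    if network is not None:
        weighted, total = 0.0, 0
        for component in network.components:
            fams = [
                truth.features[fid].family
                for fid in component
                if fid in truth.features and not truth.features[fid].is_noise
            ]
            if len(fams) < 2:
                continue
            top = max(pd.Series(fams).value_counts())
            weighted += top
            total += len(fams)
        report["network"] = {"family_purity": _safe_ratio(int(weighted), total)}

    if annotations is not None:
        non_noise = [f for f in truth.features.values() if not f.is_noise]
        correct = sum(
            1
            for f in non_noise
            if f.feature_id in annotations
            and annotations[f.feature_id].category == f.category
        )
        report["annotation"] = {
            "category_accuracy": _safe_ratio(correct, len(non_noise)),
            "n_features": len(non_noise),
        }

    if diff is not None:
        tp = fp = tn = fn = 0
        for result in diff:
            ft = truth.features.get(result.feature_id)
            if ft is None:
                raise KeyError(f"diff result for unknown feature {result.feature_id}")
            truly_diff = (
                not ft.is_noise
                and bool(truth.compounds[ft.compound].effects)
            )
            called = result.p_adjusted < alpha
            tp += called and truly_diff
            fp += called and not truly_diff
            tn += (not called) and not truly_diff
            fn += (not called) and truly_diff
        report["differential"] = {
            "tp": tp, "fp": fp, "tn": tn, "fn": fn,
            "recall": _safe_ratio(tp, tp + fn),
            "precision": _safe_ratio(tp, tp + fp),
        }

    return report
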