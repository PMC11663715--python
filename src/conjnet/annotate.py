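"""Multi-step metabolite annotation with network propagation.

The cascade mirrors common untargeted-metabolomics practice:

1. exact-mass / retention-time search against a custom library
   (level 1 when an RT standard gates the match, level 2 when the entry is
   exact-mass-only);
2. MS2 spectral-library matching by modified cosine (level 2);
3. metabolic-category propagation through molecular-network clusters: an
   unannotated node in a cluster that contains seeded annotations inherits
   the cluster's majority category (level 3).

A fourth verification pass (external fragmentation-tree software) is out of
scope and represented by a no-op hook that records which annotations would
be re-checked.

Precedence: a level-1 annotation is never overwritten by a later step, and
propagation never touches seeded nodes; propagation is idempotent.

:func:`screen_conjugates` is the targeted counterpart: it matches feature
m/z values against a combinatorial hormone-amino-acid conjugate library at
ppm tolerance, reporting mass-indistinguishable amino acids (Leu/Ile) as a
single joint label.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

from .chemmass import ConjugateEntry, ION_SPECIES
from .feature_io import FeatureTable, Spectrum
from .spectral_network import CosineParams, MolecularNetwork, modified_cosine

__all__ = [
    "MassRtLibraryEntry",
    "SpectralLibraryEntry",
    "Annotation",
    "match_mass_rt",
    "match_spectral_library",
    "propagate_categories",
    "screen_conjugates",
    "annotate_cascade",
    "verification_hook",
]


@dataclass(frozen=True)
class MassRtLibraryEntry:
    """A custom-database record: ion m/z, category, and optionally an RT.

    An entry without RT is an exact-mass-only record; with RT it represents
    an authentic standard measured on the same chromatography.
    """

    name: str
    category: str
    mz: float
    ion: str = ""
    rt: float | None = None

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError(f"{self.name}: library m/z must be positive")


@dataclass(frozen=True)
class SpectralLibraryEntry:
    """A reference MS2 spectrum with compound name and metabolic category."""

    id: str
    name: str
    category: str
    spectrum: Spectrum


@dataclass
class Annotation:
    """Per-feature label with confidence level and evidence trail.

    level 1: exact mass + RT against a standard; level 2: MS2 spectral match
    (or exact-mass-only library hit); level 3: category propagated through a
    network cluster.  Conflicting evidence is retained in ``evidence``.
    """

    feature_id: str
    label: str
    category: str | None
    level: int
    evidence: dict = field(default_factory=dict)


def _mz_tolerance(mz: float, tol_da: float, tol_ppm: float) -> float:
    # permissive reading of "absolute Da or ppm": whichever window is wider
    return max(tol_da, tol_ppm * 1e-6 * mz)


def match_mass_rt(
    table: FeatureTable,
    lib: Sequence[MassRtLibraryEntry],
    mz_tol_da: float = 0.005,
    mz_tol_ppm: float = 10.0,
    rt_tol_min: float = 0.2,
) -> list[Annotation]:
    """Annotation step 1: exact-mass (and RT, when available) library search.

    A feature matches an entry when |Δm/z| <= max(mz_tol_da, ppm window)
    and, if the entry carries an RT, |ΔRT| <= rt_tol_min.  Among passing
    entries the smallest |Δm/z| wins.  RT-gated matches are level 1,
    exact-mass-only matches level 2.
    """
    annotations: list[Annotation] = []
    for row in table.data.itertuples(index=False):
        best: tuple[float, MassRtLibraryEntry] | None = None
        for entry in lib:
            dmz = abs(row.mz - entry.mz)
            if dmz > _mz_tolerance(row.mz, mz_tol_da, mz_tol_ppm):
                continue
            if entry.rt is not None and abs(row.rt - entry.rt) > rt_tol_min:
                continue
            if best is None or dmz < best[0]:
                best = (dmz, entry)
        if best is None:
            continue
        dmz, entry = best
        annotations.append(
            Annotation(
                feature_id=row.id,
                label=entry.name,
                category=entry.category,
                level=1 if entry.rt is not None else 2,
                evidence={
                    "step": "mass_rt",
                    "library_entry": entry.name,
                    "delta_mz": dmz,
                    "rt_gated": entry.rt is not None,
                },
            )
        )
    return annotations


def match_spectral_library(
    spectra: Iterable[Spectrum],
    library: Sequence[SpectralLibraryEntry],
    mz_tol: float = 0.02,
    min_peaks: int = 4,
    min_cosine: float = 0.8,
    params: CosineParams | None = None,
) -> list[Annotation]:
    """Annotation step 2: MS2 spectral-library matching (level 2).

    Each query is scored (modified cosine) against every library spectrum;
    the best hit with score >= ``min_cosine`` and >= ``min_peaks`` matched
    fragments is assigned.
    """
    params = params or CosineParams(
        fragment_tolerance=mz_tol, min_matched_peaks=min_peaks, score_threshold=min_cosine
    )
    annotations: list[Annotation] = []
    for query in spectra:
        best: tuple[float, int, SpectralLibraryEntry] | None = None
        for entry in library:
            score, n = modified_cosine(query, entry.spectrum, params)
            if n < min_peaks or score < min_cosine:
                continue
            if best is None or score > best[0]:
                best = (score, n, entry)
        if best is None:
            continue
        score, n, entry = best
        annotations.append(
            Annotation(
                feature_id=query.feature_id,
                label=entry.name,
                category=entry.category,
                level=2,
                evidence={
                    "step": "spectral_library",
                    "library_spectrum": entry.id,
                    "score": score,
                    "n_matched": n,
                },
            )
        )
    return annotations


def propagate_categories(
    net: MolecularNetwork, seeds: Sequence[Annotation]
) -> list[Annotation]:
    """Annotation step 3: propagate categories through network clusters.

    Every unannotated node in a connected component holding at least one
    seeded category receives the component's majority category at level 3.
    Ties are broken by the category of the highest-scoring seed (spectral
    score, falling back to level: lower is stronger), then lexicographically.
    Components without seeds stay unannotated.  When seed categories
    conflict, the full category tally is recorded on every propagated
    annotation.  Seeded nodes are never modified, which also makes the
    operation idempotent.
    """
    seeded: dict[str, Annotation] = {a.feature_id: a for a in seeds}
    out: list[Annotation] = []
    for component in net.components:
        in_comp = [seeded[f] for f in component if f in seeded and seeded[f].category]
        if not in_comp:
            continue
        tally = Counter(a.category for a in in_comp)
        top = max(tally.values())
        tied = sorted(c for c, n in tally.items() if n == top)
        if len(tied) > 1:
            def seed_strength(a: Annotation) -> tuple:
                return (a.evidence.get("score", 0.0), -a.level)

            best_seed = max(
                (a for a in in_comp if a.category in tied),
                key=lambda a: (*seed_strength(a), a.category),
            )
            category = best_seed.category
        else:
            category = tied[0]
        conflict = len(tally) > 1
        for fid in sorted(component):
            if fid in seeded:
                continue
            out.append(
                Annotation(
                    feature_id=fid,
                    label=category,
                    category=category,
                    level=3,
                    evidence={
                        "step": "network_propagation",
                        "seed_ids": sorted(a.feature_id for a in in_comp),
                        "seed_categories": dict(tally),
                        "conflict": conflict,
                    },
                )
            )
    return out


def screen_conjugates(
    table: FeatureTable,
    library: Sequence[ConjugateEntry],
    mz_tol_ppm: float = 10.0,
) -> list[Annotation]:
    """Targeted screen of feature m/z against a conjugate library.

    A feature matching a conjugate ion m/z of its own polarity within
    ``mz_tol_ppm`` is labelled ``putative <hormone>-<aa>``; conjugates with
    identical formulas (Leu/Ile) yield one joint ambiguous label.  Each
    feature gets at most one hit (nearest in ppm).
    """
    annotations: list[Annotation] = []
    for row in table.data.itertuples(index=False):
        best: tuple[float, ConjugateEntry, str] | None = None
        for entry in library:
            for ion_name, mz in entry.mz.items():
                if ION_SPECIES[ion_name].polarity != row.polarity:
                    continue
                dppm = abs(row.mz - mz) / mz * 1e6
                if dppm > mz_tol_ppm:
                    continue
                if best is None or dppm < best[0]:
                    best = (dppm, entry, ion_name)
        if best is None:
            continue
        dppm, entry, ion_name = best
        annotations.append(
            Annotation(
                feature_id=row.id,
                label=f"putative {entry.label}",
                category=None,
                level=2,
                evidence={
                    "step": "conjugate_screen",
                    "ion": ion_name,
                    "delta_ppm": dppm,
                    "formula": entry.formula.hill(),
                    "ambiguous_amino_acids": sorted(
                        (entry.amino_acid, *entry.indistinguishable_from)
                    )
                    if entry.indistinguishable_from
                    else [],
                },
            )
        )
    return annotations


def annotate_cascade(
    table: FeatureTable,
    spectra: Iterable[Spectrum],
    mass_rt_library: Sequence[MassRtLibraryEntry],
    spectral_library: Sequence[SpectralLibraryEntry],
    network: MolecularNetwork,
    **kwargs,
) -> dict[str, Annotation]:
    """Run annotation steps 1-3 with cascade precedence.

    Step 1 assignments are kept over step 2 for the same feature (and
    level 1 over everything); step 3 only fills features with no prior
    annotation.  The later, discarded candidate is retained under
    ``evidence["superseded"]``.  Returns feature id -> primary annotation.
    """
    mass_kwargs = {k: kwargs[k] for k in ("mz_tol_da", "mz_tol_ppm", "rt_tol_min") if k in kwargs}
    spec_kwargs = {k: kwargs[k] for k in ("mz_tol", "min_peaks", "min_cosine") if k in kwargs}
    primary: dict[str, Annotation] = {}
    for ann in match_mass_rt(table, mass_rt_library, **mass_kwargs):
        primary[ann.feature_id] = ann
    for ann in match_spectral_library(spectra, spectral_library, **spec_kwargs):
        held = primary.get(ann.feature_id)
        if held is None:
            primary[ann.feature_id] = ann
        else:
            held.evidence.setdefault("superseded", []).append(
                {"label": ann.label, "level": ann.level, "step": ann.evidence.get("step")}
            )
    for ann in propagate_categories(network, list(primary.values())):
        primary.setdefault(ann.feature_id, ann)
    return primary


def verification_hook(annotations: Mapping[str, Annotation]) -> list[str]:
    """Placeholder for the external verification pass (step 4).

    Performs no re-annotation; returns the feature ids whose assignments
    rest on propagated or ambiguous evidence and would be re-checked by
    fragmentation-tree software or manual MS2 inspection.
    """
    flagged = [
        fid
        for fid, a in annotations.items()
        if a.level == 3 or a.evidence.get("conflict") or a.evidence.get("ambiguous_amino_acids")
    ]
    return sorted(flagged)
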