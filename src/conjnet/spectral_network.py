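"""MS/MS cosine similarity and molecular-network construction.

The modified cosine score aligns two fragment spectra allowing a fragment
pair to match either directly (|Δm/z| <= tolerance) or offset by the
precursor mass difference, which is what lets structural analogues (e.g. the
same backbone conjugated to different amino acids) score highly.  Intensities
are power-transformed (square root by default, the common networking
convention) and L2-normalized, and the score is the total product weight of a
one-to-one peak matching.

The matching is solved as an optimal assignment over the candidate pairs
(scipy's linear sum assignment), so the reported score is exactly the
maximum over all one-to-one matchings; the cheaper greedy descending-score
matcher is available via ``CosineParams.matching = "greedy"``.

A molecular network keeps an edge wherever the score reaches the threshold
with enough matched peaks; connected components ("clusters") are the units
used for annotation propagation.  Pairs are only ever scored within one
ionization mode.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment

from .feature_io import Spectrum

__all__ = [
    "CosineParams",
    "MolecularNetwork",
    "modified_cosine",
    "build_network",
    "decorate_nodes",
    "export_graph",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CosineParams:
    """Scoring and network-building parameters.

    fragment_tolerance : Da window for a fragment pair to count as matched.
    min_matched_peaks  : matchings with fewer pairs score 0.
    score_threshold    : minimum score for a network edge.
    allow_precursor_shift : also match pairs offset by Δprecursor
        (modified cosine); disable for the plain cosine.
    intensity_power    : intensities are raised to this power before
        normalization (0.5 = square-root weighting).
    matching           : "optimal" (exact maximum-weight one-to-one
        matching) or "greedy" (descending pair score).
    """

    fragment_tolerance: float = 0.02
    min_matched_peaks: int = 4
    score_threshold: float = 0.7
    allow_precursor_shift: bool = True
    intensity_power: float = 0.5
    matching: str = "optimal"

    def __post_init__(self):
        if self.fragment_tolerance <= 0:
            raise ValueError("fragment_tolerance must be > 0")
        if not 0.0 <= self.score_threshold <= 1.0:
            raise ValueError("score_threshold must be in [0, 1]")
        if self.min_matched_peaks < 1:
            raise ValueError("min_matched_peaks must be >= 1")
        if self.matching not in ("optimal", "greedy"):
            raise ValueError("matching must be 'optimal' or 'greedy'")


def _weights(spec: Spectrum, power: float) -> np.ndarray:
    w = spec.intensities.astype(float) ** power
    norm = np.sqrt((w**2).sum())
    return w / norm if norm > 0 else w


def modified_cosine(
    a: Spectrum, b: Spectrum, params: CosineParams | None = None
) -> tuple[float, int]:
    """Cosine similarity of two MS2 spectra with optional precursor shift.

    Returns ``(score, n_matched)``.  The score is the maximum-weight
    one-to-one matching of candidate fragment pairs on power-transformed,
    L2-normalized intensities; it is 0.0 (match count still reported) when
    fewer than ``min_matched_peaks`` pairs match.
    """
    params = params or CosineParams()
    if len(a) == 0 or len(b) == 0:  # defensive; Spectrum forbids empty
        raise ValueError("cannot score an empty spectrum")
    wa = _weights(a, params.intensity_power)
    wb = _weights(b, params.intensity_power)
    diff = a.mz[:, None] - b.mz[None, :]
    candidate = np.abs(diff) <= params.fragment_tolerance
    if params.allow_precursor_shift:
        shift = a.precursor_mz - b.precursor_mz
        candidate |= np.abs(diff - shift) <= params.fragment_tolerance
    if not candidate.any():
        return 0.0, 0
    pair_score = np.where(candidate, wa[:, None] * wb[None, :], 0.0)

    if params.matching == "optimal":
        rows, cols = linear_sum_assignment(pair_score, maximize=True)
        chosen = [(i, j) for i, j in zip(rows, cols) if candidate[i, j] and pair_score[i, j] > 0]
    else:  # greedy: descending pair score, deterministic tie-break on indices
        order = sorted(
            zip(*np.nonzero(candidate)),
            key=lambda ij: (-pair_score[ij[0], ij[1]], ij[0], ij[1]),
        )
        used_a: set[int] = set()
        used_b: set[int] = set()
        chosen = []
        for i, j in order:
            if i in used_a or j in used_b or pair_score[i, j] <= 0:
                continue
            chosen.append((i, j))
            used_a.add(i)
            used_b.add(j)

    n_matched = len(chosen)
    if n_matched < params.min_matched_peaks:
        return 0.0, n_matched
    score = float(sum(pair_score[i, j] for i, j in chosen))
    return min(score, 1.0), n_matched


@dataclass
class MolecularNetwork:
    """Cosine-weighted graph over MS features.

    Undirected, no self-loops; every edge carries ``score`` and
    ``n_matched`` and satisfies the thresholds in ``params``.  Clusters are
    the connected components.
    """

    graph: nx.Graph
    params: CosineParams = field(default_factory=CosineParams)

    @property
    def components(self) -> list[frozenset[str]]:
        comps = [frozenset(c) for c in nx.connected_components(self.graph)]
        return sorted(comps, key=lambda c: sorted(c)[0])

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


def build_network(
    spectra: Iterable[Spectrum],
    params: CosineParams | None = None,
    polarities: Mapping[str, int] | None = None,
) -> MolecularNetwork:
    """Score all same-polarity spectrum pairs and keep edges over threshold.

    ``polarities`` maps feature id -> +1/-1; spectra without an entry (or
    when the mapping is omitted) are treated as one mode.  Deterministic for
    a given input order-insensitive set of spectra (nodes and pairs are
    processed in sorted feature-id order).
    """
    params = params or CosineParams()
    by_id = {s.feature_id: s for s in spectra}
    graph = nx.Graph()
    ids = sorted(by_id)
    for fid in ids:
        s = by_id[fid]
        pol = polarities.get(fid, 0) if polarities else 0
        attrs = {"mz": float(s.precursor_mz), "polarity": int(pol)}
        if s.rt is not None:
            attrs["rt"] = float(s.rt)
        graph.add_node(fid, **attrs)
    for i, fid_a in enumerate(ids):
        for fid_b in ids[i + 1 :]:
            if graph.nodes[fid_a]["polarity"] != graph.nodes[fid_b]["polarity"]:
                continue
            score, n = modified_cosine(by_id[fid_a], by_id[fid_b], params)
            if score >= params.score_threshold and n >= params.min_matched_peaks:
                graph.add_edge(fid_a, fid_b, score=score, n_matched=n)
    return MolecularNetwork(graph, params)


def decorate_nodes(
    net: MolecularNetwork,
    fold_changes: Mapping[str, float] | None = None,
    annotations: Mapping[str, object] | None = None,
) -> MolecularNetwork:
    """Attach log2 fold changes and annotation labels to network nodes.

    Nodes without a value keep no attribute (and are logged); extra mapping
    keys that match no node are logged as well.
    """
    for name, mapping, extract in (
        ("log2fc", fold_changes, float),
        ("annotation", annotations, None),
    ):
        if mapping is None:
            continue
        unmatched = [k for k in mapping if k not in net.graph.nodes]
        if unmatched:
            logger.warning("%s: %d id(s) not in network (e.g. %s)", name, len(unmatched), unmatched[:3])
        for fid in net.graph.nodes:
            if fid in mapping:
                value = mapping[fid]
                if name == "annotation" and hasattr(value, "label"):
                    net.graph.nodes[fid]["annotation"] = value.label
                    net.graph.nodes[fid]["annotation_level"] = int(value.level)
                    if getattr(value, "category", None):
                        net.graph.nodes[fid]["category"] = value.category
                else:
                    net.graph.nodes[fid][name] = extract(value) if extract else value
            else:
                logger.debug("node %s has no %s value", fid, name)
    return net


def export_graph(net: MolecularNetwork, path, fmt: str = "graphml") -> None:
    """Serialize the network for Cytoscape.

    ``graphml`` writes a schema-valid GraphML document; ``edgelist`` writes a
    delimited edge table to ``path`` and a node-attribute table next to it
    (``<path>.nodes.csv``).
    """
    if fmt == "graphml":
        nx.write_graphml(net.graph, str(path))
    elif fmt == "edgelist":
        import pandas as pd

        edges = pd.DataFrame(
            [
                {"source": u, "target": v, **d}
                for u, v, d in net.graph.edges(data=True)
            ]
        )
        edges.to_csv(path, index=False)
        nodes = pd.DataFrame(
            [{"id": n, **d} for n, d in net.graph.nodes(data=True)]
        )
        nodes.to_csv(f"{path}.nodes.csv", index=False)
    else:
        raise ValueError(f"unknown export format: {fmt!r}")
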