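"""ROI-to-network parcellation and edge-hypothesis bookkeeping.

A :class:`NetworkAtlas` maps each region of interest (ROI) to exactly one of
five resting-state functional networks — Default Mode (DMN), Fronto-Parietal
(FPN), Salience (SN), Cingulo-Opercular (CON) and Sensory-Motor (SMN).  Every
unordered ROI pair is then either an *intra*-network edge (both endpoints in
one network) or an *inter*-network edge (endpoints in two different
networks); the two families are tested separately downstream.

Canonical edge identity is ``(min_index, max_index)`` by atlas row order, so
all downstream tables are reproducible regardless of label sort locale.

The bundled 40-ROI atlas (``data/atlas40_synthetic.tsv``) is a synthetic
reconstruction of a published parcellation: the ROI/network assignments that
the source tables reveal are kept verbatim, and the remaining slots are
filled with canonical members of each network so that the family sizes (157
intra and 623 inter pairs per band) match the published test counts.  It is
a plausible stand-in, not ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .bands import BandSpec

NETWORK_NAMES: tuple[str, ...] = ("DMN", "FPN", "SN", "CON", "SMN")
HEMISPHERES: tuple[str, ...] = ("L", "R")


class AtlasError(ValueError):
    """Raised for malformed atlas tables or unresolvable ROI labels."""


@dataclass(frozen=True)
class ROIEntry:
    """A single region: label, functional network, hemisphere."""

    name: str
    network: str
    hemisphere: str

    def __post_init__(self) -> None:
        if self.network not in NETWORK_NAMES:
            raise AtlasError(
                f"unknown network {self.network!r} for ROI {self.name!r}; "
                f"expected one of {NETWORK_NAMES}"
            )
        if self.hemisphere not in HEMISPHERES:
            raise AtlasError(
                f"unknown hemisphere {self.hemisphere!r} for ROI {self.name!r}"
            )


@dataclass(frozen=True)
class EdgeFamily:
    """Classification of one edge: intra-network or inter-network.

    For inter edges ``networks`` holds the two network names in sorted
    order, so the family label is independent of argument order.
    """

    kind: str  # "intra" | "inter"
    networks: tuple[str, ...]

    @property
    def label(self) -> str:
        return self.networks[0] if self.kind == "intra" else "-".join(self.networks)


class NetworkAtlas:
    """Ordered collection of :class:`ROIEntry`; row order is ROI index order."""

    def __init__(self, entries: Sequence[ROIEntry]):
        if len(entries) < 2:
            raise AtlasError("an atlas needs at least 2 ROIs")
        names = [e.name for e in entries]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise AtlasError(f"duplicate ROI names in atlas: {sorted(dupes)}")
        self.entries: tuple[ROIEntry, ...] = tuple(entries)
        self._index: dict[str, int] = {e.name: i for i, e in enumerate(entries)}

    @property
    def n_rois(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def index_of(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise AtlasError(f"ROI {name!r} not in atlas") from None

    def network_of(self, name: str) -> str:
        return self.entries[self.index_of(name)].network

    def network_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for e in self.entries:
            sizes[e.network] = sizes.get(e.network, 0) + 1
        return sizes

    def hemisphere_counts(self, names: Iterable[str]) -> dict[str, int]:
        """Count L/R membership of a set of ROI labels (reporting metadata)."""
        counts = {"L": 0, "R": 0}
        for n in set(names):
            counts[self.entries[self.index_of(n)].hemisphere] += 1
        return counts

    def __len__(self) -> int:
        return self.n_rois

    def __repr__(self) -> str:
        return f"NetworkAtlas(n_rois={self.n_rois}, networks={self.network_sizes()})"


def load_atlas(path: str | Path) -> NetworkAtlas:
    """Read a delimited atlas table (columns roi_name, network, hemisphere).

    Tab- and comma-delimited files are both accepted; a header row is
    required and row order defines the ROI index order.
    """
    path = Path(path)
    import csv

    try:
        table = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except (pd.errors.EmptyDataError, csv.Error):
        raise AtlasError(f"atlas file {path} is empty or undelimited") from None
    required = {"roi_name", "network", "hemisphere"}
    missing = required - set(table.columns)
    if missing:
        raise AtlasError(f"atlas file {path} missing columns: {sorted(missing)}")
    if table.empty:
        raise AtlasError(f"atlas file {path} has a header but no rows")
    entries = [
        ROIEntry(row.roi_name.strip(), row.network.strip(), row.hemisphere.strip())
        for row in table.itertuples()
    ]
    return NetworkAtlas(entries)


def default_atlas() -> NetworkAtlas:
    """The bundled synthetic 40-ROI / 5-network parcellation."""
    with resources.as_file(
        resources.files("plvnet.data") / "atlas40_synthetic.tsv"
    ) as p:
        return load_atlas(p)


def classify_edge(atlas: NetworkAtlas, roi_a: str, roi_b: str) -> EdgeFamily:
    """Classify an unordered ROI pair as intra- or inter-network."""
    if roi_a == roi_b:
        raise AtlasError(f"self-edge {roi_a!r} is not a valid hypothesis")
    net_a = atlas.network_of(roi_a)
    net_b = atlas.network_of(roi_b)
    if net_a == net_b:
        return EdgeFamily("intra", (net_a,))
    return EdgeFamily("inter", tuple(sorted((net_a, net_b))))


def enumerate_hypotheses(
    atlas: NetworkAtlas, bands: Sequence[BandSpec]
) -> dict[str, list[tuple[tuple[int, int], str]]]:
    """Enumerate every (unordered ROI pair, band) hypothesis by family.

    Returns ``{"intra": [...], "inter": [...]}`` where each element is
    ``((i, j), band_name)`` with i < j by atlas index.  Ordering is
    deterministic: pair index-lexicographic, then band order.  Together the
    two lists partition all C(n_rois, 2) * len(bands) hypotheses.
    """
    if not bands:
        raise AtlasError("at least one band is required")
    out: dict[str, list[tuple[tuple[int, int], str]]] = {"intra": [], "inter": []}
    nets = [e.network for e in atlas.entries]
    for i in range(atlas.n_rois):
        for j in range(i + 1, atlas.n_rois):
            kind = "intra" if nets[i] == nets[j] else "inter"
            for band in bands:
                out[kind].append(((i, j), band.name))
    return out
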