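"""Region tables and network partitions.

The default fixture is the 15-region, three-network parcellation used
throughout the package: the core default network (cDN: PCC, aMPFC and the
bilateral angular gyri), the salience network (SN: dACC, bilateral anterior
insula and bilateral anterior PFC) and the dorsal attention network (DAN:
bilateral FEF, IFG and IPS).  Coordinates are group-level MNI peaks in mm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

#: Canonical ordering of the three networks in every 3x3 network-level matrix.
NETWORK_ORDER: Tuple[str, str, str] = ("cDN", "SN", "DAN")

# label, network, MNI x, y, z
_DEFAULT_TABLE = [
    ("PCC", "cDN", -3, -57, 21),
    ("aMPFC", "cDN", 3, 54, 18),
    ("lAG", "cDN", -48, -69, 33),
    ("rAG", "cDN", 51, -63, 27),
    ("dACC", "SN", -3, 15, 42),
    ("lAI", "SN", -36, 15, 6),
    ("rAI", "SN", 33, 18, 6),
    ("laPFC", "SN", -27, 45, 30),
    ("raPFC", "SN", 30, 42, 30),
    ("lFEF", "DAN", -24, -9, 57),
    ("rFEF", "DAN", 27, -3, 54),
    ("lIFG", "DAN", -51, 9, 27),
    ("rIFG", "DAN", 54, 12, 30),
    ("lIPS", "DAN", -42, -36, 45),
    ("rIPS", "DAN", 39, -42, 51),
]


@dataclass(frozen=True)
class RegionSet:
    """An ordered set of named regions with a network tag per region.

    A ``RegionSet`` doubles as the network partition: every region carries
    exactly one network label, and network-level operations group regions by
    that label.
    """

    labels: Tuple[str, ...]
    networks: Tuple[str, ...]
    coordinates: Optional[Tuple[Tuple[float, float, float], ...]] = None

    def __post_init__(self):
        labels = tuple(self.labels)
        networks = tuple(self.networks)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "networks", networks)
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"region labels must be unique; duplicated: {dupes}")
        if len(networks) != len(labels):
            raise ValueError(
                f"{len(labels)} labels but {len(networks)} network tags"
            )
        if self.coordinates is not None:
            coords = tuple(tuple(float(v) for v in c) for c in self.coordinates)
            if len(coords) != len(labels) or any(len(c) != 3 for c in coords):
                raise ValueError("coordinates must be one (x, y, z) triplet per region")
            object.__setattr__(self, "coordinates", coords)

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def network_names(self) -> Tuple[str, ...]:
        """Networks in canonical order (NETWORK_ORDER first, extras appended)."""
        present = [n for n in NETWORK_ORDER if n in self.networks]
        extras = sorted(set(self.networks) - set(NETWORK_ORDER))
        return tuple(present + extras)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown region label {label!r}") from None

    def indices(self, network: str) -> np.ndarray:
        """Indices of the regions belonging to ``network``."""
        idx = np.flatnonzero(np.asarray(self.networks) == network)
        if idx.size == 0:
            raise KeyError(f"no regions tagged with network {network!r}")
        return idx

    def counts(self) -> dict:
        return {net: int(len(self.indices(net))) for net in self.network_names}


def load_region_fixture() -> RegionSet:
    """The packaged 15-region table (4 cDN, 5 SN, 6 DAN) with MNI peaks."""
    labels, networks, coords = zip(*((r[0], r[1], (r[2], r[3], r[4])) for r in _DEFAULT_TABLE))
    return RegionSet(labels=labels, networks=networks, coordinates=coords)
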