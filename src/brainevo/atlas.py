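"""Region atlas: node identities, 3-D coordinates and pairwise distances.

The atlas stands in for a 90-region anatomical parcellation. Node
coordinates live in millimetres; the pairwise Euclidean distance matrix
drives both the long-distance edge count (> 75 mm) and the distance terms
of the evolution rules. A synthetic atlas samples coordinates uniformly in
a 140 x 170 x 120 mm box (a brain-like extent); a user-supplied coordinate
table in the same format can replace it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

#: Default number of regions (90-region parcellation).
N_REGIONS_DEFAULT = 90

#: Extent of the synthetic coordinate box, millimetres (x, y, z).
BOX_MM = (140.0, 170.0, 120.0)

#: Anatomical separation above which an edge counts as long-distance, mm.
LONG_DISTANCE_MM = 75.0


@dataclass(frozen=True)
class RegionAtlas:
    """Node labels, coordinates (mm) and the derived distance matrix."""

    labels: tuple[str, ...]
    coords: np.ndarray  # (n, 3), mm
    distance: np.ndarray = field(init=False)  # (n, n), mm

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise InvalidArgumentError("coords must be an (n, 3) array")
        if len(self.labels) != coords.shape[0]:
            raise InvalidArgumentError("labels and coords disagree on the number of regions")
        diff = coords[:, None, :] - coords[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=-1))
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "distance", dist)

    @property
    def n_regions(self) -> int:
        return self.coords.shape[0]

    def validate(self) -> None:
        d = self.distance
        if not np.allclose(d, d.T):
            raise InvalidArgumentError("distance matrix is not symmetric")
        off = d[~np.eye(self.n_regions, dtype=bool)]
        if np.any(off <= 0):
            raise InvalidArgumentError("two regions share identical coordinates")


def generate_atlas(n_regions: int = N_REGIONS_DEFAULT, seed: int = 0) -> RegionAtlas:
    """Sample a synthetic atlas with coordinates uniform in a brain-sized box.

    Deterministic for a fixed ``(n_regions, seed)``.
    """
    if n_regions < 2:
        raise InvalidArgumentError("an atlas needs at least 2 regions")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(low=(0.0, 0.0, 0.0), high=BOX_MM, size=(n_regions, 3))
    labels = tuple(f"R{i:03d}" for i in range(n_regions))
    atlas = RegionAtlas(labels=labels, coords=coords)
    atlas.validate()
    return atlas
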