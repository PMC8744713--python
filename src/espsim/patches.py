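"""Labeled patches: connected components of a categorical or binary raster.

A :class:`Patch` is a connected set of cells (8-connectivity throughout the
package) with its area in hm² and its boundary cells — the substrate of the
connectivity index and of corridor routing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import BinaryMask

#: 3×3 structuring element for 8-connectivity.
STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class Patch:
    id: int
    area_hm2: float
    cells: np.ndarray  # (n, 2) row/col indices
    boundary: np.ndarray  # (m, 2) row/col indices of cells with an outside 8-neighbor

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass
class PatchSet:
    patches: list[Patch]
    cell_size: float
    origin: tuple[float, float]
    shape: tuple[int, int]

    def __len__(self) -> int:
        return len(self.patches)

    def __iter__(self):
        return iter(self.patches)

    def ids(self) -> list[int]:
        return [p.id for p in self.patches]

    def by_id(self, pid: int) -> Patch:
        for p in self.patches:
            if p.id == pid:
                return p
        raise KeyError(pid)

    def total_area_hm2(self) -> float:
        return float(sum(p.area_hm2 for p in self.patches))

    def mask(self) -> BinaryMask:
        bits = np.zeros(self.shape, dtype=bool)
        for p in self.patches:
            bits[p.cells[:, 0], p.cells[:, 1]] = True
        return BinaryMask(self.cell_size, self.origin, bits)

    def subset(self, ids) -> "PatchSet":
        keep = set(ids)
        return PatchSet(
            [p for p in self.patches if p.id in keep],
            self.cell_size,
            self.origin,
            self.shape,
        )


def label_mask(mask: BinaryMask, min_area_hm2: float = 0.0) -> PatchSet:
    """8-connected components of a mask, keeping those with area >= threshold."""
    labels, n = ndimage.label(mask.bits, structure=STRUCT8)
    cell_hm2 = mask.cell_area_hm2
    interior = ndimage.binary_erosion(mask.bits, structure=STRUCT8, border_value=0)
    patches = []
    for obj_id, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        sub = labels[sl] == obj_id
        rows, cols = np.nonzero(sub)
        cells = np.column_stack([rows + sl[0].start, cols + sl[1].start])
        area = len(cells) * cell_hm2
        if area < min_area_hm2:
            continue
        on_boundary = ~interior[cells[:, 0], cells[:, 1]]
        patches.append(
            Patch(id=obj_id, area_hm2=area, cells=cells, boundary=cells[on_boundary])
        )
    return PatchSet(patches, mask.cell_size, mask.origin, mask.bits.shape)
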