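"""Morphological spatial pattern analysis (MSPA).

Classifies a binary habitat (foreground) map into seven mutually exclusive
classes — core, islet, perforation, edge, bridge, loop, branch — using
8-connectivity and an edge width measured in erosion iterations with the
3×3 structuring element (Chebyshev distance). Cells outside the grid count
as background.

Class geometry:

* **core** — foreground farther than ``edge_width`` from background
  (iterated 8-neighborhood erosion).
* **islet** — an entire 8-connected foreground component containing no core.
* **edge / perforation** — non-core foreground within ``edge_width`` of a
  core (the boundary zone of core regions); *perforation* where the nearby
  background is a hole enclosed by the component, *edge* where it is outer
  background (outer takes precedence when both are in reach).
* **bridge / loop / branch** — the remaining narrow residue, classified per
  8-connected residue component by the core regions it contacts (directly
  or through their boundary zone): two or more distinct cores → bridge;
  one core reached at two or more separate contact stretches → loop;
  otherwise → branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import GRASSLAND, WOODLAND, BinaryMask, LandUseGrid
from .patches import STRUCT8, PatchSet, label_mask

BACKGROUND, CORE, ISLET, PERFORATION, EDGE, BRIDGE, LOOP, BRANCH = range(8)

CLASS_NAMES = {
    BACKGROUND: "background",
    CORE: "core",
    ISLET: "islet",
    PERFORATION: "perforation",
    EDGE: "edge",
    BRIDGE: "bridge",
    LOOP: "loop",
    BRANCH: "branch",
}

#: Default ecological foreground: woodland and grassland (the six-class
#: legend does not split grassland by coverage, so all grassland counts).
DEFAULT_FOREGROUND_CLASSES = (WOODLAND, GRASSLAND)


@dataclass
class MSPAResult:
    classes: np.ndarray  # integer grid over the 0..7 code table
    edge_width: int
    cell_size: float
    origin: tuple[float, float]

    def mask_of(self, *codes: int) -> BinaryMask:
        return BinaryMask(
            self.cell_size, self.origin, np.isin(self.classes, codes)
        )

    def class_counts(self) -> dict[str, int]:
        return {
            CLASS_NAMES[c]: int(np.sum(self.classes == c)) for c in range(8)
        }


def make_foreground(
    landuse: LandUseGrid,
    classes: tuple[int, ...] = DEFAULT_FOREGROUND_CLASSES,
) -> BinaryMask:
    """Ecological foreground mask; nodata cells are background."""
    return landuse.class_mask(*classes)


def _dilate(bits: np.ndarray, iterations: int) -> np.ndarray:
    if iterations <= 0 or not bits.any():
        return bits.copy()
    return ndimage.binary_dilation(bits, structure=STRUCT8, iterations=iterations)


def classify_mspa(mask: BinaryMask, edge_width: int = 1) -> MSPAResult:
    if edge_width < 1:
        raise ValueError("edge_width must be >= 1")
    fg = mask.bits
    out = np.zeros(fg.shape, dtype=np.int8)

    core = ndimage.binary_erosion(
        fg, structure=STRUCT8, iterations=edge_width, border_value=0
    )

    comp_labels, n_comp = ndimage.label(fg, structure=STRUCT8)
    core_labels, n_core = ndimage.label(core, structure=STRUCT8)

    # Components without core are islets in their entirety.
    has_core = np.zeros(n_comp + 1, dtype=bool)
    has_core[np.unique(comp_labels[core])] = True
    islet = fg & ~has_core[comp_labels]

    # Holes: background components (4-connected complement) not reaching
    # the grid border.
    bg_labels, n_bg = ndimage.label(~fg)
    border_ids = np.unique(
        np.concatenate(
            [bg_labels[0, :], bg_labels[-1, :], bg_labels[:, 0], bg_labels[:, -1]]
        )
    )
    outer = np.isin(bg_labels, border_ids[border_ids > 0])
    hole = ~fg & ~outer

    near_outer = _dilate(outer, edge_width)
    # Outside the grid is outer background too (erosion used border_value=0).
    rr, cc = np.indices(fg.shape)
    border_dist = np.minimum.reduce(
        [rr + 1, cc + 1, fg.shape[0] - rr, fg.shape[1] - cc]
    )
    near_outer |= border_dist <= edge_width
    near_hole = _dilate(hole, edge_width)

    # Boundary zone of core regions: edge vs perforation.
    near_core = _dilate(core, edge_width)
    boundary = fg & ~core & near_core & ~islet
    edge_cells = boundary & near_outer
    perf_cells = boundary & near_hole & ~near_outer

    residue = fg & ~core & ~boundary & ~islet

    out[core] = CORE
    out[islet] = ISLET
    out[edge_cells] = EDGE
    out[perf_cells] = PERFORATION

    if residue.any() and n_core > 0:
        # Nearest-core-region id for every cell, to attribute boundary
        # cells to the core they skirt.
        _, (ir, ic) = ndimage.distance_transform_edt(~core, return_indices=True)
        nearest_core = core_labels[ir, ic]
        contactable = core | boundary
        res_labels, n_res = ndimage.label(residue, structure=STRUCT8)
        slices = ndimage.find_objects(res_labels)
        for rid, sl in enumerate(slices, start=1):
            if sl is None:
                continue
            esl = (
                slice(max(sl[0].start - 1, 0), min(sl[0].stop + 1, fg.shape[0])),
                slice(max(sl[1].start - 1, 0), min(sl[1].stop + 1, fg.shape[1])),
            )
            comp = res_labels[esl] == rid
            ring = ndimage.binary_dilation(comp, structure=STRUCT8) & ~comp
            contact = ring & contactable[esl]
            cls = BRANCH
            if contact.any():
                ids = np.unique(nearest_core[esl][contact])
                ids = ids[ids > 0]
                if len(ids) >= 2:
                    cls = BRIDGE
                elif len(ids) == 1:
                    _, n_stretch = ndimage.label(contact, structure=STRUCT8)
                    cls = LOOP if n_stretch >= 2 else BRANCH
            out[esl][comp] = cls
    elif residue.any():
        out[residue] = BRANCH

    return MSPAResult(out, edge_width, mask.cell_size, mask.origin)


def extract_cores(result: MSPAResult, min_area_hm2: float = 100.0) -> PatchSet:
    """8-connected core components with area >= ``min_area_hm2``."""
    if min_area_hm2 < 0:
        raise ValueError("min_area_hm2 must be >= 0")
    return label_mask(result.mask_of(CORE), min_area_hm2=min_area_hm2)
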