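"""End-to-end composition of the computerized sizing pipeline.

Binary mask -> marching-cubes surface -> non-shrinking smoothing ->
geodesic-ball ROI around the annotated centre -> neck-curve dome isolation
-> maximum dome diameter (MaxLen).
"""

from __future__ import annotations

import numpy as np

from aneumorph.dome_isolation import auto_neck_curve_from_plane, isolate_dome
from aneumorph.io_formats import BinaryVolume
from aneumorph.measurement import SizeMeasurement, max_diameter
from aneumorph.mesh_geometry import (
    DEFAULT_N_ROI_POINTS,
    extract_isosurface,
    extract_roi,
    smooth_non_shrinking,
)


def computerized_size_from_mask(
    volume: BinaryVolume,
    ia_center,
    neck_plane=None,
    neck_anchor_ids=None,
    n_roi_points: int = DEFAULT_N_ROI_POINTS,
    smoothing_iterations: int = 10,
    shrink_factor: float = 0.5,
    inflate_factor: float = -0.53,
    case_id: str = "",
) -> SizeMeasurement:
    """Run the full pipeline on a binary mask and return MaxLen.

    The neck annotation comes either from explicit anchor vertex ids on the
    ROI mesh (``neck_anchor_ids``) or is synthesized from an analytic
    ``neck_plane`` (point, normal) — exactly one must be given.
    """
    if (neck_plane is None) == (neck_anchor_ids is None):
        raise ValueError("give exactly one of neck_plane or neck_anchor_ids")
    mesh = extract_isosurface(volume)
    mesh = smooth_non_shrinking(
        mesh,
        iterations=smoothing_iterations,
        shrink_factor=shrink_factor,
        inflate_factor=inflate_factor,
    )
    roi = extract_roi(mesh, np.asarray(ia_center, float), n_points=n_roi_points)
    if neck_plane is not None:
        curve = auto_neck_curve_from_plane(roi, neck_plane)
    else:
        from aneumorph.dome_isolation import project_closed_curve

        curve = project_closed_curve(roi, neck_anchor_ids)
    dome = isolate_dome(roi, curve)
    return max_diameter(dome, case_id=case_id)


def measure_phantom(volume, truth, **kwargs) -> SizeMeasurement:
    """Convenience: run the pipeline on a phantom using its ground truth
    centre and neck plane for the annotation."""
    return computerized_size_from_mask(
        volume,
        ia_center=truth.dome_center,
        neck_plane=truth.neck_plane,
        case_id=truth.case_id,
        **kwargs,
    )
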