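"""Deterministic intensity-and-morphology segmenter for phantom frames.

Downstream geometry and decision tests need label masks that do not depend on
the stochastics of network training.  On phantom frames the landmark classes
are separable by intensity alone — bone echoes are bright, the femoral head
is hypoechoic — so this reference segmenter thresholds a lightly smoothed
frame and cleans the result morphologically:

* class 1 (acetabulum-ilium): pixels above ``bright_thresh`` after removing
  specks smaller than ``min_bone_px``;
* class 2 (femoral head): the largest connected dark component below
  ``dark_thresh``, if its area reaches ``min_head_px`` — otherwise the class
  is left empty (a landmark-absent result, not an error).

Valid for phantoms rendered with ``speckle_strength`` up to about 0.12 and
``shadow_strength`` up to about 0.5; beyond that the fixed thresholds start
to confuse shadow with the femoral head.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure
from skimage import morphology

from ..phantom import LabelMask


@dataclass(frozen=True)
class ReferenceSegmenterConfig:
    smooth_sigma_px: float = 1.0
    bright_thresh: float = 0.60
    dark_thresh: float = 0.18
    min_bone_px: int = 20
    min_head_px: int = 60
    #: documented validity bound on PhantomSpec.speckle_strength
    max_speckle_strength: float = 0.12


def reference_segment(image: np.ndarray,
                      config: ReferenceSegmenterConfig = ReferenceSegmenterConfig()
                      ) -> LabelMask:
    """Segment a phantom frame into background / bone / femoral head."""
    arr = np.asarray(image, dtype=float)
    smooth = ndimage.gaussian_filter(arr, sigma=config.smooth_sigma_px)

    bone = smooth > config.bright_thresh
    bone = morphology.remove_small_objects(bone, max_size=config.min_bone_px - 1)
    # close 1-px speckle gaps so the two strokes stay one clean component
    bone = morphology.closing(bone, np.ones((3, 3), dtype=bool))

    dark = smooth < config.dark_thresh
    head = np.zeros_like(dark)
    lab = skmeasure.label(dark, connectivity=2)
    if lab.max() > 0:
        counts = np.bincount(lab.ravel())
        counts[0] = 0
        biggest = int(np.argmax(counts))
        if counts[biggest] >= config.min_head_px:
            head = lab == biggest

    labels = np.zeros(arr.shape, dtype=np.uint8)
    labels[head] = 2
    labels[bone] = 1  # bone takes precedence on overlap
    return LabelMask(labels)
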