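"""Lesion-to-background contrast score I_c.

The score is the difference between the summary gray value of a lesion
region R_l and a healthy reference region R_h on the grayscale image:

    I_c = g(R_l) - g(R_h)

with g(R) the mean intensity of region R by default.  On an 8-bit scale
the magnitude lies in [0, 255]; small values mean the lesion is barely
distinguishable from surrounding mucosa, large values mean high lesion
visibility.  By default the absolute value is reported (the score is a
visibility magnitude: a dye may render a depressed lesion darker or
brighter than background) while the signed difference is retained in the
result record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_model import RegionPair, region_mean, validate_gray_image

__all__ = ["ContrastResult", "contrast_score"]


@dataclass(frozen=True)
class ContrastResult:
    """Contrast score with its constituent region means.

    ``i_c`` is the reported score (absolute value when ``absolute`` is
    True); ``signed`` always holds ``lesion_mean - healthy_mean``.
    """

    i_c: float
    signed: float
    lesion_mean: float
    healthy_mean: float
    absolute: bool


def contrast_score(
    img: np.ndarray,
    regions: RegionPair,
    absolute: bool = True,
    stat: str = "mean",
) -> ContrastResult:
    """Compute the lesion-to-background contrast I_c on a gray image.

    Parameters
    ----------
    img
        2-D gray image with intensities in [0, 255].
    regions
        Disjoint lesion / healthy masks; both must be nonempty and match
        the image shape.
    absolute
        Report |I_c| (default).  The signed difference is kept in the
        result either way.
    stat
        Region summary statistic, ``"mean"`` (default) or ``"median"``.
    """
    img = validate_gray_image(img)
    lesion_mean = region_mean(img, regions.lesion_mask, stat=stat)
    healthy_mean = region_mean(img, regions.healthy_mask, stat=stat)
    signed = lesion_mean - healthy_mean
    return ContrastResult(
        i_c=abs(signed) if absolute else signed,
        signed=signed,
        lesion_mean=lesion_mean,
        healthy_mean=healthy_mean,
        absolute=absolute,
    )
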