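"""Shared helpers for constructing toy masks and GC instances in tests."""

import numpy as np
from skimage.draw import disk as draw_disk

from nodemorph.morphometrics import GCInstance


def disk_mask(shape, center_rc, r):
    m = np.zeros(shape, bool)
    rr, cc = draw_disk(center_rc, r, shape=shape)
    m[rr, cc] = True
    return m


def disk_instance(shape, center_rc, r):
    m = disk_mask(shape, center_rc, r)
    return GCInstance(polygon=np.zeros((4, 2)), coords=np.argwhere(m),
                      frame_shape=shape, area_mm2=1.0, perimeter_mm=1.0,
                      circularity=1.0, centroid_xy=center_rc[::-1])
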