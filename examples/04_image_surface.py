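"""Measure tattoo surface from a calibrated photograph stand-in.

A synthetic image plays the role of a tattoo photograph: the scale comes
from a known in-image distance (here 100 px = 10 cm), ink is darker than
skin so thresholding selects it, and the area is averaged over three
thresholds. Color-resolved areas use nearest-prototype classification.
"""

import numpy as np

from tatexpo import (
    CalibratedImage,
    binary_area,
    calibrate_scale,
    color_class_area,
    threshold_set,
)

scale = calibrate_scale(pixel_distance=100, physical_distance_cm=10)  # 10 px/cm

# grayscale: a 5 cm-radius disk of ink on pale skin
yy, xx = np.mgrid[0:200, 0:200]
gray = np.full((200, 200), 230, dtype=np.uint8)
gray[(xx - 100) ** 2 + (yy - 100) ** 2 <= 50**2] = 20
image = CalibratedImage(gray, scale)

thresholds = threshold_set(image, delta=10)
meas = binary_area(image, thresholds)
print(f"thresholds: {thresholds}")
print(f"measured ink area: {meas.total_area_cm2:.1f} cm^2 (analytic {np.pi * 25:.1f})")

# RGB: a red 10x10 cm square and a blue 5x5 cm square
rgb = np.full((300, 300, 3), 255, dtype=np.uint8)
rgb[10:110, 10:110] = (200, 30, 30)
rgb[150:200, 150:200] = (40, 70, 200)
per_color = color_class_area(CalibratedImage(rgb, scale), ["red", "blue"])
for color, area in per_color.items():
    print(f"{color:5s} area: {area:.1f} cm^2")

# Areas are pixel counts divided by scale^2; the disk recovers pi*r^2 to
# within pixelation error and the painted squares are exact.
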