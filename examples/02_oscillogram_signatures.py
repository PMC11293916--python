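"""Oscillogram signatures of the six Lenke curve types.

Each scoliotic curve leaves one peak-trough pair in the 34-endplate tilt
sequence; the peak-trough height is the curve's Cobb angle.  This renders
all six preset signatures into one directory of SVGs.
"""

import dataclasses
from pathlib import Path

from oscillocobb import build_oscillogram, detect_curves, find_extrema, preset_for_type, simulate_case
from oscillocobb.plotting import plot_oscillogram

out_dir = Path("oscillogram_signatures")
out_dir.mkdir(exist_ok=True)

for k in range(1, 7):
    views, truth = simulate_case(dataclasses.replace(preset_for_type(k), landmark_noise_sd=0.0))
    series = build_oscillogram(views.coronal)
    extrema = find_extrema(series, 5.0)
    curves = detect_curves(series, views.coronal)
    path = out_dir / f"lenke{k}.svg"
    plot_oscillogram(series, extrema, curves, path=path, title=f"Lenke {k}")
    marks = ", ".join(f"{e.polarity}@{e.index}" for e in extrema)
    print(f"Lenke {k}: extrema [{marks}] -> {path}")

print()
print("Peaks/troughs mark the end vertebrae; adjacent curves share the merged")
print("extremum between them (e.g. the deep mid-thoracic trough of type 2).")
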