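"""Color-Doppler neovascularization area over a frame sequence.

Builds a 4-frame synthetic Doppler sequence whose colored blob grows and
shrinks (peaking at 6.5 mm^2) and reports the per-frame areas and the
sequence maximum — the vascularity outcome.
"""

from tendonkit import PolygonROI
from tendonkit import doppler as dop
from tendonkit import synthetic as syn

roi = PolygonROI.rectangle(3.5, 3.5, 44.5, 64.5)
seq, truth_areas = syn.gen_doppler_sequence(
    n_frames=4, blob_areas_mm2=[1.0, 6.5, 3.0, 0.5],
    pixel_size_mm=(0.1, 0.1), roi=roi, seed=0)

res = dop.sequence_max_area(seq, chroma_threshold=30)
for i, (a, t) in enumerate(zip(res.per_frame_area_mm2, truth_areas)):
    print(f"frame {i}: measured {a:5.2f} mm^2 (generated {t:5.2f} mm^2)")
print(f"sequence maximum: {res.max_area_mm2:.2f} mm^2 at frame {res.argmax_frame}")
print("\nThe sequence maximum is the neovascularization index; measured areas "
      "match the generated pixel budgets exactly.")
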