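"""Peak spatial frequency of a tendon-like speckle image.

Generates two synthetic B-mode images — one with well-aligned fascicle bands
(0.5 mm spacing) and one heavily disorganized — and computes the kernel-mean
peak spatial frequency (PSF) inside a rectangular ROI. A higher PSF means
denser, better-aligned collagen bands; the disorganized image should score
clearly lower.
"""

from tendonkit import PolygonROI, image_psf
from tendonkit import synthetic as syn

roi = PolygonROI.rectangle(-0.5, -0.5, 95.5, 159.5)

for label, d in (("aligned bands", 0.0), ("disorganized ", 0.85)):
    image = syn.gen_speckle_image(syn.SpeckleSpec(
        image_size_px=(96, 160), pixel_size_mm=(0.05, 0.05),
        band_spacing_mm=0.5, disorganization=d, speckle_contrast=0.4, seed=7))
    res = image_psf(image, roi)
    print(f"{label}: mean PSF = {res.mean_psf_mm_inv:.3f} mm^-1 "
          f"over {res.n_kernels} kernels ({res.n_no_peak} without a peak)")

print("\nThe aligned pattern peaks near 1/0.5 mm = 2.0 mm^-1; disorganization "
      "pushes the spectral peak toward the high-pass cutoff (1.23 mm^-1).")
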