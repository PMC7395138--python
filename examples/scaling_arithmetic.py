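"""Expansion-scaling bookkeeping: what a factor of ~16 buys.

The closed-form conversions between image-frame and specimen-frame
lengths: effective PSF size after correction, volumetric decrowding,
inter-protein spacing in the gel, and the residual antibody-label
offset.
"""

from exmetric import scale_convert

print("effective PSF, 300 nm optics at 13x: "
      f"{scale_convert(300, 13, 'image_to_specimen'):.1f} nm in the specimen")
print("effective PSF, 250 nm optics at 21x: "
      f"{scale_convert(250, 21, 'image_to_specimen'):.1f} nm in the specimen")
print("volumetric decrowding at 16x linear: "
      f"{scale_convert(0, 16, 'volumetric'):.0f}-fold")
print("3 nm inter-protein spacing in the expanded gel: "
      f"{scale_convert(3, 16, 'specimen_to_image'):.0f} nm")
print("25 nm antibody span, expansion-corrected: "
      f"{scale_convert(25, 16, 'image_to_specimen'):.2f} nm")
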