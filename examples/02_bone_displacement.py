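"""Recover a known surgical displacement from noisy landmarks.

Simulates a bimaxillary case (+6 mm maxillary advancement, +4 mm mandibular
advancement) with 0.3 mm landmark picking noise and a random scan pose,
then runs the cranial-base + segment registration to read the signed
six-DOF displacement back out.  The antero-posterior (AP) component is the
clinically analysed quantity: advancement positive, setback negative.
"""

from airwaymorph import compute_bone_displacement, simulate_case

case = simulate_case(6.0, 4.0, noise=0.3, seed=21, patient="demo", group="MMA")

for segment, truth in (("maxilla", 6.0), ("mandible", 4.0)):
    rec = compute_bone_displacement(case.pre, case.post, segment, patient="demo")
    print(f"{segment:9s} AP = {rec.ap:+.2f} mm (simulated {truth:+.1f}), "
          f"rotations (pitch/roll/yaw) = "
          f"{rec.pitch:+.2f}/{rec.roll:+.2f}/{rec.yaw:+.2f} deg, "
          f"landmark fit RMS = {rec.residual_rms:.2f} mm")
print("\nThe residual RMS reflects the 0.3 mm picking noise; AP errors stay "
      "within a few tenths of a millimetre.  Rotations are less reliable: "
      "the four cusp landmarks are nearly coplanar, so pitch is poorly "
      "constrained by landmarks alone (ICP against segment meshes refines "
      "it when those are available).")
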