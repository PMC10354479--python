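# Wing posture presets: sweep angles in degrees from the transverse axis,
# posterior sweep positive. Taxon-specific poses are approximations
# digitised from published skeletal reconstructions; they are editable
# configuration, not ground truth. The anterior-sweep pose (shoulder
# forward, elbow back) used for Pteranodon is shared by Sinopterus and
# Pterodactylus; the neutral pose is the across-taxa average with the
# leading edge essentially perpendicular to the body axis.
Rhamphorhynchus:
  sweep: {humerus: -25, ulna_radius: 20, mcIV: -5, wp1: 0, wp2: 12, wp3: 30, wp4: 55}
  femur_angle: 45
anurognathids:
  sweep: {humerus: -25, ulna_radius: 20, mcIV: -5, wp1: 0, wp2: 12, wp3: 30, wp4: 55}
  femur_angle: 45
Pteranodon:
  sweep: {humerus: -35, ulna_radius: 25, mcIV: -10, wp1: -5, wp2: 20, wp3: 40, wp4: 60}
  femur_angle: 45
Sinopterus:
  sweep: {humerus: -35, ulna_radius: 25, mcIV: -10, wp1: -5, wp2: 20, wp3: 40, wp4: 60}
  femur_angle: 45
Pterodactylus:
  sweep: {humerus: -35, ulna_radius: 25, mcIV: -10, wp1: -5, wp2: 20, wp3: 40, wp4: 60}
  femur_angle: 45
neutral:
  sweep: {humerus: -31, ulna_radius: 23, mcIV: -8, wp1: -3, wp2: 17, wp3: 36, wp4: 58}
  femur_angle: 45
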