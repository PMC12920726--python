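"""Shipped organ lookup tables.

``DEFAULT_MODEL_TABLE`` decides whether an organ is aligned rigidly
(bones, vertebrae) or with an affine transform (soft tissue);
``DEFAULT_REGION_TABLE`` assigns each organ to one of the six anatomical
regions used for harmonic interpolation.  Both are plain dicts and can be
overridden through configuration; names match case-insensitively, with
prefix matching for instance-numbered structures (vertebra_l1, rib_3, ...).
"""

DEFAULT_MODEL_TABLE: dict[str, str] = {
    # rigid: skeleton
    "skull": "rigid",
    "vertebra": "rigid",
    "spine": "rigid",
    "rib": "rigid",
    "sternum": "rigid",
    "pelvis": "rigid",
    "sacrum": "rigid",
    "hip": "rigid",
    "femur": "rigid",
    "left_femur": "rigid",
    "right_femur": "rigid",
    "humerus": "rigid",
    "left_humerus": "rigid",
    "right_humerus": "rigid",
    "tibia": "rigid",
    "clavicle": "rigid",
    "scapula": "rigid",
    # affine: soft tissue
    "brain": "affine",
    "liver": "affine",
    "spleen": "affine",
    "pancreas": "affine",
    "stomach": "affine",
    "gallbladder": "affine",
    "lung": "affine",
    "left_lung": "affine",
    "right_lung": "affine",
    "kidney": "affine",
    "left_kidney": "affine",
    "right_kidney": "affine",
    "heart": "affine",
    "aorta": "affine",
    "bladder": "affine",
    "urinary_bladder": "affine",
    "prostate": "affine",
    "thyroid": "affine",
}

DEFAULT_REGION_TABLE: dict[str, str] = {
    "brain": "head",
    "skull": "head",
    "thyroid": "head",
    "vertebra": "torso",
    "spine": "torso",
    "rib": "torso",
    "sternum": "torso",
    "clavicle": "torso",
    "scapula": "torso",
    "liver": "torso",
    "spleen": "torso",
    "pancreas": "torso",
    "stomach": "torso",
    "gallbladder": "torso",
    "lung": "torso",
    "left_lung": "torso",
    "right_lung": "torso",
    "kidney": "torso",
    "left_kidney": "torso",
    "right_kidney": "torso",
    "heart": "torso",
    "aorta": "torso",
    "bladder": "torso",
    "urinary_bladder": "torso",
    "prostate": "torso",
    "pelvis": "torso",
    "sacrum": "torso",
    "hip": "torso",
    "left_humerus": "left_arm",
    "right_humerus": "right_arm",
    "left_radius": "left_arm",
    "right_radius": "right_arm",
    "left_ulna": "left_arm",
    "right_ulna": "right_arm",
    "left_femur": "left_leg",
    "right_femur": "right_leg",
    "left_tibia": "left_leg",
    "right_tibia": "right_leg",
}
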