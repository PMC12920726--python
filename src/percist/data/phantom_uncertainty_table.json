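{
 "distances": {
  "brain": [
   4.242640687119285,
   4.242640687119285,
   4.242640687119285,
   3.0,
   4.242640687119285
  ],
  "liver": [
   3.0,
   3.0,
   4.242640687119285,
   4.242640687119285,
   0.0
  ],
  "spleen": [
   3.0,
   0.0,
   3.0,
   3.0,
   3.0
  ],
  "left_lung": [
   4.242640687119285,
   3.0,
   3.0,
   4.242640687119285,
   4.242640687119285
  ],
  "right_lung": [
   3.0,
   4.242640687119285,
   3.0,
   3.0,
   0.0
  ],
  "heart": [
   3.0,
   4.242640687119285,
   0.0,
   3.0,
   3.0
  ],
  "aorta": [
   3.0,
   3.0,
   4.242640687119285,
   4.242640687119285,
   4.242640687119285
  ],
  "urinary_bladder": [
   3.0,
   0.0,
   3.0,
   0.0,
   3.0
  ],
  "vertebra_1": [
   3.0,
   3.0,
   3.0,
   3.0,
   0.0
  ],
  "vertebra_2": [
   3.0,
   0.0,
   3.0,
   0.0,
   3.0
  ],
  "vertebra_3": [
   3.0,
   0.0,
   3.0,
   0.0,
   3.0
  ],
  "left_humerus": [
   3.0,
   3.0,
   0.0,
   3.0,
   3.0
  ],
  "right_humerus": [
   3.0,
   3.0,
   3.0,
   3.0,
   3.0
  ],
  "left_femur": [
   3.0,
   3.0,
   3.0,
   3.0,
   0.0
  ],
  "right_femur": [
   3.0,
   3.0,
   0.0,
   3.0,
   3.0
  ]
 },
 "values": {
  "brain": 4.242640687119285,
  "liver": 4.242640687119285,
  "spleen": 3.0,
  "left_lung": 4.242640687119285,
  "right_lung": 3.0,
  "heart": 3.0,
  "aorta": 4.242640687119285,
  "urinary_bladder": 3.0,
  "vertebra_1": 3.0,
  "vertebra_2": 3.0,
  "vertebra_3": 3.0,
  "left_humerus": 3.0,
  "right_humerus": 3.0,
  "left_femur": 3.0,
  "right_femur": 3.0
 }
}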