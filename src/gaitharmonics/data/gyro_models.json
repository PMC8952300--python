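{
  "signal_kind": "normalized",
  "description": "Harmonic-model coefficients (amplitude normalized to the fundamental, phases in radians, cosine convention) for the sagittal gyro signal of the six most common stride patterns during level walking. Fundamental frequency is a placeholder of 1 Hz; it is replaced by the stride frequency at reconstruction time.",
  "models": [
    {
      "label": 1,
      "fundamental_hz": 1.0,
      "dc_offset": 0.0,
      "harmonics": [
        {"n": 1, "amplitude": 1.0, "phase_rad": 5.19},
        {"n": 2, "amplitude": 0.36027, "phase_rad": 4.402},
        {"n": 3, "amplitude": 0.2489, "phase_rad": 3.3649},
        {"n": 4, "amplitude": 0.059486, "phase_rad": 4.5546},
        {"n": 5, "amplitude": 0.063368, "phase_rad": 3.0386},
        {"n": 6, "amplitude": 0.051567, "phase_rad": 2.0871},
        {"n": 7, "amplitude": 0.043595, "phase_rad": 5.3394},
        {"n": 8, "amplitude": 0.06063, "phase_rad": 2.397},
        {"n": 9, "amplitude": 0.006469, "phase_rad": 4.7733}
      ]
    },
    {
      "label": 2,
      "fundamental_hz": 1.0,
      "dc_offset": 0.0,
      "harmonics": [
        {"n": 1, "amplitude": 1.0, "phase_rad": 4.996},
        {"n": 2, "amplitude": 0.42343, "phase_rad": 4.3092},
        {"n": 3, "amplitude": 0.084499, "phase_rad": 2.1904},
        {"n": 4, "amplitude": 0.085638, "phase_rad": 4.3984},
        {"n": 5, "amplitude": 0.047704, "phase_rad": 2.1871},
        {"n": 6, "amplitude": 0.01632, "phase_rad": 2.187},
        {"n": 7, "amplitude": 0.028081, "phase_rad": 3.7139},
        {"n": 8, "amplitude": 0.008522, "phase_rad": 1.0669},
        {"n": 9, "amplitude": 0.00339, "phase_rad": 5.8446}
      ]
    },
    {
      "label": 3,
      "fundamental_hz": 1.0,
      "dc_offset": 0.0,
      "harmonics": [
        {"n": 1, "amplitude": 1.0, "phase_rad": 5.0759},
        {"n": 2, "amplitude": 0.42098, "phase_rad": 4.58},
        {"n": 3, "amplitude": 0.22486, "phase_rad": 2.9632},
        {"n": 4, "amplitude": 0.11145, "phase_rad": 5.1886},
        {"n": 5, "amplitude": 0.10383, "phase_rad": 3.1609},
        {"n": 6, "amplitude": 0.014819, "phase_rad": 1.4992},
        {"n": 7, "amplitude": 0.042851, "phase_rad": 4.2084},
        {"n": 8, "amplitude": 0.031311, "phase_rad": 1.8894},
        {"n": 9, "amplitude": 0.002707, "phase_rad": 4.9969}
      ]
    },
    {
      "label": 4,
      "fundamental_hz": 1.0,
      "dc_offset": 0.0,
      "harmonics": [
        {"n": 1, "amplitude": 1.0, "phase_rad": 5.0243},
        {"n": 2, "amplitude": 0.46313, "phase_rad": 4.666},
        {"n": 3, "amplitude": 0.28408, "phase_rad": 2.8688},
        {"n": 4, "amplitude": 0.12266, "phase_rad": 5.3146},
        {"n": 5, "amplitude": 0.087658, "phase_rad": 2.9082},
        {"n": 6, "amplitude": 0.039558, "phase_rad": 0.79304},
        {"n": 7, "amplitude": 0.064016, "phase_rad": 4.4247},
        {"n": 8, "amplitude": 0.030717, "phase_rad": 1.7806},
        {"n": 9, "amplitude": 0.002826, "phase_rad": 4.7229}
      ]
    },
    {
      "label": 5,
      "fundamental_hz": 1.0,
      "dc_offset": 0.0,
      "harmonics": [
        {"n": 1, "amplitude": 1.0, "phase_rad": 4.9736},
        {"n": 2, "amplitude": 0.53663, "phase_rad": 4.8087},
        {"n": 3, "amplitude": 0.25256, "phase_rad": 2.7775},
        {"n": 4, "amplitude": 0.15274, "phase_rad": 5.2844},
        {"n": 5, "amplitude": 0.077172, "phase_rad": 3.0107},
        {"n": 6, "amplitude": 0.029039, "phase_rad": 3.3201},
        {"n": 7, "amplitude": 0.049497, "phase_rad": 4.3447},
        {"n": 8, "amplitude": 0.015691, "phase_rad": 1.9591},
        {"n": 9, "amplitude": 0.000666, "phase_rad": 3.3624}
      ]
    },
    {
      "label": 6,
      "fundamental_hz": 1.0,
      "dc_offset": 0.0,
      "harmonics": [
        {"n": 1, "amplitude": 1.0, "phase_rad": 5.0247},
        {"n": 2, "amplitude": 0.36973, "phase_rad": 4.8195},
        {"n": 3, "amplitude": 0.32584, "phase_rad": 3.1308},
        {"n": 4, "amplitude": 0.086019, "phase_rad": 5.6766},
        {"n": 5, "amplitude": 0.10968, "phase_rad": 3.9544},
        {"n": 6, "amplitude": 0.069381, "phase_rad": 1.4251},
        {"n": 7, "amplitude": 0.067827, "phase_rad": 4.5243},
        {"n": 8, "amplitude": 0.022453, "phase_rad": 1.9092},
        {"n": 9, "amplitude": 0.000749, "phase_rad": 4.6469}
      ]
    }
  ]
}
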