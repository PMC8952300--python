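{
  "signal_kind": "normalized",
  "description": "Harmonic-model coefficients (amplitude normalized to the fundamental, phases in radians, cosine convention) for the six most common thigh flexion-extension stride patterns during level walking. Fundamental frequency is a placeholder of 1 Hz; it is replaced by the stride frequency at reconstruction time.",
  "models": [
    {
      "label": 1,
      "fundamental_hz": 1.0,
      "dc_offset": 0.0,
      "harmonics": [
        {"n": 1, "amplitude": 1.0, "phase_rad": 3.6133},
        {"n": 2, "amplitude": 0.18150, "phase_rad": 2.8125},
        {"n": 3, "amplitude": 0.08525, "phase_rad": 1.7860},
        {"n": 4, "amplitude": 0.015085, "phase_rad": 2.8816},
        {"n": 5, "amplitude": 0.013952, "phase_rad": 1.4683}
      ]
    },
    {
      "label": 2,
      "fundamental_hz": 1.0,
      "dc_offset": 0.0,
      "harmonics": [
        {"n": 1, "amplitude": 1.0, "phase_rad": 3.4174},
        {"n": 2, "amplitude": 0.21348, "phase_rad": 2.7200},
        {"n": 3, "amplitude": 0.03001, "phase_rad": 0.6868},
        {"n": 4, "amplitude": 0.022038, "phase_rad": 2.7407},
        {"n": 5, "amplitude": 0.010615, "phase_rad": 0.7321}
      ]
    },
    {
      "label": 3,
      "fundamental_hz": 1.0,
      "dc_offset": 0.0,
      "harmonics": [
        {"n": 1, "amplitude": 1.0, "phase_rad": 3.5088},
        {"n": 2, "amplitude": 0.20959, "phase_rad": 3.0176},
        {"n": 3, "amplitude": 0.07352, "phase_rad": 1.3860},
        {"n": 4, "amplitude": 0.028212, "phase_rad": 3.6534},
        {"n": 5, "amplitude": 0.019884, "phase_rad": 1.5846}
      ]
    },
    {
      "label": 4,
      "fundamental_hz": 1.0,
      "dc_offset": 0.0,
      "harmonics": [
        {"n": 1, "amplitude": 1.0, "phase_rad": 3.4504},
        {"n": 2, "amplitude": 0.23148, "phase_rad": 3.0875},
        {"n": 3, "amplitude": 0.09581, "phase_rad": 1.2984},
        {"n": 4, "amplitude": 0.030199, "phase_rad": 3.727},
        {"n": 5, "amplitude": 0.018138, "phase_rad": 1.3387}
      ]
    },
    {
      "label": 5,
      "fundamental_hz": 1.0,
      "dc_offset": 0.0,
      "harmonics": [
        {"n": 1, "amplitude": 1.0, "phase_rad": 3.4057},
        {"n": 2, "amplitude": 0.26781, "phase_rad": 3.2431},
        {"n": 3, "amplitude": 0.08322, "phase_rad": 1.1994},
        {"n": 4, "amplitude": 0.038494, "phase_rad": 3.7332},
        {"n": 5, "amplitude": 0.014827, "phase_rad": 1.4261}
      ]
    },
    {
      "label": 6,
      "fundamental_hz": 1.0,
      "dc_offset": 0.0,
      "harmonics": [
        {"n": 1, "amplitude": 1.0, "phase_rad": 3.4515},
        {"n": 2, "amplitude": 0.18452, "phase_rad": 3.2409},
        {"n": 3, "amplitude": 0.10950, "phase_rad": 1.5581},
        {"n": 4, "amplitude": 0.021041, "phase_rad": 4.0952},
        {"n": 5, "amplitude": 0.022180, "phase_rad": 2.3650}
      ]
    }
  ]
}
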