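{
  "comment": "Illustrative mouse-brain-like study conditions: concentrations in mM (NAD+ ~ 2x NADH, total NAD ~ 0.42 mM), per-metabolite linewidths in Hz (PCr 13 Hz), and a smooth broad baseline (broad Lorentzian humps; center_ppm, fwhm_hz, height). These are plausible defaults, not measured values.",
  "concentrations_mM": {
    "PCr": 3.3, "gATP": 2.8, "aATP": 2.8, "bATP": 2.8,
    "Pi_int": 1.0, "Pi_ext": 0.3, "PE": 2.0, "PC": 0.6,
    "GPE": 0.9, "GPC": 0.6, "MP": 2.5, "UDPG": 0.1,
    "NADH": 0.14, "NAD+": 0.28
  },
  "linewidths_hz": {
    "PCr": 13.0, "gATP": 18.0, "aATP": 18.0, "bATP": 20.0,
    "Pi_int": 15.0, "Pi_ext": 15.0, "PE": 16.0, "PC": 16.0,
    "GPE": 16.0, "GPC": 16.0, "MP": 250.0, "UDPG": 20.0,
    "NADH": 18.0, "NAD+": 18.0
  },
  "baseline": {
    "kind": "broad_peaks",
    "peaks": [[-9.0, 2500.0, 0.012], [3.0, 1200.0, 0.02]]
  }
}
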