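{
  "comment": "Literature-default 31P spin parameters for the 14-metabolite mouse-brain basis. Chemical shifts are ppm relative to PCr at 0; line offsets are Hz about each resonance centre. These defaults are editable placeholders (ground truth in all synthetic tests comes from the generator, not from this file). The NAD+ signal is a symmetric four-line pattern parameterized by an internal shift difference of 60 Hz between its two doublets and a 20 Hz coupling; NADH is a singlet on the alpha-ATP shoulder.",
  "systems": [
    {"name": "PCr", "nuclei_per_molecule": 1, "resonances": [
      {"shift_ppm": 0.0, "amplitude": 1.0, "lines": [{"offset_hz": 0.0, "weight": 1.0}]}]},
    {"name": "gATP", "nuclei_per_molecule": 1, "resonances": [
      {"shift_ppm": -2.50, "amplitude": 1.0, "lines": [
        {"offset_hz": -8.15, "weight": 0.5}, {"offset_hz": 8.15, "weight": 0.5}]}]},
    {"name": "aATP", "nuclei_per_molecule": 1, "resonances": [
      {"shift_ppm": -7.60, "amplitude": 1.0, "lines": [
        {"offset_hz": -8.05, "weight": 0.5}, {"offset_hz": 8.05, "weight": 0.5}]}]},
    {"name": "bATP", "nuclei_per_molecule": 1, "resonances": [
      {"shift_ppm": -16.20, "amplitude": 1.0, "lines": [
        {"offset_hz": -16.2, "weight": 0.25}, {"offset_hz": 0.0, "weight": 0.5},
        {"offset_hz": 16.2, "weight": 0.25}]}]},
    {"name": "Pi_int", "nuclei_per_molecule": 1, "resonances": [
      {"shift_ppm": 4.90, "amplitude": 1.0, "lines": [{"offset_hz": 0.0, "weight": 1.0}]}]},
    {"name": "Pi_ext", "nuclei_per_molecule": 1, "resonances": [
      {"shift_ppm": 5.25, "amplitude": 1.0, "lines": [{"offset_hz": 0.0, "weight": 1.0}]}]},
    {"name": "PE", "nuclei_per_molecule": 1, "resonances": [
      {"shift_ppm": 6.78, "amplitude": 1.0, "lines": [{"offset_hz": 0.0, "weight": 1.0}]}]},
    {"name": "PC", "nuclei_per_molecule": 1, "resonances": [
      {"shift_ppm": 6.24, "amplitude": 1.0, "lines": [{"offset_hz": 0.0, "weight": 1.0}]}]},
    {"name": "GPE", "nuclei_per_molecule": 1, "resonances": [
      {"shift_ppm": 3.50, "amplitude": 1.0, "lines": [{"offset_hz": 0.0, "weight": 1.0}]}]},
    {"name": "GPC", "nuclei_per_molecule": 1, "resonances": [
      {"shift_ppm": 2.95, "amplitude": 1.0, "lines": [{"offset_hz": 0.0, "weight": 1.0}]}]},
    {"name": "MP", "nuclei_per_molecule": 1, "resonances": [
      {"shift_ppm": 2.00, "amplitude": 1.0, "lines": [{"offset_hz": 0.0, "weight": 1.0}]}]},
    {"name": "UDPG", "nuclei_per_molecule": 2, "resonances": [
      {"shift_ppm": -9.80, "amplitude": 1.0, "lines": [
        {"offset_hz": -10.0, "weight": 0.5}, {"offset_hz": 10.0, "weight": 0.5}]},
      {"shift_ppm": -11.50, "amplitude": 1.0, "lines": [
        {"offset_hz": -10.0, "weight": 0.5}, {"offset_hz": 10.0, "weight": 0.5}]}]},
    {"name": "NADH", "nuclei_per_molecule": 2, "resonances": [
      {"shift_ppm": -8.13, "amplitude": 1.0, "lines": [{"offset_hz": 0.0, "weight": 1.0}]}]},
    {"name": "NAD+", "nuclei_per_molecule": 2, "resonances": [
      {"shift_ppm": -8.30, "amplitude": 1.0, "lines": [
        {"offset_hz": -40.0, "weight": 0.25}, {"offset_hz": -20.0, "weight": 0.25},
        {"offset_hz": 20.0, "weight": 0.25}, {"offset_hz": 40.0, "weight": 0.25}]}]}
  ]
}
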