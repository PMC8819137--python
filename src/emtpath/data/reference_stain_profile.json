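{
  "comment": "Synthetic reference H&E stain space: column-unit OD vectors (hematoxylin, eosin) matching the package's Beer-Lambert rendering defaults, with per-stain 99th-percentile reference concentrations.",
  "stain_matrix": [
    [0.650028, 0.249863],
    [0.704031, 0.949479],
    [0.286013, 0.189896]
  ],
  "max_concentrations": [1.2, 1.3],
  "i0": 255.0,
  "od_threshold": 0.15,
  "angle_percentile": 1.0
}
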