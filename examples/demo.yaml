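# Demo configuration for `adipoflim run --config examples/demo.yaml
#                          --out runs/demo --seed 7`
# Small phantom fields keep the whole run to a few seconds on one CPU.
seed: 7
erosion_radius: 2        # gentler than the 5 px production default for 48 px fields
simulate:
  mice_per_cell: 2
  images_per_mouse: 2
  depots: [BAT, scWAT]
  image_size: 48
  photons_per_pixel: 400
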